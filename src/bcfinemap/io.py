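"""Readers and writers for summary-statistic and result files.

Formats are deliberately plain: z-scores as a two-column TSV
(variant id, z; optional header), the LD matrix as a whitespace- or
comma-delimited square matrix (optionally gzipped), PIPs and credible
sets as TSV tables with ``#`` header comments recording the run
parameters. Variant order is file order everywhere; the LD matrix must
match the z-score file row for row — no reordering by id is attempted.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable

import numpy as np

from .data import SummaryStats
from .posterior import CredibleSet, FineMapResult

__all__ = [
    "read_zscores",
    "read_ld",
    "read_summary_stats",
    "write_zscores",
    "write_ld",
    "write_summary_stats",
    "write_pip_table",
    "write_credible_sets",
    "write_plink_raw",
]

logger = logging.getLogger("bcfinemap")

Z_CLIP = 200.0
_FLOAT_FMT = "%.10g"


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_zscores(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a (variant id, z) TSV; returns ids and z in file order.

    An optional single header line is detected by a non-numeric second
    column. Non-finite z values are clipped to +/-200 with a warning;
    duplicate ids and non-numeric values raise with the line number.
    """
    ids: list[str] = []
    zs: list[float] = []
    seen: dict[str, int] = {}
    first_row = True
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected at least 2 columns")
            vid, raw = parts[0], parts[1]
            try:
                z = float(raw)
            except ValueError:
                if first_row:
                    first_row = False
                    continue  # header line
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric z value {raw!r}"
                ) from None
            first_row = False
            if vid in seen:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate variant id {vid!r} "
                    f"(first seen on line {seen[vid]})"
                )
            seen[vid] = lineno
            if not np.isfinite(z) or abs(z) > Z_CLIP:
                clipped = float(np.clip(np.nan_to_num(z, nan=0.0, posinf=np.inf, neginf=-np.inf),
                                        -Z_CLIP, Z_CLIP))
                logger.warning(
                    "%s: line %d: z=%s clipped to %g", path, lineno, raw, clipped
                )
                z = clipped
            ids.append(vid)
            zs.append(z)
    if not ids:
        raise ValueError(f"{path}: no z-score rows found")
    return ids, np.array(zs)


def read_ld(path: str | Path, m: int | None = None) -> np.ndarray:
    """Read a square LD matrix; symmetrize and pin the diagonal to 1.

    Asymmetry above 1e-6, off-square shapes, or entries outside
    [-1-1e-6, 1+1e-6] raise. Comma and whitespace delimiters are both
    accepted; ``.gz`` files are transparently decompressed.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        delim = "," if "," in first else None
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[arg-type]
        mat = np.loadtxt(fh, delimiter=delim, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: LD matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
    if m is not None and mat.shape[0] != m:
        raise ValueError(f"{path}: LD matrix has {mat.shape[0]} variants, expected {m}")
    asym = float(np.max(np.abs(mat - mat.T))) if mat.size else 0.0
    if asym > 1e-6:
        raise ValueError(f"{path}: LD matrix asymmetry {asym:.2e} exceeds 1e-6")
    mat = 0.5 * (mat + mat.T)
    if np.any(np.abs(mat) > 1.0 + 1e-6):
        raise ValueError(f"{path}: LD entries outside [-1, 1] beyond tolerance")
    diag_err = float(np.max(np.abs(np.diag(mat) - 1.0)))
    if diag_err > 1e-6:
        raise ValueError(f"{path}: LD diagonal deviates from 1 by {diag_err:.2e}")
    np.fill_diagonal(mat, 1.0)
    return np.clip(mat, -1.0, 1.0)


def read_summary_stats(z_path: str | Path, ld_path: str | Path, n: int) -> SummaryStats:
    ids, z = read_zscores(z_path)
    ld = read_ld(ld_path, m=len(ids))
    return SummaryStats(z=z, ld=ld, n=n, variant_ids=ids)


def write_zscores(path: str | Path, variant_ids: Iterable[str], z: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tz\n")
        for vid, zi in zip(variant_ids, np.asarray(z, dtype=float)):
            fh.write(f"{vid}\t{_FLOAT_FMT % zi}\n")


def write_ld(path: str | Path, ld: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            np.savetxt(fh, ld, fmt=_FLOAT_FMT, delimiter="\t")
    else:
        np.savetxt(path, ld, fmt=_FLOAT_FMT, delimiter="\t")


def write_summary_stats(stats: SummaryStats, z_path: str | Path, ld_path: str | Path) -> None:
    """Write z-scores and LD; round-trips losslessly to 10 significant digits."""
    write_zscores(z_path, stats.variant_ids, stats.z)
    write_ld(ld_path, stats.ld)


def _header_comment(diagnostics: dict) -> str:
    keys = ("seed", "binarize_gamma", "sigma2", "coverage")
    parts = [f"{k}={diagnostics[k]}" for k in keys if k in diagnostics]
    return "# " + " ".join(parts) + "\n" if parts else ""


def write_pip_table(path: str | Path, result: FineMapResult) -> None:
    """PIP table TSV: variant_id, pip; run parameters in a # header."""
    with open(path, "w") as fh:
        fh.write(_header_comment(result.diagnostics))
        fh.write("variant_id\tpip\n")
        for vid, pip in zip(result.variant_ids, result.pip):
            fh.write(f"{vid}\t{_FLOAT_FMT % pip}\n")


def write_credible_sets(path: str | Path, result: FineMapResult) -> None:
    """Credible-set TSV: set_id, variant_id, pip, attained_coverage."""
    with open(path, "w") as fh:
        fh.write(_header_comment(result.diagnostics))
        fh.write("set_id\tvariant_id\tpip\tattained_coverage\tcomplete\n")
        for set_id, cs in enumerate(result.credible_sets, start=1):
            for i in cs.variants:
                fh.write(
                    f"cs{set_id}\t{result.variant_ids[i]}\t"
                    f"{_FLOAT_FMT % result.pip[i]}\t{_FLOAT_FMT % cs.attained}\t"
                    f"{int(cs.complete)}\n"
                )


def read_pip_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a PIP table written by :func:`write_pip_table`."""
    return read_zscores(path)  # same 2-column shape; clipping never triggers


def read_credible_sets(path: str | Path) -> list[list[str]]:
    """Credible sets as lists of variant ids, grouped by set_id."""
    groups: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("set_id"):
                continue
            parts = line.split("\t")
            groups.setdefault(parts[0], []).append(parts[1])
    return list(groups.values())


def write_plink_raw(path: str | Path, raw_genotypes: np.ndarray,
                    phenotype: np.ndarray, variant_ids: Iterable[str]) -> None:
    """PLINK-style .raw text export (FID IID PAT MAT SEX PHENOTYPE dosages)."""
    ids = list(variant_ids)
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(ids) + "\n")
        for i, (row, y) in enumerate(zip(raw_genotypes, phenotype), start=1):
            dosages = " ".join(str(int(g)) for g in row)
            fh.write(f"F{i} I{i} 0 0 0 {_FLOAT_FMT % y} {dosages}\n")
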