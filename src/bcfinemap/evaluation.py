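"""Evaluation metrics for fine-mapping output.

PIP quality is scored by the area under the precision-recall curve
(AUPRC), computed by exact step-function integration over the distinct
PIP thresholds with tied scores grouped into a single step. Credible
sets are scored by coverage (fraction of sets containing a causal
variant), power (fraction of causal variants captured by the union of
sets), and mean set size. A power-versus-FDR curve gives the threshold
sweep view of the same confusion counts.

A small grid runner repeats simulate -> fit -> score over a design grid
and aggregates replicate means with normal-approximation confidence
intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "auprc",
    "credible_set_metrics",
    "power_fdr_curve",
    "CredibleSetMetrics",
    "run_grid",
    "summarize_grid",
    "plot_grid_summary",
]


def _check_scores(pip: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pip = np.asarray(pip, dtype=float).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    if pip.shape != truth.shape:
        raise ValueError("pip and truth must have the same length")
    if not truth.any():
        raise ValueError("truth contains no positives")
    return pip, truth


def _pr_steps(pip: np.ndarray, truth: np.ndarray):
    """Cumulative TP/FP at each distinct threshold, descending."""
    order = np.argsort(-pip, kind="stable")
    sorted_scores = pip[order]
    tp = np.cumsum(truth[order])
    fp = np.cumsum(~truth[order])
    # keep only the last element of each tied-score run
    last = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    return sorted_scores[last], tp[last], fp[last], int(truth.sum())


def auprc(pip: np.ndarray, truth: np.ndarray) -> float:
    """Exact area under the precision-recall curve of a PIP ranking.

    Step integration sum_k (R_k - R_{k-1}) * P_k over the distinct
    thresholds; grouping ties into one step avoids optimistic linear
    interpolation across them.
    """
    pip, truth = _check_scores(pip, truth)
    _, tp, fp, n_pos = _pr_steps(pip, truth)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def power_fdr_curve(pip: np.ndarray, truth: np.ndarray) -> list[tuple[float, float]]:
    """(FDR, power) at every distinct PIP threshold, descending.

    FDR = 1 - precision and power = recall among variants called at or
    above the threshold.
    """
    pip, truth = _check_scores(pip, truth)
    _, tp, fp, n_pos = _pr_steps(pip, truth)
    fdr = fp / (tp + fp)
    power = tp / n_pos
    return list(zip(fdr.tolist(), power.tolist()))


@dataclass(frozen=True)
class CredibleSetMetrics:
    coverage: float  # NaN when no sets were produced
    power: float
    mean_size: float  # NaN when no sets were produced


def credible_set_metrics(
    sets: Iterable[Sequence[int]], truth_causal: Iterable[int], m: int | None = None
) -> CredibleSetMetrics:
    """Coverage, power, and mean size of a collection of credible sets.

    ``sets`` may be any iterable of index collections (including
    :class:`bcfinemap.posterior.CredibleSet` objects). With no sets,
    power is 0 and coverage/mean size are reported as NaN (missing).
    """
    causal = set(int(i) for i in truth_causal)
    set_list = [set(int(i) for i in getattr(s, "variants", s)) for s in sets]
    if not set_list:
        return CredibleSetMetrics(coverage=math.nan, power=0.0, mean_size=math.nan)
    n_hit = sum(1 for s in set_list if s & causal)
    union = set().union(*set_list)
    power = len(union & causal) / len(causal) if causal else 0.0
    mean_size = float(np.mean([len(s) for s in set_list]))
    return CredibleSetMetrics(
        coverage=n_hit / len(set_list), power=power, mean_size=mean_size
    )


# ---------------------------------------------------------------------------
# grid runner


def run_grid(
    d_values: Sequence[int] = (1, 4, 8, 12),
    omega2_values: Sequence[float] = (0.1, 0.2, 0.4, 0.5, 0.7, 0.8),
    share_values: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    n_replicates: int = 20,
    *,
    sim_kwargs: dict | None = None,
    mapper_kwargs: dict | None = None,
    base_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Sweep (d, omega2, share) x replicates; one tidy row per run.

    Every axis is overridable, so desk-scale subsets of the full design
    run in minutes. Each replicate gets a distinct deterministic seed
    derived from ``base_seed``.
    """
    from .estimator import FineMapper
    from .simulate import SimulationConfig, simulate_study

    sim_kwargs = dict(sim_kwargs or {})
    mapper_kwargs = dict(mapper_kwargs or {})
    rows = []
    run = 0
    for d in d_values:
        for w2 in omega2_values:
            for share in share_values:
                for rep in range(n_replicates):
                    seed = (base_seed + 7919 * run) % (2**31 - 1)
                    run += 1
                    cfg = SimulationConfig(
                        d=d, omega2=w2, causal_var_share=share, seed=seed,
                        **sim_kwargs,
                    )
                    study = simulate_study(cfg)
                    mapper = FineMapper(seed=seed, **mapper_kwargs).fit(study.stats)
                    cs = credible_set_metrics(
                        mapper.credible_sets_, study.causal_indices, cfg.m
                    )
                    rows.append(
                        {
                            "d": d,
                            "omega2": w2,
                            "share": share,
                            "replicate": rep,
                            "seed": seed,
                            "auprc": auprc(mapper.pip_, study.truth),
                            "coverage": cs.coverage,
                            "power": cs.power,
                            "mean_set_size": cs.mean_size,
                            "n_sets": len(mapper.credible_sets_),
                            "top_hit": int(
                                int(np.argmax(mapper.pip_)) in set(study.causal_indices.tolist())
                            ),
                        }
                    )
                    if progress:
                        print(f"run {run}: d={d} omega2={w2} share={share} rep={rep}")
    return pd.DataFrame(rows)


def summarize_grid(
    results: pd.DataFrame,
    by: str,
    metrics: Sequence[str] = ("auprc", "coverage", "power", "mean_set_size"),
    ci: str = "normal",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and 95% CI of each metric per level of the swept axis ``by``.

    ``ci="normal"`` uses mean +/- 1.96 * se across configurations;
    ``ci="bootstrap"`` resamples configurations.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for level, group in results.groupby(by):
        row = {by: level, "n": len(group)}
        for metric in metrics:
            vals = group[metric].dropna().to_numpy()
            mean = float(np.mean(vals)) if vals.size else math.nan
            if vals.size > 1:
                if ci == "bootstrap":
                    boots = np.array([
                        np.mean(rng.choice(vals, size=vals.size, replace=True))
                        for _ in range(n_boot)
                    ])
                    lo, hi = np.percentile(boots, [2.5, 97.5])
                else:
                    half = 1.96 * float(np.std(vals, ddof=1)) / np.sqrt(vals.size)
                    lo, hi = mean - half, mean + half
            else:
                lo = hi = mean
            row[metric] = mean
            row[f"{metric}_lo"] = float(lo)
            row[f"{metric}_hi"] = float(hi)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(by).reset_index(drop=True)


def plot_grid_summary(summary: pd.DataFrame, by: str, out_path: str,
                      metrics: Sequence[str] = ("auprc", "coverage", "power", "mean_set_size")):
    """Panel of metric-vs-axis curves with 95% CI error bars (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2))
    if len(metrics) == 1:
        axes = [axes]
    x = summary[by].to_numpy()
    for ax, metric in zip(axes, metrics):
        y = summary[metric].to_numpy()
        err = np.vstack([
            y - summary[f"{metric}_lo"].to_numpy(),
            summary[f"{metric}_hi"].to_numpy() - y,
        ])
        ax.errorbar(x, y, yerr=err, marker="o", capsize=3)
        ax.set_xlabel(by)
        ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
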