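"""Evaluation of SNP rankings against a known causal set.

Covers the standard benchmark machinery: true positives among the top k of a
ranking, TP curves averaged over phenotype replicates, median/IQR summaries
of selected-model sizes, and per-SNP recovery-frequency matrices (how often
each causal SNP lands in the top K across replicates).  The reference point
throughout is the hypergeometric baseline: a random ordering recovers
k * |truth| / d causal SNPs among its top k in expectation.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "true_positives_at_k",
    "tp_curve",
    "model_size_summary",
    "recovery_frequency",
    "random_rankings",
    "hypergeometric_expectation",
    "plot_tp_curves",
    "plot_recovery_heatmap",
]


def true_positives_at_k(ranking: Sequence, truth: set, k: int) -> int:
    """Count causal SNPs among the first k entries of a ranking."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(ranking):
        raise ValueError(f"k = {k} exceeds the ranking length {len(ranking)}")
    return sum(1 for s in ranking[:k] if s in truth)


def tp_curve(rankings: Iterable[Sequence], truth: set, k_grid=None) -> pd.Series:
    """Mean true positives at each k over replicate rankings.

    ``k_grid`` defaults to 1..200 (capped at the ranking length).
    """
    rankings = list(rankings)
    if not rankings:
        raise ValueError("need at least one ranking")
    dmax = min(len(r) for r in rankings)
    if k_grid is None:
        k_grid = np.arange(1, min(200, dmax) + 1)
    k_grid = np.asarray(k_grid, dtype=int)
    means = np.zeros(k_grid.size)
    for ranking in rankings:
        hits = np.fromiter((s in truth for s in ranking), count=len(ranking), dtype=bool)
        cum = np.concatenate(([0], np.cumsum(hits)))
        means += cum[k_grid]
    return pd.Series(means / len(rankings), index=pd.Index(k_grid, name="k"), name="mean_tp")


def model_size_summary(sizes: Sequence[int]) -> tuple[float, float]:
    """Median and interquartile range of selected-model sizes.

    Quartiles use linear interpolation (numpy default, R type 7).
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    if sizes.size < 1:
        raise ValueError("need at least one model size")
    q1, med, q3 = np.percentile(sizes, [25, 50, 75])
    return float(med), float(q3 - q1)


def recovery_frequency(
    rankings_by_method: dict[str, Iterable[Sequence]], truth: set, k: int = 100
) -> pd.DataFrame:
    """Per-causal-SNP counts of appearances in the top k, per method.

    ``rankings_by_method`` maps a method name to its B replicate rankings.
    Rows are the causal SNPs, ordered by decreasing count in the first
    method's column (heatmap convention); counts are bounded by B.
    """
    truth_ids = sorted(truth, key=str)
    counts = {}
    for method, rankings in rankings_by_method.items():
        col = dict.fromkeys(truth_ids, 0)
        for ranking in rankings:
            if k > len(ranking):
                raise ValueError(f"k = {k} exceeds a ranking of length {len(ranking)}")
            for s in ranking[:k]:
                if s in truth:
                    col[s] += 1
        counts[method] = col
    frame = pd.DataFrame(counts, index=pd.Index(truth_ids, name="snp_id"))
    first = frame.columns[0]
    return frame.sort_values(first, ascending=False, kind="stable")


def random_rankings(
    snp_ids: Sequence, b: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """B independent uniform-random orderings (the RND baseline)."""
    ids = np.asarray(snp_ids)
    return [rng.permutation(ids) for _ in range(b)]


def hypergeometric_expectation(k, n_truth: int, d: int):
    """Expected top-k overlap of a random ranking with the causal set."""
    return np.asarray(k, dtype=np.float64) * n_truth / d


def plot_tp_curves(curves: dict[str, pd.Series], path=None, ax=None):
    """TP-vs-k curves for several methods on one axis."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.plot(curve.index, curve.values, label=name)
    ax.set_xlabel("top k SNPs")
    ax.set_ylabel("mean true positives")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_recovery_heatmap(frame: pd.DataFrame, path=None, ax=None):
    """Heatmap of recovery counts (causal SNPs x methods)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, max(3, 0.15 * frame.shape[0])))
    im = ax.imshow(frame.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=45, ha="right")
    ax.set_yticks(range(frame.shape[0]), frame.index, fontsize=5)
    ax.figure.colorbar(im, ax=ax, label="replicates in top K")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
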