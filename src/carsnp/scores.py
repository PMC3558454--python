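"""Marginal and correlation-adjusted association statistics.

For a metric phenotype the marginal statistic is the vector of Pearson
correlations r_XY between each SNP and the response; for a binary phenotype it
is the two-sample t-score vector tau.  Both ignore linkage between SNPs.  The
correlation-adjusted versions decorrelate the statistic with the inverse
matrix square root of the shrunk SNP-SNP correlation matrix:

    CAR = R^{-1/2} r_XY        (metric)
    CAT = R^{-1/2} tau         (binary)

Squared CAR scores sum to the estimated coefficient of determination R^2, and
squared CAT scores to Hotelling's T^2, so either vector doubles as an additive
variable-importance decomposition over SNPs or SNP groups.  The adjustment is
evaluated through the matrix-free low-rank identity in :mod:`carsnp.core`,
never through a d x d matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_RANK_TOL,
    SpectralShrinkage,
    StandardizedMatrix,
    apply_matrix_power,
    spectral_decompose,
    standardize_columns,
)

__all__ = [
    "ScoreTable",
    "ImportanceDecomposition",
    "marginal_correlations",
    "t_scores",
    "car_scores",
    "cat_scores",
    "importance_decomposition",
]

_STD_TOL = 1e-8


@dataclass(frozen=True)
class ScoreTable:
    """Per-SNP marginal and correlation-adjusted statistics.

    ``rank`` orders SNPs by decreasing |adjusted|, ties broken by ascending
    snp_id; ``df`` carries the t-score degrees of freedom for binary scores
    (needed to map t-scores onto the correlation scale for FDR fitting).
    """

    snp_ids: np.ndarray
    marginal: np.ndarray
    adjusted: np.ndarray
    kind: str  # "metric" | "binary"
    lam: float
    df: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", np.asarray(self.snp_ids))
        object.__setattr__(self, "marginal", np.asarray(self.marginal, dtype=np.float64))
        object.__setattr__(self, "adjusted", np.asarray(self.adjusted, dtype=np.float64))
        if self.kind not in ("metric", "binary"):
            raise ValueError(f"kind must be 'metric' or 'binary', got {self.kind!r}")
        if not (self.snp_ids.shape == self.marginal.shape == self.adjusted.shape):
            raise ValueError("snp_ids, marginal and adjusted must have equal length")

    @property
    def d(self) -> int:
        return self.snp_ids.size

    @property
    def squared_importance(self) -> np.ndarray:
        return self.adjusted**2

    @property
    def rank(self) -> np.ndarray:
        """Permutation of 1..d: rank 1 is the largest |adjusted| score."""
        order = np.lexsort((self.snp_ids.astype(str), -np.abs(self.adjusted)))
        ranks = np.empty(self.d, dtype=np.int64)
        ranks[order] = np.arange(1, self.d + 1)
        return ranks

    def ranking(self) -> np.ndarray:
        """SNP ids ordered from strongest to weakest |adjusted| score."""
        order = np.lexsort((self.snp_ids.astype(str), -np.abs(self.adjusted)))
        return self.snp_ids[order]

    @property
    def total_importance(self) -> float:
        """Sum of squared adjusted scores: R^2 (metric) or T^2 (binary)."""
        return float(np.sum(self.squared_importance))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "marginal": self.marginal,
                "adjusted": self.adjusted,
                "squared_importance": self.squared_importance,
                "rank": self.rank,
            }
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n# lambda={self.lam!r}\n")
            if self.df is not None:
                fh.write(f"# df={self.df}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScoreTable":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            frame = pd.read_csv(fh, sep="\t")
        df = int(meta["df"]) if "df" in meta else None
        return cls(
            snp_ids=frame["snp_id"].to_numpy(),
            marginal=frame["marginal"].to_numpy(),
            adjusted=frame["adjusted"].to_numpy(),
            kind=meta.get("kind", "metric"),
            lam=float(meta.get("lambda", "nan")),
            df=df,
        )


@dataclass(frozen=True)
class ImportanceDecomposition:
    """Additive split of total importance (R^2 or T^2) over SNPs and groups."""

    total: float
    per_snp: pd.Series
    per_group: pd.Series


def _check_standardized(y: np.ndarray, what: str = "response") -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError(f"{what} must be a vector")
    if abs(y.mean()) > _STD_TOL or abs(y.var(ddof=1) - 1.0) > _STD_TOL:
        raise ValueError(
            f"{what} must be standardized to mean 0 and unit sample variance"
        )
    return y


def marginal_correlations(x: StandardizedMatrix, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each standardized column with a standardized y.

    On standardized data this is simply ``X^T y / (n - 1)``; results are
    clipped into [-1, 1] to absorb last-digit rounding.
    """
    y = _check_standardized(y)
    if y.size != x.n:
        raise ValueError(f"response has length {y.size}, expected n = {x.n}")
    return np.clip(x.values.T @ y / (x.n - 1), -1.0, 1.0)


def t_scores(x_raw: np.ndarray, y) -> np.ndarray:
    """Two-sample t statistic per column with pooled within-group variance.

    Groups are the two sorted unique labels of ``y`` (first minus second in
    the numerator).  A column whose pooled variance is zero gets statistic 0
    and a warning rather than an error, mirroring how a monomorphic-within-
    groups SNP carries no two-sample evidence.
    """
    x_raw = np.asarray(x_raw, dtype=np.float64)
    y = np.asarray(y)
    levels = np.unique(y)
    if levels.size != 2:
        raise ValueError(f"binary response required, found {levels.size} level(s)")
    g1 = x_raw[y == levels[0]]
    g2 = x_raw[y == levels[1]]
    n1, n2 = g1.shape[0], g2.shape[0]
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 samples")
    diff = g1.mean(axis=0) - g2.mean(axis=0)
    pooled_var = (
        (n1 - 1) * g1.var(axis=0, ddof=1) + (n2 - 1) * g2.var(axis=0, ddof=1)
    ) / (n1 + n2 - 2)
    scale = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    tau = np.zeros(x_raw.shape[1])
    ok = scale > 0
    if not ok.all():
        warnings.warn(
            f"{np.count_nonzero(~ok)} column(s) with zero pooled variance; "
            "their t-scores are set to 0",
            stacklevel=2,
        )
    tau[ok] = diff[ok] / scale[ok]
    return tau


def car_scores(
    x: StandardizedMatrix,
    y: np.ndarray,
    lam: float = 0.1,
    rank_tol: float = DEFAULT_RANK_TOL,
    decomposition: SpectralShrinkage | None = None,
) -> ScoreTable:
    """Correlation-adjusted marginal correlations for a metric response.

    Computes ``R^{-1/2} r_XY`` through the matrix-free identity.  A
    precomputed spectral decomposition may be passed when many phenotype
    replicates share one genotype matrix.
    """
    marginal = marginal_correlations(x, y)
    s = decomposition if decomposition is not None else spectral_decompose(x, lam, rank_tol)
    if s.lam != lam:
        raise ValueError("decomposition was built with a different lambda")
    adjusted = apply_matrix_power(s, -0.5, marginal)
    return ScoreTable(x.column_ids, marginal, adjusted, kind="metric", lam=lam)


def cat_scores(
    x_raw: np.ndarray,
    y,
    lam: float = 0.1,
    snp_ids=None,
    rank_tol: float = DEFAULT_RANK_TOL,
) -> ScoreTable:
    """Correlation-adjusted t-scores for a binary response.

    The SNP-SNP correlation matrix is estimated from the pooled sample
    (columns standardized over all samples); ``R^{-1/2} tau`` is evaluated
    matrix-free as for CAR scores.
    """
    tau = t_scores(x_raw, y)
    x = standardize_columns(x_raw, snp_ids)
    s = spectral_decompose(x, lam, rank_tol)
    adjusted = apply_matrix_power(s, -0.5, tau)
    n = np.asarray(x_raw).shape[0]
    return ScoreTable(x.column_ids, tau, adjusted, kind="binary", lam=lam, df=n - 2)


def importance_decomposition(scores: ScoreTable, groups=None) -> ImportanceDecomposition:
    """Split the total importance additively over SNPs and SNP groups.

    ``groups`` maps snp_id -> group id (e.g. gene); SNPs without an entry fall
    into the group ``"ungrouped"``.
    """
    per_snp = pd.Series(scores.squared_importance, index=scores.snp_ids)
    if groups is None:
        groups = {}
    labels = pd.Series(
        [groups.get(snp, "ungrouped") for snp in scores.snp_ids], index=per_snp.index
    )
    per_group = per_snp.groupby(labels).sum()
    return ImportanceDecomposition(
        total=float(per_snp.sum()), per_snp=per_snp, per_group=per_group
    )
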