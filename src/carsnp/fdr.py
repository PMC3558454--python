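"""Local false discovery rate model selection for score vectors.

CAR scores are correlations, so the null component of the score distribution
is modelled by the exact null density of an empirical correlation coefficient,

    f0(r; kappa) = (1 - r^2)^((kappa - 3)/2) / B(1/2, (kappa - 1)/2),

parametrized by an effective sample size kappa > 3 (equivalently
r^2 ~ Beta(1/2, (kappa - 1)/2)).  kappa is fitted by maximum likelihood on the
scores with |r| below their 75th percentile, treated as a truncated null
sample, and the null proportion pi0 follows by comparing the truncated count
with the fitted null mass.

The observed density enters through its monotone (Grenander) estimate on the
null p-value scale: p = P0(|R| >= |r|; kappa) is uniform under the null and
has a decreasing density under the alternative, so

    lfdr(r) = min(1, pi0 / f_hat(p(r)))

with f_hat the Grenander (least-concave-majorant) density of the p-values.
Because f_hat is a non-increasing step function of p, the lfdr is
automatically non-increasing in |r|, and at r = 0 (p = 1) it equals 1 whenever
pi0 = 1.  Selection keeps SNPs with lfdr below a cutoff, 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.isotonic import IsotonicRegression

from .scores import ScoreTable

__all__ = [
    "SelectionResult",
    "null_pdf",
    "null_cdf_folded",
    "sample_null",
    "fit_null_correlation",
    "local_fdr",
    "select_by_lfdr",
]

_TRUNC_QUANTILE = 0.75
# search window for log(kappa - 3); upper end covers near-degenerate scores
_LOG_KM3_BOUNDS = (-10.0, 35.0)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of lfdr thresholding on a score vector."""

    snp_ids: np.ndarray
    scores: np.ndarray  # adjusted scores on the correlation scale
    lfdr: np.ndarray
    kappa: float
    pi0: float
    cutoff: float

    @property
    def selected(self) -> np.ndarray:
        return self.snp_ids[self.lfdr < self.cutoff]

    @property
    def model_size(self) -> int:
        return int(np.count_nonzero(self.lfdr < self.cutoff))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "adjusted_score": self.scores,
                "lfdr": self.lfdr,
                "selected": (self.lfdr < self.cutoff).astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# kappa={self.kappa!r}\n# pi0={self.pi0!r}\n"
                f"# cutoff={self.cutoff!r}\n# model_size={self.model_size}\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)


def null_pdf(r, kappa: float):
    """Density of an empirical correlation under the null, effective size kappa."""
    r = np.asarray(r, dtype=np.float64)
    log_norm = special.betaln(0.5, (kappa - 1.0) / 2.0)
    return np.exp((kappa - 3.0) / 2.0 * np.log1p(-(r**2)) - log_norm)


def null_cdf_folded(q, kappa: float):
    """P0(|R| <= q; kappa) via the Beta(1/2, (kappa-1)/2) law of R^2."""
    q = np.asarray(q, dtype=np.float64)
    return special.betainc(0.5, (kappa - 1.0) / 2.0, q**2)


def sample_null(kappa: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw correlations from f0(r; kappa): signed square roots of a Beta law."""
    r2 = rng.beta(0.5, (kappa - 1.0) / 2.0, size=size)
    return np.sqrt(r2) * rng.choice([-1.0, 1.0], size=size)


def fit_null_correlation(scores: np.ndarray) -> tuple[float, float]:
    """Fit (kappa, pi0) of the null component of a score vector.

    Scores with |r| at or below their 75th percentile are treated as a sample
    from the null density truncated to that interval; kappa maximizes the
    truncated likelihood and pi0 = min(1, truncated count / (d * null mass)).

    Raises
    ------
    ValueError
        If all scores are identical, scores fall outside (-1, 1), or the
        fitted null is too heavy-tailed (kappa <= 3).
    """
    r = np.asarray(scores, dtype=np.float64)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("need a vector of at least 2 scores")
    if np.abs(r).max() >= 1.0:
        raise ValueError("scores must lie strictly inside (-1, 1)")
    if np.ptp(r) == 0.0:
        raise ValueError("all scores identical; null model cannot be fitted")
    a = np.abs(r)
    q = float(np.quantile(a, _TRUNC_QUANTILE))
    if q == 0.0:
        raise ValueError("more than 75% of scores are exactly zero")
    sub = a[a <= q]
    log1m_r2 = np.log1p(-(sub**2))
    sum_log = float(log1m_r2.sum())
    k = sub.size

    def nll(s: float) -> float:
        kappa = 3.0 + np.exp(s)
        b = (kappa - 1.0) / 2.0
        mass = special.betainc(0.5, b, q * q)
        if mass <= 0.0:
            return np.inf
        return -(
            (kappa - 3.0) / 2.0 * sum_log
            - k * special.betaln(0.5, b)
            - k * np.log(mass)
        )

    res = optimize.minimize_scalar(nll, bounds=_LOG_KM3_BOUNDS, method="bounded")
    s_hat = float(res.x)
    if s_hat <= _LOG_KM3_BOUNDS[0] + 1e-6:
        raise ValueError("null too heavy: fitted kappa <= 3")
    kappa = 3.0 + float(np.exp(s_hat))
    mass = float(special.betainc(0.5, (kappa - 1.0) / 2.0, q * q))
    pi0 = min(1.0, k / (r.size * mass))
    return kappa, pi0


def _grenander_pvalue_density(p: np.ndarray) -> np.ndarray:
    """Grenander estimate of a decreasing density on [0, 1], at the data points.

    The estimate is the left derivative of the least concave majorant of the
    empirical CDF with knots forced at 0 and 1; it is computed as the weighted
    antitonic regression of the empirical slopes (gap weights), which is the
    classical pool-adjacent-violators form of the estimator.
    """
    n = p.size
    xs, counts = np.unique(p, return_counts=True)
    fvals = np.cumsum(counts) / n
    if xs[0] == 0.0:
        # a point mass at 0 has no width; fold it into the first positive gap
        xs, fvals = xs[1:], fvals[1:]
    if xs.size == 0:
        # every p-value is exactly zero: uniform mass on a degenerate support
        xs, fvals = np.array([1.0]), np.array([1.0])
    x_knots = np.concatenate(([0.0], xs))
    f_knots = np.concatenate(([0.0], fvals))
    if x_knots[-1] < 1.0:
        x_knots = np.concatenate((x_knots, [1.0]))
        f_knots = np.concatenate((f_knots, [1.0]))
    else:
        f_knots[-1] = 1.0
    gaps = np.diff(x_knots)
    raw = np.diff(f_knots) / gaps
    iso = IsotonicRegression(increasing=False)
    slopes = iso.fit_transform(np.arange(raw.size), raw, sample_weight=gaps)
    # density at each observed p: slope of the interval (x_{i-1}, x_i]
    idx = np.searchsorted(x_knots[1:], p, side="left")
    idx = np.minimum(idx, slopes.size - 1)
    return slopes[idx]


def local_fdr(scores: np.ndarray, kappa: float, pi0: float) -> np.ndarray:
    """Per-score local FDR under the fitted two-group model.

    Equivalent to min(1, pi0 * folded-null / Grenander observed density) on
    the |r| scale; evaluated on the p-value scale where the null is uniform.
    Scores where the observed density estimate vanishes get lfdr 1.
    """
    r = np.abs(np.asarray(scores, dtype=np.float64))
    if np.any(r >= 1.0):
        raise ValueError("scores must lie strictly inside (-1, 1)")
    p = special.betaincc(0.5, (kappa - 1.0) / 2.0, r**2)
    f_hat = _grenander_pvalue_density(p)
    lfdr = np.ones_like(r)
    pos = f_hat > 0
    lfdr[pos] = np.minimum(1.0, pi0 / f_hat[pos])
    return lfdr


def _to_correlation_scale(table: ScoreTable) -> np.ndarray:
    """Adjusted scores on the correlation scale; CAT scores map through
    r = t / sqrt(t^2 + df)."""
    adj = table.adjusted
    if table.kind == "binary":
        if table.df is None:
            raise ValueError("binary score table lacks degrees of freedom")
        adj = adj / np.sqrt(adj**2 + table.df)
    # adjusted CAR scores can exceed 1 in magnitude by the lambda^{-1/2}
    # factor; fold such overwhelming signals just inside the open interval
    return np.clip(adj, -1.0 + 1e-12, 1.0 - 1e-12)


def select_by_lfdr(scores: ScoreTable, cutoff: float = 0.5) -> SelectionResult:
    """Threshold a score table at a local FDR cutoff (0.5 by default).

    Fits the null (kappa, pi0), computes per-SNP lfdr values and keeps SNPs
    with lfdr strictly below the cutoff.  Deterministic given the scores.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    r = _to_correlation_scale(scores)
    kappa, pi0 = fit_null_correlation(r)
    lfdr = local_fdr(r, kappa, pi0)
    return SelectionResult(
        snp_ids=scores.snp_ids,
        scores=r,
        lfdr=lfdr,
        kappa=kappa,
        pi0=pi0,
        cutoff=cutoff,
    )
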