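"""Shrinkage correlation engine.

High-dimensional association scoring needs powers of the shrunk correlation
matrix ``R = lambda * I + (1 - lambda) * R_empirical`` for d predictors, with
d often far larger than the sample size n.  Because the empirical correlation
matrix of n samples has rank m <= n - 1, R can be written

    R = lambda * (I_d + U diag(M) U^T)

with U a d x m matrix of orthonormal columns (right singular vectors of the
standardized data) and M a positive diagonal.  Any matrix power then follows
from the identity

    R^alpha = lambda^alpha * (I_d - U (I_m - (I_m + diag(M))^alpha) U^T),

so ``R^alpha v`` costs O(d * m) and never touches a d x d array.  This module
implements that representation plus a dense brute-force counterpart used as a
test oracle, and the analytic (Schaefer-Strimmer) estimator of the shrinkage
intensity lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StandardizedMatrix",
    "SpectralShrinkage",
    "standardize_columns",
    "spectral_decompose",
    "apply_matrix_power",
    "dense_shrunk_power",
    "estimate_lambda",
]

#: relative singular-value threshold below which components are treated as rank-deficient
DEFAULT_RANK_TOL = 1e-9

#: guard for the dense oracle; above this, only the matrix-free path is sensible
_DENSE_GUARD = 500


@dataclass(frozen=True)
class StandardizedMatrix:
    """Column-standardized predictor matrix (mean 0, sample variance 1, ddof=1).

    Attributes
    ----------
    values : ndarray, shape (n, d)
        The standardized data.
    column_ids : ndarray of str
        Predictor (SNP) identifiers, one per column.
    """

    values: np.ndarray
    column_ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("expected a 2-d matrix of samples x predictors")
        n, d = values.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if d < 1:
            raise ValueError("need at least one predictor column")
        if np.isnan(values).any():
            raise ValueError("standardized matrix contains missing values")
        ids = np.asarray(self.column_ids)
        if ids.shape != (d,):
            raise ValueError(f"column_ids has length {ids.size}, expected {d}")
        object.__setattr__(self, "column_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SpectralShrinkage:
    """Rank-m representation R = lambda * (I + U diag(m_diag) U^T).

    Attributes
    ----------
    u : ndarray, shape (d, m)
        Orthonormal columns (right singular vectors of the standardized data).
    m_diag : ndarray, shape (m,)
        Strictly positive diagonal of M; equals ((1 - lambda)/lambda) * Lambda_i
        where Lambda_i are the nonzero eigenvalues of the empirical correlation.
    lam : float
        Shrinkage intensity in (0, 1].
    n : int
        Sample count the decomposition was computed from.
    """

    u: np.ndarray
    m_diag: np.ndarray
    lam: float
    n: int

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=np.float64)
        m_diag = np.asarray(self.m_diag, dtype=np.float64)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "m_diag", m_diag)
        if not (0.0 < self.lam <= 1.0):
            raise ValueError(f"shrinkage intensity must lie in (0, 1], got {self.lam}")
        if u.ndim != 2 or m_diag.ndim != 1 or u.shape[1] != m_diag.size:
            raise ValueError("inconsistent shapes for U and M diagonal")
        if m_diag.size and m_diag.min() <= 0:
            raise ValueError("M diagonal must be strictly positive")

    @property
    def d(self) -> int:
        return self.u.shape[0]

    @property
    def m(self) -> int:
        return self.u.shape[1]


def standardize_columns(raw: np.ndarray, column_ids=None) -> StandardizedMatrix:
    """Center each column and scale to unit sample variance (ddof=1).

    Parameters
    ----------
    raw : array-like, shape (n, d)
        Numeric matrix; no missing values allowed.
    column_ids : sequence of str, optional
        Predictor identifiers; defaults to ``c0001``-style labels.

    Raises
    ------
    ValueError
        If n < 3, values are missing, or a column has zero variance (the error
        names the offending column).
    """
    x = np.array(raw, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("expected a 2-d matrix of samples x predictors")
    n, d = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples to standardize, got {n}")
    if column_ids is None:
        width = max(4, len(str(d)))
        column_ids = np.array([f"c{i:0{width}d}" for i in range(1, d + 1)])
    else:
        column_ids = np.asarray(column_ids)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; complete genotypes are required")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        names = ", ".join(str(column_ids[j]) for j in zero[:10])
        raise ValueError(f"zero variance column(s): {names}")
    return StandardizedMatrix((x - mean) / sd, column_ids)


def spectral_decompose(
    x: StandardizedMatrix, lam: float, rank_tol: float = DEFAULT_RANK_TOL
) -> SpectralShrinkage:
    """Build the rank-m representation of R = lam*I + (1-lam)*R_empirical.

    A thin SVD of the standardized data ``X = V diag(sigma) U^T`` gives the
    eigenvalues of the empirical correlation as ``Lambda_i = sigma_i^2/(n-1)``
    and its eigenvectors as the right singular vectors.  Components with
    ``sigma_i <= rank_tol * sigma_max`` are dropped (numerical rank).  With
    lam = 1 the result may legitimately have m = 0 (R is the identity).
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"shrinkage intensity must lie in (0, 1], got {lam}")
    values = x.values
    if values.size == 0:
        raise ValueError("empty matrix")
    if lam == 1.0:
        return SpectralShrinkage(
            np.empty((x.d, 0)), np.empty(0), lam=1.0, n=x.n
        )
    # thin SVD: only min(n, d) components ever materialize
    _, sigma, vt = np.linalg.svd(values, full_matrices=False)
    keep = sigma > rank_tol * sigma[0]
    sigma = sigma[keep]
    eigvals = sigma**2 / (x.n - 1)
    m_diag = ((1.0 - lam) / lam) * eigvals
    return SpectralShrinkage(vt[keep].T.copy(), m_diag, lam=lam, n=x.n)


def apply_matrix_power(s: SpectralShrinkage, alpha: float, v: np.ndarray) -> np.ndarray:
    """Return ``R^alpha @ v`` without forming any d x d array.

    Uses R^alpha = lam^alpha * (I - U (I - (I + M)^alpha) U^T); the largest
    intermediate is d x m.  ``alpha = 0`` and the lam = 1 (m = 0) case return
    v unchanged, exactly.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.shape[0] != s.d:
        raise ValueError(f"vector has length {v.shape[0]}, expected d = {s.d}")
    if alpha == 0:
        return v.copy()
    if s.m == 0:
        return (s.lam**alpha) * v
    w = s.u.T @ v                                     # (m,)
    shrunk = (1.0 - (1.0 + s.m_diag) ** alpha) * w    # (m,)
    return (s.lam**alpha) * (v - s.u @ shrunk)


def dense_shrunk_power(x: StandardizedMatrix, lam: float, alpha: float) -> np.ndarray:
    """Brute-force oracle: form R explicitly and take its matrix power.

    Full symmetric eigendecomposition of ``lam*I + (1-lam) * X^T X/(n-1)``;
    refuses d > 500 so a careless call can never allocate a GWAS-sized matrix.
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"shrinkage intensity must lie in (0, 1], got {lam}")
    if x.d > _DENSE_GUARD:
        raise ValueError(
            f"d = {x.d} exceeds the dense guard ({_DENSE_GUARD}); "
            "use apply_matrix_power for large problems"
        )
    r_emp = x.values.T @ x.values / (x.n - 1)
    r = lam * np.eye(x.d) + (1.0 - lam) * r_emp
    eigval, eigvec = np.linalg.eigh(r)
    return (eigvec * eigval**alpha) @ eigvec.T


def estimate_lambda(x: StandardizedMatrix) -> float:
    """Analytic variance-minimizing shrinkage intensity (Schaefer-Strimmer).

    lambda* = sum_{i != j} Var-hat(r_ij) / sum_{i != j} r_ij^2, clipped to
    [0, 1], with Var-hat(r_ij) = n/(n-1)^3 * sum_k (w_kij - w-bar_ij)^2 for the
    cross products w_kij = x_ki * x_kj of the standardized data.  Both sums are
    rearranged through the n x n Gram matrix X X^T, so no d x d array is formed.
    """
    if x.d < 2:
        raise ValueError("need at least two predictors to estimate lambda")
    values = x.values
    n = x.n
    gram = values @ values.T                       # (n, n)
    frob2 = float(np.sum(gram**2))                 # ||X^T X||_F^2 == ||X X^T||_F^2
    # off-diagonal sum of squared correlations: ||R_emp||_F^2 - d (r_ii == 1)
    denom = frob2 / (n - 1) ** 2 - x.d
    row_sq = values**2
    # sum over all (i, j) incl. diagonal of sum_k (w_kij - w-bar_ij)^2
    s_all = float(np.sum(np.sum(row_sq, axis=1) ** 2)) - frob2 / n
    # diagonal terms i == j: w_kii = x_ki^2 with column sums exactly n - 1
    s_diag = float(np.sum(row_sq**2)) - x.d * (n - 1) ** 2 / n
    num = n / (n - 1) ** 3 * (s_all - s_diag)
    if denom <= 0:
        return 1.0
    return float(np.clip(num / denom, 0.0, 1.0))
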