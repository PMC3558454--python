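"""Model/Results interface over the scoring and selection machinery.

``CarScoreModel`` (metric phenotype) and ``CatScoreModel`` (binary phenotype)
follow the familiar fit-then-results pattern: the model holds the prepared
data and the shrinkage setting, ``fit()`` performs the spectral decomposition
and scoring once, and the returned results object carries the score table,
importance decomposition, lfdr-based selection and a printable summary.

Example
-------
>>> presets = gaw17_like_presets(d=200)
>>> x, ann = simulate_genotypes(presets["Q1like"])          # doctest: +SKIP
>>> y, truth = simulate_phenotype(x, presets["Q1like"], 0)  # doctest: +SKIP
>>> res = CarScoreModel(y.values, x, lam=0.1).fit()         # doctest: +SKIP
>>> res.select().model_size                                 # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    StandardizedMatrix,
    estimate_lambda,
    spectral_decompose,
    standardize_columns,
)
from .fdr import SelectionResult, select_by_lfdr
from .preprocess import PhenotypeVector, residualize_response
from .scores import (
    ImportanceDecomposition,
    ScoreTable,
    car_scores,
    cat_scores,
    importance_decomposition,
    marginal_correlations,
)

__all__ = ["CarScoreModel", "CatScoreModel", "AssociationResults"]


class _BaseScoreModel:
    """Shared constructor plumbing for the two score models."""

    kind: str

    def __init__(self, endog, exog, snp_ids=None, lam: float | str = 0.1, covariates=None):
        if isinstance(endog, PhenotypeVector):
            if covariates is None:
                covariates = endog.covariates
            endog = endog.values
        self.endog_raw = np.asarray(endog, dtype=np.float64)
        self.covariates = covariates
        if isinstance(exog, StandardizedMatrix):
            self.exog = exog
        else:
            if isinstance(exog, pd.DataFrame):
                if snp_ids is None:
                    snp_ids = exog.columns.to_numpy()
                exog = exog.to_numpy()
            self.exog_raw = np.asarray(exog, dtype=np.float64)
            self.exog = standardize_columns(self.exog_raw, snp_ids)
        if not hasattr(self, "exog_raw"):
            self.exog_raw = self.exog.values
        if self.endog_raw.shape[0] != self.exog.n:
            raise ValueError("phenotype and genotype sample counts differ")
        self.lam = lam

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, covariates: list[str] | None = None,
        lam: float | str = 0.1,
    ):
        """Build a model from one DataFrame holding response, covariates and SNPs."""
        drop = [response] + (covariates or [])
        cov = data[covariates].to_numpy() if covariates else None
        snps = data.drop(columns=drop)
        return cls(data[response].to_numpy(), snps, lam=lam, covariates=cov)

    def _resolve_lambda(self) -> float:
        if self.lam == "auto":
            return estimate_lambda(self.exog)
        lam = float(self.lam)
        return lam


class CarScoreModel(_BaseScoreModel):
    """Correlation-adjusted marginal correlation (CAR score) model.

    Parameters
    ----------
    endog : array-like or PhenotypeVector
        Metric phenotype; covariates (if any) are regressed out and the
        residuals standardized before scoring.
    exog : array-like, DataFrame or StandardizedMatrix
        Genotypes (samples x SNPs); standardized internally if raw.
    lam : float in (0, 1] or "auto"
        Shrinkage intensity; "auto" uses the analytic estimator.
    """

    kind = "metric"

    def fit(self) -> "AssociationResults":
        lam = self._resolve_lambda()
        y = residualize_response(
            PhenotypeVector(self.endog_raw, covariates=self.covariates)
        )
        decomposition = spectral_decompose(self.exog, lam)
        table = car_scores(self.exog, y, lam, decomposition=decomposition)
        return AssociationResults(self, table, lam)


class CatScoreModel(_BaseScoreModel):
    """Correlation-adjusted t-score (CAT score) model for a binary phenotype."""

    kind = "binary"

    def __init__(self, endog, exog, snp_ids=None, lam: float | str = 0.1):
        super().__init__(endog, exog, snp_ids=snp_ids, lam=lam)

    def fit(self) -> "AssociationResults":
        lam = self._resolve_lambda()
        table = cat_scores(
            self.exog_raw, self.endog_raw, lam, snp_ids=self.exog.column_ids
        )
        return AssociationResults(self, table, lam)


class AssociationResults:
    """Fitted scores plus selection and reporting helpers."""

    def __init__(self, model: _BaseScoreModel, scores: ScoreTable, lam: float):
        self.model = model
        self.scores = scores
        self.lam = lam

    @property
    def params(self) -> pd.Series:
        """Adjusted (CAR/CAT) scores indexed by SNP id."""
        return pd.Series(self.scores.adjusted, index=self.scores.snp_ids, name="adjusted")

    @property
    def marginal(self) -> pd.Series:
        return pd.Series(self.scores.marginal, index=self.scores.snp_ids, name="marginal")

    @property
    def total_importance(self) -> float:
        """R^2 (metric) or Hotelling's T^2 (binary) explained by all SNPs."""
        return self.scores.total_importance

    def ranking(self) -> np.ndarray:
        return self.scores.ranking()

    def select(self, cutoff: float = 0.5) -> SelectionResult:
        """Local-FDR thresholding of the adjusted scores."""
        return select_by_lfdr(self.scores, cutoff=cutoff)

    def importance(self, groups=None) -> ImportanceDecomposition:
        return importance_decomposition(self.scores, groups)

    def summary(self, top: int = 10) -> str:
        """Text report: settings, total importance, the top-ranked SNPs."""
        frame = self.scores.to_frame().sort_values("rank").head(top)
        label = "R-squared" if self.scores.kind == "metric" else "Hotelling T-squared"
        lines = [
            "Correlation-adjusted association scores",
            "=" * 55,
            f"kind: {self.scores.kind}    n SNPs: {self.scores.d}    lambda: {self.lam:.4g}",
            f"{label}: {self.total_importance:.4f}",
            "-" * 55,
            frame.to_string(index=False, float_format=lambda v: f"{v: .5f}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<AssociationResults kind={self.scores.kind} d={self.scores.d} "
            f"lambda={self.lam:.4g}>"
        )
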