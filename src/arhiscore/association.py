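"""Association of the weighted allele score with hearing status, and
ROC-based assessment of the resulting prediction model.

Two standard model specifications are exposed: Model 1 regresses the
binary ARHI indicator on the score alone; Model 2 additionally adjusts
for a configurable covariate list (demographics, smoking/drinking,
diet/exercise, physical condition in the motivating study design).
Odds ratios carry 95% Wald intervals. The ROC curve is evaluated
in-sample on the fitted probabilities; its AUC is the tie-adjusted
concordance probability and equals the Mann-Whitney U statistic scaled
by the number of case-control pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .allele_score import ScoreResult
from .data import CohortTable
from .logistic import (EffectEstimate, LogisticFit, RankDeficientError,
                       SeparationError, Z_95, fit_logistic)

__all__ = [
    "ModelSpec", "MODEL1", "RocResult", "fit_logistic", "LogisticFit",
    "EffectEstimate", "score_effect", "prediction_model", "roc_auc",
    "build_design", "SeparationError", "RankDeficientError", "Z_95",
]


@dataclass(frozen=True)
class ModelSpec:
    """Named covariate specification for a score-association model.

    ``covariates=None`` means "every covariate column in the cohort
    table" (the usual Model 2); an empty tuple is the unadjusted
    Model 1.
    """

    name: str
    covariates: Optional[tuple[str, ...]] = ()

    def resolve(self, cohort: CohortTable) -> list[str]:
        if self.covariates is None:
            return cohort.covariate_names
        missing = [c for c in self.covariates if c not in cohort.covariate_names]
        if missing:
            raise KeyError(f"{self.name}: covariate(s) {missing} not in cohort "
                           f"table (available: {cohort.covariate_names})")
        return list(self.covariates)


MODEL1 = ModelSpec("model1", covariates=())
MODEL2_ALL = ModelSpec("model2", covariates=None)


@dataclass
class RocResult:
    """ROC curve and area under it."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_cases: int
    n_controls: int

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr,
                             "threshold": self.thresholds})


def build_design(cohort: CohortTable, covariates: Sequence[str],
                 score: Optional[pd.Series] = None) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble a complete-case design matrix from cohort covariates.

    Continuous covariates enter untransformed. Categorical (including
    binary non-numeric) covariates are one-hot encoded with the most
    frequent level as the reference. Subjects missing the score or any
    covariate are dropped (complete-case analysis).

    Returns the design matrix and the aligned 0/1 ARHI outcome.
    """
    parts: list[pd.DataFrame] = []
    if score is not None:
        parts.append(score.rename("score").to_frame())
    for name in covariates:
        col = cohort.table[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            parts.append(col.to_frame())
        elif pd.api.types.is_numeric_dtype(col) and set(col.dropna().unique()) <= {0, 1}:
            parts.append(col.to_frame())
        else:
            reference = col.value_counts().idxmax()
            dummies = pd.get_dummies(col, prefix=name, dtype=float)
            dummies = dummies.drop(columns=f"{name}_{reference}")
            parts.append(dummies)
    X = (pd.concat(parts, axis=1) if parts
         else pd.DataFrame(index=cohort.table.index))
    y = cohort.is_case
    complete = ~X.isna().any(axis=1) if len(X.columns) else pd.Series(
        True, index=X.index)
    return X.loc[complete], y.loc[complete]


def score_effect(score: ScoreResult, cohort: CohortTable,
                 spec: ModelSpec = MODEL1) -> EffectEstimate:
    """Odds ratio per unit of the weighted allele score.

    Fits logistic regression of ARHI on the score (plus the spec's
    covariates) and returns the score term's estimate with a 95% Wald
    interval.
    """
    series = pd.Series(score.score, index=score.subjects).reindex(cohort.subjects)
    X, y = build_design(cohort, spec.resolve(cohort), score=series)
    fit = fit_logistic(X, y)
    return fit.effect("score")


def prediction_model(score: ScoreResult, cohort: CohortTable,
                     spec: ModelSpec = MODEL2_ALL
                     ) -> tuple[LogisticFit, RocResult]:
    """Fit the ARHI prediction model and assess it with an in-sample ROC.

    The model is logistic regression of ARHI on the weighted allele
    score plus the spec's covariates; the ROC is computed on the fitted
    probabilities of the same subjects.
    """
    series = pd.Series(score.score, index=score.subjects).reindex(cohort.subjects)
    X, y = build_design(cohort, spec.resolve(cohort), score=series)
    fit = fit_logistic(X, y)
    return fit, roc_auc(fit.fitted_probs, y.to_numpy())


def roc_auc(predicted: np.ndarray | Sequence[float],
            y: np.ndarray | Sequence[int]) -> RocResult:
    """ROC curve over all distinct thresholds and its area.

    The AUC is the probability that a random case outscores a random
    control, with tied predictions counting 1/2 — numerically identical
    to the trapezoidal area under the full-resolution curve.
    """
    predicted = np.asarray(predicted, dtype=float)
    y = np.asarray(y, dtype=int)
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(f"need both classes for a ROC curve "
                         f"(cases={n_cases}, controls={n_controls})")
    fpr, tpr, thresholds = roc_curve(y, predicted, drop_intermediate=False)
    return RocResult(auc=float(roc_auc_score(y, predicted)), fpr=fpr, tpr=tpr,
                     thresholds=thresholds, n_cases=n_cases,
                     n_controls=n_controls)
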