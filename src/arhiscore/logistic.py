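"""Binary logistic regression with Wald inference.

Thin wrapper around a maximum-likelihood logit fit that adds the rank /
separation / convergence checking the pipeline relies on, and converts
fitted terms into odds-ratio effect estimates with 95% Wald intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

#: Normal quantile used for 95% Wald intervals.
Z_95 = 1.959964

MAX_ITER = 100
TOL = 1e-8


class SeparationError(RuntimeError):
    """The likelihood is unbounded: a predictor perfectly splits the outcome."""


class RankDeficientError(ValueError):
    """The design matrix is rank deficient (constant or collinear columns)."""


@dataclass(frozen=True)
class EffectEstimate:
    """One fitted term on the odds-ratio scale."""

    name: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if not np.isclose(self.or_, np.exp(self.beta)):
            raise ValueError("or_ must equal exp(beta)")


@dataclass
class LogisticFit:
    """A converged maximum-likelihood logistic fit."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    log_likelihood: float
    converged: bool
    n_used: int
    fitted_probs: np.ndarray

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def effect(self, term: str) -> EffectEstimate:
        """Wald 95% odds-ratio estimate for one term."""
        i = self.terms.index(term)
        b, s = float(self.beta[i]), float(self.se[i])
        return EffectEstimate(
            name=term, beta=b, se=s, or_=float(np.exp(b)),
            ci_low=float(np.exp(b - Z_95 * s)),
            ci_high=float(np.exp(b + Z_95 * s)),
            p=float(self.p[i]),
        )


def _check_design(X: pd.DataFrame) -> None:
    constant = [c for c in X.columns if X[c].nunique(dropna=False) <= 1]
    if constant:
        raise RankDeficientError(f"constant predictor column(s): {constant}")
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify a minimal offender set by greedy column scan
        cols, kept = list(X.columns), [np.ones(len(X))]
        collinear = []
        for c in cols:
            candidate = np.column_stack(kept + [X[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(candidate) == candidate.shape[1]:
                kept.append(X[c].to_numpy(dtype=float))
            else:
                collinear.append(c)
        raise RankDeficientError(f"collinear predictor column(s): {collinear}")


def fit_logistic(X: pd.DataFrame, y: np.ndarray | pd.Series) -> LogisticFit:
    """Fit y ~ intercept + X by maximum likelihood (logit link).

    Raises
    ------
    RankDeficientError
        For constant or collinear predictor columns.
    SeparationError
        For perfect separation or non-convergence within 100 Newton
        iterations at tolerance 1e-8.
    ValueError
        If ``y`` is not binary with both classes present.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values; "
                         "apply complete-case filtering first")
    if len(X.columns):
        _check_design(X)
    design = sm.add_constant(X.astype(float), has_constant="add")
    try:
        result = sm.Logit(y, design).fit(disp=0, method="newton",
                                         maxiter=MAX_ITER, tol=TOL)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"perfect separation or singular information: {exc}")
    if not result.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge in "
                              f"{MAX_ITER} iterations (possible separation)")
    terms = ["const"] + list(X.columns)
    return LogisticFit(
        terms=terms,
        beta=np.asarray(result.params, dtype=float),
        se=np.asarray(result.bse, dtype=float),
        p=np.asarray(result.pvalues, dtype=float),
        log_likelihood=float(result.llf),
        converged=True,
        n_used=int(len(y)),
        fitted_probs=np.asarray(result.predict(design), dtype=float),
    )


def odds_ratio_2x2(a: int, b: int, c: int, d: int,
                   name: str = "exposure") -> EffectEstimate:
    """Cross-product odds ratio with Woolf (log-scale) 95% CI.

    Table layout: exposed cases ``a``, exposed controls ``b``,
    unexposed cases ``c``, unexposed controls ``d``.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells <= 0).any():
        labels = np.array(["exposed/case", "exposed/control",
                           "unexposed/case", "unexposed/control"])
        raise SeparationError(
            f"empty cell(s) {labels[cells <= 0].tolist()}: odds ratio undefined")
    beta = float(np.log(a * d / (b * c)))
    se = float(np.sqrt((1 / cells).sum()))
    z = beta / se
    from scipy.stats import norm
    return EffectEstimate(
        name=name, beta=beta, se=se, or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        p=float(2 * norm.sf(abs(z))),
    )
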