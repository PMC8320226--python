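"""Cross-validated weighted allele score.

The score summarises a gene's SNPs as one scalar per subject:

    score = (W1*SNP1 + W2*SNP2 + ... + Wp*SNPp) / (W1 + W2 + ... + Wp)

where ``SNPi`` is the subject's minor-allele dosage and the weights
``Wi`` are per-SNP coefficients from a multivariable logistic
regression of the phenotype on all SNP dosages. To keep each subject's
weights independent of their own outcome, the cohort is split into k
folds (default 10): fold f's subjects are scored with coefficients
fitted on the other k-1 folds. Weights stay on the signed log-odds
scale; a fold whose weights sum to (numerically) zero makes the
normalisation undefined and raises an error rather than producing
unbounded scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .logistic import SeparationError, fit_logistic

#: Default RNG seed for fold assignment (reproducibility contract).
DEFAULT_SEED = 20210728

#: |sum of weights| below this is treated as a degenerate normaliser.
WEIGHT_SUM_GUARD = 1e-8

MISSING_POLICIES = ("impute", "drop")


@dataclass(frozen=True)
class FoldAssignment:
    """A deterministic k-fold split of n subjects.

    Fold labels are 1..k. Folds 1..k-1 have ``n // k`` subjects; fold k
    takes the remainder as well (``n // k + n % k``), so e.g. 861
    subjects in 10 folds split as nine folds of 86 and one of 87.
    """

    n_subjects: int
    k: int
    labels: np.ndarray
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels != fold)

    def sizes(self) -> list[int]:
        return [int((self.labels == f).sum()) for f in range(1, self.k + 1)]


@dataclass
class WeightSet:
    """Per-fold SNP weights from out-of-fold logistic fits."""

    snp_ids: list[str]
    k: int
    weights: np.ndarray       # (k, p), row f-1 holds fold f's weights
    intercepts: np.ndarray    # (k,)
    converged: np.ndarray     # (k,) bool
    n_train: np.ndarray       # (k,)
    train_mean_dosage: np.ndarray  # (k, p) training-set mean dosage per SNP

    def weight_sums(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class ScoreResult:
    """Per-subject weighted allele scores."""

    subjects: list[str]
    score: np.ndarray
    fold: np.ndarray
    weight_sum: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold": self.fold, "score": self.score, "weight_sum": self.weight_sum},
            index=pd.Index(self.subjects, name="subject_id"),
        )


def assign_folds(n: int, k: int, seed: int = DEFAULT_SEED) -> FoldAssignment:
    """Randomly partition n subjects into k folds.

    A uniformly random permutation is cut into consecutive blocks: the
    first k-1 blocks of size ``n // k`` and a final block that also
    absorbs the remainder. Deterministic given ``(n, k, seed)``.
    """
    if k < 2:
        raise ValueError(f"need at least 2 folds, got k={k}")
    if n < k:
        raise ValueError(f"cannot split n={n} subjects into k={k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base = n // k
    labels = np.empty(n, dtype=int)
    for f in range(1, k + 1):
        start = (f - 1) * base
        stop = f * base if f < k else n
        labels[order[start:stop]] = f
    return FoldAssignment(n_subjects=n, k=k, labels=labels, seed=seed)


def estimate_fold_weights(matrix: GenotypeMatrix,
                          phenotype: np.ndarray | pd.Series,
                          folds: FoldAssignment) -> WeightSet:
    """Fit each fold's SNP weights on the subjects outside that fold.

    One multivariable logistic regression per fold: phenotype on all
    SNP dosages jointly (additive coding, intercept included, no
    covariates). The fitted coefficient of SNP i is its weight Wi for
    subjects of the held-out fold. Missing training dosages are
    imputed with the training-set mean of that SNP; the means are kept
    for scoring-time imputation.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != matrix.n_subjects:
        raise ValueError("phenotype length does not match genotype matrix")
    p = matrix.n_snps
    weights = np.empty((folds.k, p))
    intercepts = np.empty(folds.k)
    converged = np.zeros(folds.k, dtype=bool)
    n_train = np.empty(folds.k, dtype=int)
    train_means = np.empty((folds.k, p))
    for f in range(1, folds.k + 1):
        idx = folds.train_indices(f)
        D = matrix.dosage[idx].copy()
        with warnings.catch_warnings():
            # an all-NaN column is reported as an explicit error below
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(D, axis=0)
        if np.isnan(means).any():
            bad = [matrix.snp_ids[j] for j in np.flatnonzero(np.isnan(means))]
            raise ValueError(f"fold {f}: SNP(s) {bad} all-missing in training set")
        nan_rows, nan_cols = np.nonzero(np.isnan(D))
        D[nan_rows, nan_cols] = means[nan_cols]
        X = pd.DataFrame(D, columns=matrix.snp_ids)
        try:
            fit = fit_logistic(X, y[idx])
        except (SeparationError, ValueError) as exc:
            raise SeparationError(f"weight regression failed in fold {f}: {exc}")
        weights[f - 1] = fit.beta[1:]
        intercepts[f - 1] = fit.beta[0]
        converged[f - 1] = fit.converged
        n_train[f - 1] = len(idx)
        train_means[f - 1] = means
    return WeightSet(snp_ids=list(matrix.snp_ids), k=folds.k, weights=weights,
                     intercepts=intercepts, converged=converged,
                     n_train=n_train, train_mean_dosage=train_means)


def compute_weighted_score(matrix: GenotypeMatrix, weights: WeightSet,
                           folds: FoldAssignment, missing: str = "impute",
                           guard: float = WEIGHT_SUM_GUARD) -> ScoreResult:
    """Score every subject with their own fold's weight vector.

    ``score = sum_i Wi * dosage_i / sum_i Wi``. Missing dosages are
    imputed with the training-fold mean (``missing="impute"``, default;
    keeps the normaliser comparable across subjects) or the subject's
    score is set to NaN (``missing="drop"``). Positive rescaling of a
    fold's weight vector leaves its scores unchanged.
    """
    if missing not in MISSING_POLICIES:
        raise ValueError(f"missing policy {missing!r} not in {MISSING_POLICIES}")
    if weights.k != folds.k or len(weights.snp_ids) != matrix.n_snps:
        raise ValueError("weights, folds and genotype matrix are inconsistent")
    sums = weights.weight_sums()
    degenerate = np.flatnonzero(np.abs(sums) < guard)
    if degenerate.size:
        raise ZeroDivisionError(
            f"degenerate weight sum in fold(s) {(degenerate + 1).tolist()}: "
            f"|sum(W)| < {guard:g}, the normalised score is undefined")
    n = matrix.n_subjects
    score = np.full(n, np.nan)
    weight_sum = np.empty(n)
    for f in range(1, folds.k + 1):
        idx = folds.fold_indices(f)
        D = matrix.dosage[idx].copy()
        w = weights.weights[f - 1]
        if missing == "impute":
            nan_rows, nan_cols = np.nonzero(np.isnan(D))
            D[nan_rows, nan_cols] = weights.train_mean_dosage[f - 1][nan_cols]
            score[idx] = D @ w / sums[f - 1]
        else:
            complete = ~np.isnan(D).any(axis=1)
            score[idx[complete]] = D[complete] @ w / sums[f - 1]
        weight_sum[idx] = sums[f - 1]
    return ScoreResult(subjects=list(matrix.subjects), score=score,
                       fold=folds.labels.copy(), weight_sum=weight_sum)


def cross_validated_allele_score(matrix: GenotypeMatrix,
                                 phenotype: np.ndarray | pd.Series,
                                 k: int = 10, seed: int = DEFAULT_SEED,
                                 missing: str = "impute"
                                 ) -> tuple[FoldAssignment, WeightSet, ScoreResult]:
    """Convenience wrapper: assign folds, fit weights, score everybody."""
    folds = assign_folds(matrix.n_subjects, k, seed)
    weights = estimate_fold_weights(matrix, phenotype, folds)
    scores = compute_weighted_score(matrix, weights, folds, missing=missing)
    return folds, weights, scores
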