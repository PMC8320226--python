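"""Synthetic genotype/phenotype cohort generator.

Emulates an elderly candidate-gene study: independent biallelic SNPs in
Hardy-Weinberg proportions, covariates (age, sex, smoking, drinking),
and a binary hearing phenotype drawn from a logistic model whose
intercept is calibrated so the simulated ARHI prevalence hits a target.
Each subject also receives a per-ear audiogram whose better-ear
pure-tone average is consistent with the assigned class, so phenotype
derivation (PTA computation and the 25 dB HL cutoff) is exercised
end to end.

The default ``paper_like_spec`` mirrors the motivating study design:
n = 861 subjects, prevalence 659/861, nine NR3C1 SNPs at the cohort
minor-allele frequencies implied by its genotype table, and covariate
effects in the direction of its characteristics table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (ARHI, CohortTable, GenotypeMatrix, NORMAL, PTA_CUTOFF_DB,
                   SnpInfo, THRESHOLD_COLUMNS)

#: Prevalence of the motivating study: 659 ARHI cases of 861 subjects.
PAPER_PREVALENCE = 659 / 861

#: dB HL guard band between the class cutoff and any simulated PTA, so
#: float rounding in the threshold->PTA round trip can never flip a class.
PTA_GUARD_DB = 0.5

# Half-normal scales (dB) for the distance of PTA from the cutoff;
# chosen to land the group medians near 21 (normal) and 35 (ARHI) dB HL.
NORMAL_PTA_SCALE = 5.0
ARHI_PTA_SCALE = 14.0


@dataclass(frozen=True)
class SnpSimSpec:
    """One simulated SNP: id, alleles, MAF and per-minor-allele log-OR."""

    snp_id: str
    maf: float
    log_or: float = 0.0
    major_allele: str = "A"
    minor_allele: str = "G"

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class CovariateSimSpec:
    """One simulated covariate.

    ``kind="binary"`` draws Bernoulli(``p``); ``kind="normal"`` draws
    Normal(``mean``, ``sd``) and enters the linear predictor centred at
    its mean (so the intercept calibration is stable).
    """

    name: str
    kind: str
    log_or: float = 0.0
    p: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "normal"):
            raise ValueError(f"{self.name}: kind must be 'binary' or 'normal'")
        if self.kind == "binary" and not (self.p is not None and 0 <= self.p <= 1):
            raise ValueError(f"{self.name}: binary covariate needs p in [0,1]")
        if self.kind == "normal" and (self.mean is None or self.sd is None
                                      or self.sd < 0):
            raise ValueError(f"{self.name}: normal covariate needs mean and sd >= 0")


@dataclass(frozen=True)
class SimSpec:
    """Full description of one simulated study."""

    n_subjects: int
    snps: tuple[SnpSimSpec, ...]
    covariates: tuple[CovariateSimSpec, ...] = ()
    target_prevalence: Optional[float] = PAPER_PREVALENCE
    intercept: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.target_prevalence is None) == (self.intercept is None):
            raise ValueError("give exactly one of target_prevalence / intercept")
        if self.target_prevalence is not None and not (
                0 < self.target_prevalence < 1):
            raise ValueError(f"target_prevalence {self.target_prevalence} "
                             "outside (0, 1)")

    def null(self) -> "SimSpec":
        """Same design with every SNP and covariate effect set to zero."""
        return replace(
            self,
            snps=tuple(replace(s, log_or=0.0) for s in self.snps),
            covariates=tuple(replace(c, log_or=0.0) for c in self.covariates),
        )


# Cohort MAFs implied by the motivating study's genotype counts, with its
# major>minor allele labels; effect sizes are that study's crude per-allele
# log odds ratios for its three significant SNPs, zero elsewhere.
PAPER_SNPS: tuple[SnpSimSpec, ...] = (
    SnpSimSpec("rs6191", 0.047, 0.0, "A", "C"),
    SnpSimSpec("rs61757411", 0.239, 0.0, "G", "T"),
    SnpSimSpec("rs41400245", 0.108, 0.0, "C", "T"),
    SnpSimSpec("rs258751", 0.051, 0.0, "G", "A"),
    SnpSimSpec("rs6196", 0.053, 0.0, "A", "G"),
    SnpSimSpec("rs41423247", 0.199, 0.37, "G", "C"),
    SnpSimSpec("rs6877893", 0.221, 0.38, "A", "G"),
    SnpSimSpec("rs12655166", 0.123, 0.0, "T", "C"),
    SnpSimSpec("rs33388", 0.222, -0.21, "T", "A"),
)

PAPER_COVARIATES: tuple[CovariateSimSpec, ...] = (
    CovariateSimSpec("age", "normal", log_or=0.08, mean=67.0, sd=5.0),
    CovariateSimSpec("sex_male", "binary", log_or=0.74, p=0.40),
    CovariateSimSpec("smoking", "binary", log_or=0.68, p=0.34),
    CovariateSimSpec("drinking", "binary", log_or=0.41, p=0.36),
)


def paper_like_spec(seed: int = 0, with_effects: bool = True,
                    n_subjects: int = 861) -> SimSpec:
    """The default study design (set ``with_effects=False`` for the null)."""
    spec = SimSpec(n_subjects=n_subjects, snps=PAPER_SNPS,
                   covariates=PAPER_COVARIATES,
                   target_prevalence=PAPER_PREVALENCE, seed=seed)
    return spec if with_effects else spec.null()


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(maf: float, n: int,
                       rng: np.random.Generator | int) -> np.ndarray:
    """Draw n dosages as Binomial(2, maf): Hardy-Weinberg proportions."""
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.binomial(2, maf, size=n).astype(float)


def _draw_covariates(spec: SimSpec, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for cov in spec.covariates:
        if cov.kind == "binary":
            cols[cov.name] = rng.binomial(1, cov.p, size=n).astype(float)
        else:
            cols[cov.name] = rng.normal(cov.mean, cov.sd, size=n)
    return pd.DataFrame(cols)


def _linear_predictor_no_intercept(spec: SimSpec, dosage: np.ndarray,
                                   covariates: pd.DataFrame) -> np.ndarray:
    eta = dosage @ np.array([s.log_or for s in spec.snps])
    for cov in spec.covariates:
        x = covariates[cov.name].to_numpy()
        if cov.kind == "normal":
            x = x - cov.mean
        eta = eta + cov.log_or * x
    return eta


def calibrate_intercept(spec: SimSpec, n_mc: int = 200_000,
                        tol: float = 1e-6) -> float:
    """Logistic intercept hitting the spec's target prevalence.

    Bisects on the intercept until the Monte-Carlo mean of
    ``expit(intercept + eta)`` over ``n_mc`` draws from the spec's
    genotype and covariate distributions is within ``tol`` of the
    target. Deterministic given the spec's seed.
    """
    if spec.target_prevalence is None:
        raise ValueError("spec fixes the intercept; nothing to calibrate")
    target = spec.target_prevalence
    if all(s.log_or == 0 for s in spec.snps) and \
            all(c.log_or == 0 for c in spec.covariates):
        # no effects: mean outcome probability is expit(intercept) exactly
        return float(np.log(target / (1 - target)))
    rng_g, rng_c = _streams(spec.seed ^ 0x5F3759DF, 2)
    dosage = np.column_stack([simulate_genotypes(s.maf, n_mc, rng_g)
                              for s in spec.snps]) if spec.snps else \
        np.empty((n_mc, 0))
    covariates = _draw_covariates(spec, n_mc, rng_c)
    eta = _linear_predictor_no_intercept(spec, dosage, covariates)
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        prev = float(expit(mid + eta).mean())
        if abs(prev - target) <= tol:
            return mid
        if prev < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _audiograms(is_case: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Per-ear thresholds whose better-ear mean is class-consistent.

    The target PTA sits at least ``PTA_GUARD_DB`` away from the 25 dB
    cutoff: normal-hearing subjects at ``25 - guard - |N(0, 5)|``
    (floored at 0), ARHI subjects at ``25 + guard + |N(0, 14)|``. The
    better ear gets an integer symmetric spread (+-d at two frequencies
    each) so its arithmetic mean equals the target exactly; the worse
    ear sits a positive gap above it.
    """
    n = len(is_case)
    gap_below = np.abs(rng.normal(0.0, NORMAL_PTA_SCALE, size=n))
    gap_above = np.abs(rng.normal(0.0, ARHI_PTA_SCALE, size=n))
    pta = np.where(
        is_case == 1,
        PTA_CUTOFF_DB + PTA_GUARD_DB + gap_above,
        np.maximum(0.0, PTA_CUTOFF_DB - PTA_GUARD_DB - gap_below),
    )
    spread = rng.integers(0, 6, size=n).astype(float)
    spread = np.minimum(spread, pta)  # keep thresholds non-negative
    patterns = np.array([[-1.0, -1.0, 1.0, 1.0]])[np.zeros(n, dtype=int)]
    patterns = rng.permuted(patterns, axis=1)
    better = pta[:, None] + spread[:, None] * patterns
    worse = better + (1.0 + np.abs(rng.normal(0.0, 6.0, size=n)))[:, None]
    better_is_left = rng.random(n) < 0.5
    left = np.where(better_is_left[:, None], better, worse)
    right = np.where(better_is_left[:, None], worse, better)
    return pd.DataFrame(np.hstack([left, right]), columns=list(THRESHOLD_COLUMNS))


def simulate_study(spec: SimSpec) -> tuple[GenotypeMatrix, CohortTable]:
    """Draw one full study: genotypes, covariates, outcome, audiograms.

    The outcome is Bernoulli(expit(intercept + per-SNP and covariate
    effects)); the cohort table's PTA column is re-derived from the
    generated audiograms, so ``classify_hearing(compute_pta(...))``
    reproduces the simulated classes by construction. Fully
    deterministic given ``spec.seed``.
    """
    n = spec.n_subjects
    rng_g, rng_c, rng_y, rng_a = _streams(spec.seed, 4)
    dosage = np.column_stack([simulate_genotypes(s.maf, n, rng_g)
                              for s in spec.snps]) if spec.snps else \
        np.empty((n, 0))
    covariates = _draw_covariates(spec, n, rng_c)
    intercept = (spec.intercept if spec.intercept is not None
                 else calibrate_intercept(spec))
    eta = intercept + _linear_predictor_no_intercept(spec, dosage, covariates)
    y = rng_y.binomial(1, expit(eta)).astype(int)
    audio = _audiograms(y, rng_a)
    subjects = [f"S{i:04d}" for i in range(1, n + 1)]
    snps = [SnpInfo(s.snp_id, s.major_allele, s.minor_allele,
                    ref_minor_freq=s.maf if s.maf > 0 else None)
            for s in spec.snps]
    matrix = GenotypeMatrix(subjects, snps, dosage)
    table = audio.copy()
    table.index = pd.Index(subjects, name="subject_id")
    left_pta = table[list(THRESHOLD_COLUMNS[:4])].mean(axis=1)
    right_pta = table[list(THRESHOLD_COLUMNS[4:])].mean(axis=1)
    table["pta"] = np.minimum(left_pta, right_pta)
    for col in covariates.columns:
        table[col] = covariates[col].to_numpy()
    cohort = CohortTable(table)
    if not np.array_equal(cohort.is_case.to_numpy(), y):
        raise AssertionError("internal error: derived hearing class diverged "
                             "from the simulated outcome")
    return matrix, cohort
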