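"""Per-SNP QC and association statistics recomputable from counts.

All chi-square statistics are Pearson's, without continuity correction,
and all p-values are two-sided upper-tail probabilities; this matches
the convention of candidate-gene reports that print genotype and allele
contingency tables. Hardy-Weinberg equilibrium is tested on the full
cohort (cases and controls combined).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountTable, allele_counts_from_genotypes
from .logistic import (EffectEstimate, SeparationError, fit_logistic,
                       odds_ratio_2x2)

GENETIC_MODELS = ("additive", "dominant", "recessive")


@dataclass
class HweResult:
    """Hardy-Weinberg goodness-of-fit test for one SNP."""

    snp_id: str
    chi2: float
    df: int
    p: float
    expected_counts: tuple[float, float, float]
    minor_freq: float
    monomorphic: bool = False


@dataclass
class ContingencyResult:
    """Pearson chi-square test on an r x c count table."""

    table: CountTable
    chi2: float
    df: int
    p: float
    dropped_categories: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    """Two-group comparison of one cohort characteristic."""

    variable: str
    test: str  # "mann_whitney" or "chi_square"
    statistic: float
    p: float
    summaries: dict[str, str]


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int,
             snp_id: str = "") -> HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (df = 1).

    With minor-allele frequency ``q = (2*hom_minor + het) / 2n`` the
    expected genotype counts are ``n(1-q)^2, 2nq(1-q), nq^2``. No
    continuity correction. A monomorphic SNP (q in {0, 1}) is flagged
    and returns chi2 = 0, p = 1.
    """
    obs = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    n = obs.sum()
    if n < 1:
        raise ValueError("hwe_test needs at least one genotype")
    q = (2 * n_hom_minor + n_het) / (2 * n)
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q ** 2)
    if q in (0.0, 1.0):
        return HweResult(snp_id, 0.0, 1, 1.0, expected, q, monomorphic=True)
    chi2 = float(((obs - np.array(expected)) ** 2 / np.array(expected)).sum())
    return HweResult(snp_id, chi2, 1, float(stats.chi2.sf(chi2, 1)), expected, q)


def contingency_test(table: CountTable | Sequence[Sequence[int]],
                     drop_empty: bool = True) -> ContingencyResult:
    """Pearson chi-square on a contingency table, df = (r-1)(c-1).

    All-zero rows/columns are removed first (reported in
    ``dropped_categories``); a zero *expected* cell in the retained
    table is an error, as is a table smaller than 2 x 2 after dropping.
    """
    if not isinstance(table, CountTable):
        arr = np.asarray(table)
        table = CountTable([f"r{i}" for i in range(arr.shape[0])],
                           [f"c{j}" for j in range(arr.shape[1])], arr)
    dropped: list[str] = []
    if drop_empty:
        table, dropped = table.drop_empty()
    r, c = table.counts.shape
    if r < 2 or c < 2:
        raise ValueError(f"degenerate table ({r}x{c}) after dropping empty "
                         f"categories {dropped}")
    expected = stats.contingency.expected_freq(table.counts)
    if (expected == 0).any():
        raise ValueError("zero expected count in retained table")
    chi2, p, df, _ = stats.chi2_contingency(table.counts, correction=False)
    return ContingencyResult(table, float(chi2), int(df), float(p), dropped)


def allele_association(case_genotype_counts: tuple[int, int, int],
                       control_genotype_counts: tuple[int, int, int]
                       ) -> ContingencyResult:
    """Case-control allele-count test (2 x 2 Pearson chi-square).

    Each group's genotype triple (hom-major, het, hom-minor) is
    collapsed to major/minor allele counts before testing.
    """
    case_major, case_minor, _ = allele_counts_from_genotypes(*case_genotype_counts)
    ctrl_major, ctrl_minor, _ = allele_counts_from_genotypes(*control_genotype_counts)
    table = CountTable(["case", "control"], ["major", "minor"],
                       np.array([[case_major, case_minor],
                                 [ctrl_major, ctrl_minor]]))
    return contingency_test(table, drop_empty=True)


def _recode(dosage: np.ndarray, model: str) -> np.ndarray:
    if model == "additive":
        return dosage.astype(float)
    if model == "dominant":
        return (dosage > 0).astype(float)
    if model == "recessive":
        return (dosage == 2).astype(float)
    raise ValueError(f"unknown genetic model {model!r}; expected one of "
                     f"{GENETIC_MODELS}")


def genetic_model_test(dosages: np.ndarray | Sequence[int],
                       phenotype: np.ndarray | Sequence[int],
                       model: str = "additive",
                       covariates: Optional[pd.DataFrame] = None,
                       name: str = "snp") -> EffectEstimate:
    """Logistic association of one SNP with a binary phenotype.

    ``additive`` enters the minor-allele dosage as a numeric trend;
    ``dominant`` codes any minor allele as exposure; ``recessive``
    codes two minor alleles as exposure. The unadjusted dominant or
    recessive estimate coincides with the 2x2 cross-product odds ratio
    and its Woolf interval (a property of the saturated logistic fit).
    Missing dosages are dropped pairwise (with matching covariate rows).
    """
    dosages = np.asarray(dosages, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(dosages)
    dosages, phenotype = dosages[keep], phenotype[keep]
    x = _recode(dosages, model)
    if model in ("dominant", "recessive"):
        cells = {
            "exposed/case": ((x == 1) & (phenotype == 1)).sum(),
            "exposed/control": ((x == 1) & (phenotype == 0)).sum(),
            "unexposed/case": ((x == 0) & (phenotype == 1)).sum(),
            "unexposed/control": ((x == 0) & (phenotype == 0)).sum(),
        }
        empty = [k for k, v in cells.items() if v == 0]
        if empty:
            raise SeparationError(f"{name} ({model}): empty cell(s) {empty}")
    X = pd.DataFrame({name: x})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).iloc[np.flatnonzero(keep)]
        X = pd.concat([X, cov.reset_index(drop=True)], axis=1)
    fit = fit_logistic(X, phenotype)
    return fit.effect(name)


def group_comparison(values: Sequence, group_labels: Sequence,
                     variable: str = "", kind: Optional[str] = None
                     ) -> GroupComparison:
    """Compare one characteristic between two groups.

    Continuous variables use the Mann-Whitney U test (midranks,
    tie-corrected variance; exact enumeration for small untied samples);
    categorical variables use the Pearson chi-square on the group-by-
    level count table. ``kind`` may force ``"continuous"`` or
    ``"categorical"``; by default numeric data with more than two
    distinct values is treated as continuous.
    """
    values = pd.Series(list(values), name=variable or "value")
    groups = pd.Series(list(group_labels), name="group")
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    split = {g: values[groups == g] for g in levels}
    for g, v in split.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
    if kind is None:
        numeric = pd.api.types.is_numeric_dtype(values)
        kind = "continuous" if numeric and values.nunique() > 2 else "categorical"
    if kind == "continuous":
        x, y = split[levels[0]], split[levels[1]]
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        summaries = {
            str(g): f"{v.median():g} ({(v.quantile(0.75) - v.quantile(0.25)):g})"
            for g, v in split.items()
        }
        return GroupComparison(variable, "mann_whitney",
                               float(res.statistic), float(res.pvalue), summaries)
    crosstab = pd.crosstab(groups, values)
    table = CountTable([str(r) for r in crosstab.index],
                       [str(c) for c in crosstab.columns],
                       crosstab.to_numpy())
    result = contingency_test(table, drop_empty=True)
    summaries = {}
    for g in levels:
        v = split[g]
        counts = v.value_counts()
        summaries[str(g)] = "; ".join(
            f"{lvl}: {n} ({100 * n / len(v):.2f}%)" for lvl, n in counts.items())
    return GroupComparison(variable, "chi_square", result.chi2, result.p, summaries)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (capped at 1)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
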