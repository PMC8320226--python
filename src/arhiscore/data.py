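"""Core data model: genotypes, audiograms, cohort tables, count tables.

Genotype dosages count copies of the *minor* allele (0/1/2), stored as
float64 with NaN marking missing calls so per-SNP analyses can use
pairwise deletion. Hearing phenotype is derived from the better-ear
pure-tone average (PTA) over 0.5/1/2/4 kHz: PTA > 25 dB HL is classed
as age-related hearing impairment (ARHI), PTA <= 25 dB HL as normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Audiometric frequencies entering the pure-tone average, in kHz.
PTA_FREQUENCIES_KHZ = (0.5, 1.0, 2.0, 4.0)

#: Better-ear PTA cutoff (dB HL); above this value a subject is classed ARHI.
PTA_CUTOFF_DB = 25.0

NORMAL = "normal"
ARHI = "ARHI"

#: Cohort-table column names for per-ear thresholds, left then right ear.
THRESHOLD_COLUMNS = (
    "l500", "l1000", "l2000", "l4000",
    "r500", "r1000", "r2000", "r4000",
)


@dataclass(frozen=True)
class SnpInfo:
    """Identity and allele coding of one biallelic SNP.

    ``minor_allele`` is the allele counted by the dosage; after
    :func:`assign_allele_coding` it is the lower-frequency allele.
    ``ref_minor_freq`` is an optional reference-panel frequency of the
    minor allele (e.g. from an external population panel).
    """

    snp_id: str
    major_allele: Optional[str] = None
    minor_allele: Optional[str] = None
    ref_minor_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.major_allele is not None and self.major_allele == self.minor_allele:
            raise ValueError(f"{self.snp_id}: major and minor allele are both "
                             f"{self.major_allele!r}")
        if self.ref_minor_freq is not None and not (0 < self.ref_minor_freq <= 0.5):
            raise ValueError(f"{self.snp_id}: ref_minor_freq {self.ref_minor_freq} "
                             "outside (0, 0.5]")

    def flipped(self) -> "SnpInfo":
        """Swap major/minor alleles (and complement the reference frequency)."""
        return replace(
            self,
            major_allele=self.minor_allele,
            minor_allele=self.major_allele,
            ref_minor_freq=None if self.ref_minor_freq is None
            else 1.0 - self.ref_minor_freq,
        )


class GenotypeMatrix:
    """Subjects-by-SNPs minor-allele dosage matrix.

    Parameters
    ----------
    subjects
        Ordered subject identifiers.
    snps
        One :class:`SnpInfo` per column.
    dosage
        Array of shape ``(n_subjects, n_snps)``; entries in {0, 1, 2}
        or NaN for a missing call.
    """

    def __init__(self, subjects: Sequence[str], snps: Sequence[SnpInfo],
                 dosage: np.ndarray) -> None:
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(subjects), len(snps)):
            raise ValueError(f"dosage shape {dosage.shape} does not match "
                             f"{len(subjects)} subjects x {len(snps)} SNPs")
        observed = dosage[~np.isnan(dosage)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages outside {{0,1,2}}: {np.unique(bad)}")
        self.subjects = list(subjects)
        self.snps = list(snps)
        self.dosage = dosage

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missingness(self) -> pd.Series:
        """Per-SNP fraction of missing calls."""
        return pd.Series(np.isnan(self.dosage).mean(axis=0), index=self.snp_ids)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(hom-major, het, hom-minor) counts among non-missing subjects."""
        col = self.dosage[:, self.snp_ids.index(snp_id)]
        col = col[~np.isnan(col)]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=pd.Index(self.subjects, name="subject_id"),
                            columns=self.snp_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.subjects == other.subjects and self.snps == other.snps
                and np.array_equal(self.dosage, other.dosage, equal_nan=True))


@dataclass(frozen=True)
class AudiogramRecord:
    """Per-ear air-conduction thresholds (dB HL) at 0.5/1/2/4 kHz.

    Either ear may be absent (``None``); an ear that is present carries
    all four frequencies.
    """

    thresholds_left: Optional[tuple[float, float, float, float]] = None
    thresholds_right: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        for name, thr in (("left", self.thresholds_left),
                          ("right", self.thresholds_right)):
            if thr is None:
                continue
            if len(thr) != len(PTA_FREQUENCIES_KHZ):
                raise ValueError(f"{name} ear: expected "
                                 f"{len(PTA_FREQUENCIES_KHZ)} thresholds, got {len(thr)}")
            if not all(np.isfinite(t) for t in thr):
                raise ValueError(f"{name} ear: non-finite threshold in {thr}")


def compute_pta(record: AudiogramRecord) -> tuple[float, str]:
    """Better-ear pure-tone average.

    Each ear's PTA is the arithmetic mean of its four thresholds; the
    better (lower-PTA) ear is reported. Ties go to the left ear; a
    single-ear record uses that ear.

    Returns
    -------
    (pta, ear) where ``ear`` is ``"left"`` or ``"right"``.
    """
    left, right = record.thresholds_left, record.thresholds_right
    if left is None and right is None:
        raise ValueError("audiogram has no ears")
    pta_left = float(np.mean(left)) if left is not None else np.inf
    pta_right = float(np.mean(right)) if right is not None else np.inf
    if pta_left <= pta_right:
        return pta_left, "left"
    return pta_right, "right"


def classify_hearing(pta: float) -> str:
    """Class label from better-ear PTA: ARHI iff pta > 25 dB HL."""
    if not np.isfinite(pta):
        raise ValueError(f"non-finite PTA: {pta}")
    return ARHI if pta > PTA_CUTOFF_DB else NORMAL


class CohortTable:
    """Per-subject phenotype and covariates.

    Wraps a DataFrame indexed by subject id with columns ``pta`` (dB HL),
    ``hearing`` (``"normal"``/``"ARHI"``, always re-derived from ``pta``)
    and any number of covariate columns. Per-ear threshold columns
    (``l500`` ... ``r4000``), when present, are retained but not treated
    as covariates.
    """

    RESERVED = ("pta", "hearing") + THRESHOLD_COLUMNS

    def __init__(self, table: pd.DataFrame) -> None:
        if "pta" not in table.columns:
            raise ValueError("cohort table needs a 'pta' column "
                             "(use from_audiograms/read_cohort_table to derive it)")
        table = table.copy()
        table["hearing"] = [classify_hearing(p) for p in table["pta"]]
        if table.columns.duplicated().any():
            dups = table.columns[table.columns.duplicated()].tolist()
            raise ValueError(f"duplicate covariate columns: {dups}")
        self.table = table

    @property
    def subjects(self) -> list[str]:
        return list(self.table.index)

    @property
    def pta(self) -> pd.Series:
        return self.table["pta"]

    @property
    def hearing(self) -> pd.Series:
        return self.table["hearing"]

    @property
    def is_case(self) -> pd.Series:
        """Binary ARHI indicator (1 = ARHI)."""
        return (self.table["hearing"] == ARHI).astype(int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.RESERVED]

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountTable:
    """A small r x c contingency table of non-negative integer counts."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(int)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integral")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def drop_empty(self) -> tuple["CountTable", list[str]]:
        """Remove all-zero rows and columns; return (table, dropped labels)."""
        row_keep = self.counts.sum(axis=1) > 0
        col_keep = self.counts.sum(axis=0) > 0
        dropped = ([r for r, k in zip(self.row_labels, row_keep) if not k]
                   + [c for c, k in zip(self.col_labels, col_keep) if not k])
        table = CountTable(
            [r for r, k in zip(self.row_labels, row_keep) if k],
            [c for c, k in zip(self.col_labels, col_keep) if k],
            self.counts[np.ix_(row_keep, col_keep)],
        )
        return table, dropped

    def proportions(self, axis: int = 1) -> np.ndarray:
        """Counts normalised along ``axis`` (default: within rows)."""
        totals = self.counts.sum(axis=axis, keepdims=True)
        return self.counts / totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


def allele_counts_from_genotypes(n_hom_major: int, n_het: int,
                                 n_hom_minor: int) -> tuple[int, int, float]:
    """Collapse genotype counts to allele counts.

    Returns ``(major_count, minor_count, minor_freq)`` with
    ``minor_count = 2*hom_minor + het`` and ``major_count = 2*hom_major + het``.
    """
    for n in (n_hom_major, n_het, n_hom_minor):
        if n < 0 or int(n) != n:
            raise ValueError(f"genotype counts must be non-negative integers, got {n}")
    total = n_hom_major + n_het + n_hom_minor
    if total == 0:
        raise ValueError("empty stratum: all genotype counts are zero")
    minor = 2 * n_hom_minor + n_het
    major = 2 * n_hom_major + n_het
    return major, minor, minor / (major + minor)


def minor_allele_frequency(major_count: int, minor_count: int) -> float:
    """Minor-allele frequency from a pair of allele counts."""
    total = major_count + minor_count
    if total == 0:
        raise ValueError("empty stratum: no alleles")
    return minor_count / total


def assign_allele_coding(matrix: GenotypeMatrix,
                         ref_minor_freqs: Optional[dict[str, float]] = None
                         ) -> GenotypeMatrix:
    """Recode each SNP so dosage counts the lower-frequency (minor) allele.

    The frequency of the currently-counted allele is taken from
    ``ref_minor_freqs`` when supplied for a SNP (reference panel takes
    precedence), otherwise estimated from the cohort itself. Wherever
    that frequency exceeds 0.5 the alleles are swapped and dosages
    flipped (d -> 2 - d). An exact 0.5 tie is broken lexicographically:
    the alphabetically smaller allele symbol becomes the minor allele.
    """
    ref_minor_freqs = ref_minor_freqs or {}
    dosage = matrix.dosage.copy()
    snps: list[SnpInfo] = []
    for j, snp in enumerate(matrix.snps):
        if snp.snp_id in ref_minor_freqs:
            freq = ref_minor_freqs[snp.snp_id]
        else:
            col = dosage[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                raise ValueError(f"{snp.snp_id}: all genotypes missing, "
                                 "cannot infer allele frequencies")
            freq = float(col.sum() / (2 * col.size))
        flip = freq > 0.5
        if freq == 0.5 and snp.major_allele is not None:
            # tie: alphabetically smaller symbol is declared minor
            flip = snp.major_allele < snp.minor_allele
        if flip:
            dosage[:, j] = 2.0 - dosage[:, j]
            snp = replace(snp, major_allele=snp.minor_allele,
                          minor_allele=snp.major_allele, ref_minor_freq=None)
            freq = 1.0 - freq
        if snp.snp_id in ref_minor_freqs:
            snp = replace(snp, ref_minor_freq=freq if 0 < freq <= 0.5 else None)
        snps.append(snp)
    return GenotypeMatrix(matrix.subjects, snps, dosage)
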