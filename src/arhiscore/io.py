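"""Readers and writers for genotype tables (TSV/VCF) and cohort tables (CSV).

Genotype TSV: tab-separated, UTF-8, header ``subject_id`` followed by
SNP ids, one row per subject, cells ``0|1|2|NA``.

VCF: standard VCF 4.x; only the GT field of biallelic SNV records is
consulted. Dosage counts ALT alleles; run
:func:`arhiscore.data.assign_allele_coding` afterwards if ALT may be the
major allele in your population.

Cohort CSV: comma-separated, header ``subject_id`` then either a ``pta``
column or the eight per-ear threshold columns ``l500,l1000,l2000,l4000,
r500,r1000,r2000,r4000`` (dB HL), then covariate columns.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .data import (AudiogramRecord, CohortTable, GenotypeMatrix, SnpInfo,
                   THRESHOLD_COLUMNS, compute_pta)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_genotype_table(path: PathLike, format: str = "tsv") -> GenotypeMatrix:
    """Load a genotype matrix from a TSV dosage table or a VCF."""
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {format!r} (expected 'tsv' or 'vcf')")


def _read_genotype_tsv(path: PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be 'subject_id', "
                         f"got {df.columns[0]!r}")
    subjects = df["subject_id"].tolist()
    snp_ids = list(df.columns[1:])
    dosage = np.full((len(subjects), len(snp_ids)), np.nan)
    for j, snp in enumerate(snp_ids):
        for i, cell in enumerate(df[snp]):
            cell = cell.strip()
            if cell in ("NA", "", "."):
                continue
            if cell not in ("0", "1", "2"):
                raise ValueError(f"{path}: malformed genotype {cell!r} for subject "
                                 f"{subjects[i]!r}, SNP {snp!r}")
            dosage[i, j] = float(cell)
    return GenotypeMatrix(subjects, [SnpInfo(s) for s in snp_ids], dosage)


def write_genotype_table(matrix: GenotypeMatrix, path: PathLike) -> None:
    """Write a genotype matrix as a dosage TSV (missing calls as NA)."""
    df = matrix.to_frame()
    out = df.map(lambda d: "NA" if np.isnan(d) else str(int(d)))
    out.to_csv(path, sep="\t")


def _read_genotype_vcf(path: PathLike) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires cyvcf2 (pip install cyvcf2)") from exc
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snps: list[SnpInfo] = []
    columns: list[np.ndarray] = []
    for record in vcf:
        if len(record.ALT) != 1 or len(record.REF) != 1 or len(record.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNV record %s at %s:%d",
                           record.ID or ".", record.CHROM, record.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = record.gt_types
        col = np.full(len(subjects), np.nan)
        col[gt == 0] = 0.0
        col[gt == 1] = 1.0
        col[gt == 3] = 2.0
        snp_id = record.ID if record.ID not in (None, ".") else \
            f"{record.CHROM}:{record.POS}"
        snps.append(SnpInfo(snp_id, major_allele=record.REF,
                            minor_allele=record.ALT[0]))
        columns.append(col)
    dosage = (np.column_stack(columns) if columns
              else np.empty((len(subjects), 0)))
    return GenotypeMatrix(subjects, snps, dosage)


def read_cohort_table(path: PathLike) -> CohortTable:
    """Load a cohort CSV, deriving PTA from per-ear thresholds if needed."""
    df = pd.read_csv(path, index_col="subject_id")
    if "pta" not in df.columns:
        missing = [c for c in THRESHOLD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: needs a 'pta' column or all threshold "
                             f"columns; missing {missing}")
        ptas = []
        for _, row in df.iterrows():
            record = AudiogramRecord(
                thresholds_left=tuple(row[c] for c in THRESHOLD_COLUMNS[:4]),
                thresholds_right=tuple(row[c] for c in THRESHOLD_COLUMNS[4:]),
            )
            ptas.append(compute_pta(record)[0])
        df["pta"] = ptas
    return CohortTable(df)


def write_cohort_table(cohort: CohortTable, path: PathLike) -> None:
    cohort.table.to_csv(path)


def read_reference_frequencies(path: PathLike) -> dict[str, float]:
    """Read a two-column TSV ``snp_id<TAB>minor_freq`` of panel frequencies."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns snp_id, minor_freq")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
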