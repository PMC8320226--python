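"""End-to-end orchestration: QC, association tables, score, models, ROC.

``run_pipeline`` reproduces the report surface of a candidate-gene
study: a characteristics table (group comparisons per covariate), a
Hardy-Weinberg table, genotype and allele association tables, per-SNP
genetic-model odds ratios, the cross-validated weighted allele score
with its fold/weight artifacts, Model 1 / Model 2 score odds ratios,
and the ROC of the covariate-adjusted prediction model. Outputs are
TSV files plus one JSON bundle; a manifest records versions, seed and
input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .allele_score import DEFAULT_SEED, cross_validated_allele_score
from .association import (MODEL1, ModelSpec, prediction_model, score_effect)
from .data import ARHI, CohortTable, CountTable, GenotypeMatrix, NORMAL
from .logistic import RankDeficientError, SeparationError
from .snp_stats import (GENETIC_MODELS, allele_association, bonferroni,
                        contingency_test, genetic_model_test, group_comparison,
                        hwe_test)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on."""

    genotype_path: Optional[str] = None
    cohort_path: Optional[str] = None
    ref_freq_path: Optional[str] = None
    genotype_format: str = "tsv"
    k_folds: int = 10
    seed: int = DEFAULT_SEED
    model2_covariates: Optional[list[str]] = None  # None = all covariates
    out_dir: Optional[str] = None
    drop_empty: bool = True
    bonferroni: bool = False
    missing_dosage: str = "impute"

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError(f"k_folds must be >= 2, got {self.k_folds}")


def _load(config: PipelineConfig) -> tuple[GenotypeMatrix, CohortTable]:
    from .data import assign_allele_coding
    from .io import read_cohort_table, read_genotype_table, read_reference_frequencies
    if config.genotype_path is None or config.cohort_path is None:
        raise ValueError("config needs genotype_path and cohort_path "
                         "(or pass matrix/cohort to run_pipeline directly)")
    matrix = read_genotype_table(config.genotype_path, config.genotype_format)
    ref = (read_reference_frequencies(config.ref_freq_path)
           if config.ref_freq_path else None)
    matrix = assign_allele_coding(matrix, ref)
    cohort = read_cohort_table(config.cohort_path)
    return matrix, cohort


def _align(matrix: GenotypeMatrix, cohort: CohortTable
           ) -> tuple[GenotypeMatrix, CohortTable]:
    common = [s for s in cohort.subjects if s in set(matrix.subjects)]
    if not common:
        raise ValueError("genotype and cohort tables share no subjects")
    if len(common) < len(cohort.subjects) or len(common) < matrix.n_subjects:
        logger.warning("restricting to %d subjects present in both tables",
                       len(common))
    pos = {s: i for i, s in enumerate(matrix.subjects)}
    idx = [pos[s] for s in common]
    matrix = GenotypeMatrix(common, matrix.snps, matrix.dosage[idx])
    cohort = CohortTable(cohort.table.loc[common])
    return matrix, cohort


def _characteristics(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    group = cohort.hearing
    pta_cmp = group_comparison(cohort.pta, group, variable="pta")
    rows.append(pta_cmp)
    for name in cohort.covariate_names:
        rows.append(group_comparison(cohort.table[name], group, variable=name))
    return pd.DataFrame([{
        "variable": r.variable, "test": r.test, "statistic": r.statistic,
        "p": r.p, **{f"summary_{g}": s for g, s in r.summaries.items()},
    } for r in rows])


def _snp_tables(matrix: GenotypeMatrix, cohort: CohortTable,
                config: PipelineConfig) -> dict[str, pd.DataFrame]:
    is_case = cohort.is_case.to_numpy()
    hwe_rows, geno_rows, allele_rows, model_rows = [], [], [], []
    for j, snp in enumerate(matrix.snps):
        col = matrix.dosage[:, j]
        observed = ~np.isnan(col)
        if not observed.any():
            raise ValueError(f"SNP {snp.snp_id}: all genotypes missing")
        counts = matrix.genotype_counts(snp.snp_id)
        hwe = hwe_test(*counts, snp_id=snp.snp_id)
        hwe_rows.append({
            "snp_id": snp.snp_id, "n": int(sum(counts)),
            "n_hom_major": counts[0], "n_het": counts[1], "n_hom_minor": counts[2],
            "minor_freq": hwe.minor_freq, "chi2": hwe.chi2, "p": hwe.p,
            "monomorphic": hwe.monomorphic,
        })
        case_counts = tuple(int(((col == d) & (is_case == 1)).sum())
                            for d in (0.0, 1.0, 2.0))
        ctrl_counts = tuple(int(((col == d) & (is_case == 0)).sum())
                            for d in (0.0, 1.0, 2.0))
        geno_table = CountTable(
            [ARHI, NORMAL], ["hom_major", "het", "hom_minor"],
            np.array([case_counts, ctrl_counts]))
        try:
            geno = contingency_test(geno_table, drop_empty=config.drop_empty)
            geno_rows.append({"snp_id": snp.snp_id, "chi2": geno.chi2,
                              "df": geno.df, "p": geno.p,
                              "dropped": ",".join(geno.dropped_categories),
                              **_flatten_counts(case_counts, ctrl_counts)})
        except ValueError as exc:
            raise ValueError(f"genotype association failed for {snp.snp_id}: {exc}")
        allele = allele_association(case_counts, ctrl_counts)
        allele_rows.append({
            "snp_id": snp.snp_id,
            "case_major": int(allele.table.counts[0, 0]),
            "case_minor": int(allele.table.counts[0, 1]),
            "control_major": int(allele.table.counts[1, 0]),
            "control_minor": int(allele.table.counts[1, 1]),
            "chi2": allele.chi2, "p": allele.p,
        })
        for model in GENETIC_MODELS:
            try:
                eff = genetic_model_test(col, is_case, model=model,
                                         name=snp.snp_id)
                model_rows.append({
                    "snp_id": snp.snp_id, "model": model, "beta": eff.beta,
                    "se": eff.se, "or": eff.or_, "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high, "p": eff.p, "note": "",
                })
            except (SeparationError, RankDeficientError) as exc:
                logger.warning("%s %s model not estimable: %s",
                               snp.snp_id, model, exc)
                model_rows.append({
                    "snp_id": snp.snp_id, "model": model, "beta": np.nan,
                    "se": np.nan, "or": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "p": np.nan,
                    "note": f"not estimable: {exc}",
                })
    tables = {
        "hwe": pd.DataFrame(hwe_rows),
        "genotype_association": pd.DataFrame(geno_rows),
        "allele_association": pd.DataFrame(allele_rows),
        "genetic_models": pd.DataFrame(model_rows),
    }
    if config.bonferroni:
        for key in ("genotype_association", "allele_association"):
            tables[key]["p_bonferroni"] = bonferroni(tables[key]["p"].tolist())
    return tables


def _flatten_counts(case_counts, ctrl_counts) -> dict[str, int]:
    labels = ("hom_major", "het", "hom_minor")
    out = {f"case_{l}": int(c) for l, c in zip(labels, case_counts)}
    out.update({f"control_{l}": int(c) for l, c in zip(labels, ctrl_counts)})
    return out


def run_pipeline(config: PipelineConfig,
                 matrix: Optional[GenotypeMatrix] = None,
                 cohort: Optional[CohortTable] = None) -> dict:
    """Run every stage and return the JSON-serialisable report bundle.

    Inputs come either from the config's file paths or from in-memory
    objects. When ``config.out_dir`` is set, per-stage TSVs, the JSON
    bundle and a run manifest are written there.
    """
    if matrix is None or cohort is None:
        matrix, cohort = _load(config)
    matrix, cohort = _align(matrix, cohort)
    logger.info("pipeline: %d subjects (%d ARHI), %d SNPs, seed %d",
                len(cohort), cohort.n_cases, matrix.n_snps, config.seed)

    characteristics = _characteristics(cohort)
    snp_tables = _snp_tables(matrix, cohort, config)

    folds, weights, scores = cross_validated_allele_score(
        matrix, cohort.is_case.to_numpy(), k=config.k_folds, seed=config.seed,
        missing=config.missing_dosage)

    model2 = ModelSpec("model2", covariates=None if config.model2_covariates
                       is None else tuple(config.model2_covariates))
    effect1 = score_effect(scores, cohort, MODEL1)
    effect2 = score_effect(scores, cohort, model2)
    fit, roc = prediction_model(scores, cohort, model2)

    score_models = pd.DataFrame([
        {"model": "model1", "or": effect1.or_, "ci_low": effect1.ci_low,
         "ci_high": effect1.ci_high, "p": effect1.p, "beta": effect1.beta,
         "se": effect1.se, "covariates": ""},
        {"model": "model2", "or": effect2.or_, "ci_low": effect2.ci_low,
         "ci_high": effect2.ci_high, "p": effect2.p, "beta": effect2.beta,
         "se": effect2.se, "covariates": ",".join(model2.resolve(cohort))},
    ])

    bundle = {
        "n_subjects": len(cohort),
        "n_cases": cohort.n_cases,
        "n_snps": matrix.n_snps,
        "seed": config.seed,
        "k_folds": config.k_folds,
        "characteristics": characteristics.to_dict(orient="records"),
        "hwe": snp_tables["hwe"].to_dict(orient="records"),
        "genotype_association":
            snp_tables["genotype_association"].to_dict(orient="records"),
        "allele_association":
            snp_tables["allele_association"].to_dict(orient="records"),
        "genetic_models": snp_tables["genetic_models"].to_dict(orient="records"),
        "fold_sizes": folds.sizes(),
        "fold_weights": {
            "snp_ids": weights.snp_ids,
            "weights": weights.weights.tolist(),
            "intercepts": weights.intercepts.tolist(),
            "weight_sums": weights.weight_sums().tolist(),
        },
        "score_summary": {
            "mean": float(np.nanmean(scores.score)),
            "sd": float(np.nanstd(scores.score)),
            "n_scored": int(np.isfinite(scores.score).sum()),
        },
        "score_models": score_models.to_dict(orient="records"),
        "roc": {"auc": roc.auc, "n_cases": roc.n_cases,
                "n_controls": roc.n_controls},
        "prediction_model_note": (
            "prediction model = logistic regression of ARHI on the weighted "
            "allele score plus the model-2 covariates; AUC is in-sample"),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        characteristics.to_csv(out / "characteristics.tsv", sep="\t", index=False)
        for name, df in snp_tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        scores.to_frame().to_csv(out / "scores.tsv", sep="\t")
        pd.DataFrame(weights.weights, columns=weights.snp_ids,
                     index=pd.Index(range(1, folds.k + 1), name="fold")
                     ).to_csv(out / "fold_weights.tsv", sep="\t")
        score_models.to_csv(out / "score_models.tsv", sep="\t", index=False)
        roc.curve().to_csv(out / "roc.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(bundle, indent=2,
                                                    default=_json_default))
        (out / "manifest.json").write_text(json.dumps(
            _manifest(config), indent=2, default=_json_default))
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _manifest(config: PipelineConfig) -> dict:
    manifest = {
        "arhiscore_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": dataclasses.asdict(config),
        "input_checksums": {},
    }
    for key in ("genotype_path", "cohort_path", "ref_freq_path"):
        path = getattr(config, key)
        if path and Path(path).exists():
            manifest["input_checksums"][key] = _sha256(path)
    return manifest
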