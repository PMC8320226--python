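"""Fold assignment, out-of-fold weights, and the weighted allele score."""

import numpy as np
import pandas as pd
import pytest

import arhiscore as a
from arhiscore.allele_score import WEIGHT_SUM_GUARD
from arhiscore.logistic import fit_logistic


def _matrix(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, p = dosage.shape
    return a.GenotypeMatrix([f"S{i}" for i in range(n)],
                            [a.SnpInfo(f"rs{j}") for j in range(p)], dosage)


class TestFoldAssignment:
    @pytest.mark.parametrize("n, k, sizes", [
        (861, 10, [86] * 9 + [87]),   # the study's split
        (100, 10, [10] * 10),
        (95, 10, [9] * 9 + [14]),     # remainder all in the last fold
    ])
    def test_fold_sizes(self, n, k, sizes):
        assert a.assign_folds(n, k, seed=3).sizes() == sizes

    def test_deterministic_given_seed(self):
        f1 = a.assign_folds(200, 10, seed=9)
        f2 = a.assign_folds(200, 10, seed=9)
        f3 = a.assign_folds(200, 10, seed=10)
        assert np.array_equal(f1.labels, f2.labels)
        assert not np.array_equal(f1.labels, f3.labels)

    def test_too_few_subjects_is_an_error(self):
        with pytest.raises(ValueError):
            a.assign_folds(5, 10)
        with pytest.raises(ValueError):
            a.assign_folds(100, 1)


class TestFoldWeights:
    def test_single_snp_weight_is_log_cross_product_ratio(self):
        # training 2x2: dosage 1 -> 20 cases/10 controls; 0 -> 10/20
        dosage = np.concatenate([np.ones(30), np.zeros(30)])[:, None]
        y = np.concatenate([np.ones(20), np.zeros(10),
                            np.ones(10), np.zeros(20)])
        m = _matrix(np.vstack([dosage, dosage]))
        folds = a.FoldAssignment(120, 2,
                                 np.array([1] * 60 + [2] * 60), seed=0)
        weights = a.estimate_fold_weights(m, np.concatenate([y, y]), folds)
        assert weights.weights[0, 0] == pytest.approx(np.log(4), abs=1e-6)
        assert weights.weights[1, 0] == pytest.approx(np.log(4), abs=1e-6)

    def test_null_weights_shrink_to_zero(self, rng):
        n = 20_000
        dosage = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        y = rng.binomial(1, 0.6, size=n)
        folds = a.assign_folds(n, 2, seed=1)
        weights = a.estimate_fold_weights(_matrix(dosage), y, folds)
        assert np.all(np.abs(weights.weights) < 0.1)

    def test_duplicating_training_subjects_leaves_weights_unchanged(self, rng):
        n = 120
        dosage = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        y = rng.binomial(1, 0.5, size=n)
        base_fit = fit_logistic(pd.DataFrame(dosage, columns=["a", "b"]), y)
        doubled = fit_logistic(
            pd.DataFrame(np.vstack([dosage, dosage]), columns=["a", "b"]),
            np.concatenate([y, y]))
        assert doubled.beta == pytest.approx(base_fit.beta, abs=1e-7)

    def test_out_of_fold_discipline(self, paper_study):
        # permuting phenotype labels inside fold f never changes W^(f)
        matrix, cohort = paper_study
        y = cohort.is_case.to_numpy().astype(float)
        folds = a.assign_folds(matrix.n_subjects, 10, seed=2)
        base = a.estimate_fold_weights(matrix, y, folds)
        rng = np.random.default_rng(0)
        y2 = y.copy()
        inside = folds.fold_indices(3)
        y2[inside] = rng.permutation(y2[inside])
        perturbed = a.estimate_fold_weights(matrix, y2, folds)
        assert perturbed.weights[2] == pytest.approx(base.weights[2],
                                                     rel=1e-9)

    def test_training_all_missing_snp_is_an_error(self):
        dosage = np.full((40, 1), np.nan)
        m = _matrix(dosage)
        folds = a.assign_folds(40, 2, seed=0)
        with pytest.raises(ValueError, match="all-missing"):
            a.estimate_fold_weights(m, np.tile([0, 1], 20), folds)


def _weightset(w, snp_ids=None, means=None):
    w = np.asarray(w, dtype=float)
    k, p = w.shape
    return a.WeightSet(
        snp_ids=snp_ids or [f"rs{j}" for j in range(p)], k=k, weights=w,
        intercepts=np.zeros(k), converged=np.ones(k, bool),
        n_train=np.full(k, 10),
        train_mean_dosage=means if means is not None else np.full((k, p), 1.0))


class TestWeightedScore:
    def test_equal_weights_reduce_to_mean_dosage(self):
        m = _matrix([[0, 1, 2]])
        folds = a.FoldAssignment(1, 2, np.array([1]), seed=0)
        scores = a.compute_weighted_score(m, _weightset([[1, 1, 1], [1, 1, 1]]),
                                          folds)
        assert scores.score[0] == pytest.approx(1.0)

    def test_hand_computed_score(self):
        m = _matrix([[2, 1]])
        folds = a.FoldAssignment(1, 2, np.array([1]), seed=0)
        scores = a.compute_weighted_score(
            m, _weightset([[0.5, 1.5], [0.5, 1.5]]), folds)
        assert scores.score[0] == pytest.approx((0.5 * 2 + 1.5 * 1) / 2.0)

    def test_single_snp_weight_cancels(self):
        m = _matrix([[2], [1], [0]])
        folds = a.FoldAssignment(3, 2, np.array([1, 1, 2]), seed=0)
        scores = a.compute_weighted_score(m, _weightset([[0.7], [-2.0]]), folds)
        assert scores.score.tolist() == [2.0, 1.0, 0.0]

    def test_invariant_under_positive_rescaling(self, rng):
        dosage = rng.binomial(2, 0.3, size=(30, 4)).astype(float)
        m = _matrix(dosage)
        folds = a.assign_folds(30, 3, seed=0)
        w = rng.normal(size=(3, 4))
        base = a.compute_weighted_score(m, _weightset(w), folds)
        scaled = a.compute_weighted_score(m, _weightset(w * 7.5), folds)
        assert scaled.score == pytest.approx(base.score, rel=1e-12)

    def test_degenerate_weight_sum_is_an_error(self):
        m = _matrix([[1, 1], [0, 2]])
        folds = a.FoldAssignment(2, 2, np.array([1, 2]), seed=0)
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            a.compute_weighted_score(
                m, _weightset([[1.0, -1.0 + WEIGHT_SUM_GUARD / 10], [1, 1]]),
                folds)

    def test_missing_policy_impute_vs_drop(self):
        dosage = np.array([[1.0, np.nan], [2.0, 0.0]])
        m = _matrix(dosage)
        folds = a.FoldAssignment(2, 2, np.array([1, 2]), seed=0)
        ws = _weightset([[1.0, 1.0], [1.0, 1.0]],
                        means=np.array([[0.5, 0.5], [0.5, 0.5]]))
        imputed = a.compute_weighted_score(m, ws, folds, missing="impute")
        assert imputed.score[0] == pytest.approx((1.0 + 0.5) / 2.0)
        dropped = a.compute_weighted_score(m, ws, folds, missing="drop")
        assert np.isnan(dropped.score[0]) and dropped.score[1] == 1.0

    def test_identical_training_data_matches_single_model(self, rng):
        # all folds see the same training rows -> every weight vector
        # coincides and the CV score equals the single-model score
        block_d = rng.binomial(2, 0.4, size=(80, 3)).astype(float)
        block_y = rng.binomial(1, 0.5, size=80)
        dosage = np.vstack([block_d, block_d])
        y = np.concatenate([block_y, block_y])
        m = _matrix(dosage)
        folds = a.FoldAssignment(160, 2, np.array([1] * 80 + [2] * 80), seed=0)
        weights = a.estimate_fold_weights(m, y, folds)
        assert weights.weights[0] == pytest.approx(weights.weights[1],
                                                   abs=1e-7)
        single = fit_logistic(pd.DataFrame(block_d), block_y).beta[1:]
        scores = a.compute_weighted_score(m, weights, folds)
        expected = block_d @ single / single.sum()
        assert scores.score[:80] == pytest.approx(expected, abs=1e-5)


class TestEndToEndScore:
    def test_convenience_wrapper_is_deterministic(self, paper_study):
        matrix, cohort = paper_study
        y = cohort.is_case.to_numpy()
        f1, w1, s1 = a.cross_validated_allele_score(matrix, y, seed=21)
        f2, w2, s2 = a.cross_validated_allele_score(matrix, y, seed=21)
        assert np.array_equal(f1.labels, f2.labels)
        assert np.array_equal(w1.weights, w2.weights)
        assert np.array_equal(s1.score, s2.score)

    def test_score_test_calibrated_when_weights_are_outcome_free(self):
        # control experiment for the naive score test: with weights
        # drawn independently of the outcome, the one-df Wald test on
        # the normalised score keeps its nominal 5% level
        rejections = 0
        n_reps = 500
        for rep in range(n_reps):
            spec = a.paper_like_spec(seed=rep, with_effects=False)
            matrix, cohort = a.simulate_study(spec)
            rng = np.random.default_rng(10_000 + rep)
            w = rng.normal(0.0, 0.2, matrix.n_snps)
            while abs(w.sum()) < 1e-3:
                w = rng.normal(0.0, 0.2, matrix.n_snps)
            score = matrix.dosage @ w / w.sum()
            fit = fit_logistic(pd.DataFrame({"score": score}),
                               cohort.is_case.to_numpy())
            rejections += fit.p[1] < 0.05
        rate = rejections / n_reps
        mc_err = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) <= 3 * mc_err

    def test_weighting_beats_unweighted_count_under_real_effects(self):
        # heterogeneous true effects (two risk alleles, one protective,
        # six null SNPs): the CV-weighted score should separate groups
        # better than the raw minor-allele count on average
        z_weighted, z_unweighted = [], []
        for rep in range(200):
            spec = a.paper_like_spec(seed=rep)
            matrix, cohort = a.simulate_study(spec)
            y = cohort.is_case.to_numpy()
            _, _, s = a.cross_validated_allele_score(matrix, y, seed=rep)
            fw = fit_logistic(pd.DataFrame({"s": s.score}), y)
            z_weighted.append(abs(fw.beta[1] / fw.se[1]))
            fu = fit_logistic(
                pd.DataFrame({"s": matrix.dosage.sum(axis=1)}), y)
            z_unweighted.append(abs(fu.beta[1] / fu.se[1]))
        assert np.mean(z_weighted) > np.mean(z_unweighted)
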