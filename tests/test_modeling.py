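"""Labels, the Mann-Whitney AUC, repeated CV and the SOFA regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sepsisphase.matrix import FeatureMatrix
from sepsisphase.modeling import (
    DEFAULT_SOFA_EXCLUSIONS, ModelSpec, auc, binarize_labels,
    fit_predict_proba, regress_sofa, repeated_cv, spearman,
)
from sepsisphase.synthetic import binormal_matrix


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestBinarizeLabels:
    def test_early_to_peak_categories_positive(self):
        assert binarize_labels([3]) == [1]
        assert binarize_labels([7]) == [0]
        assert binarize_labels([1]) == [0]
        assert binarize_labels(range(1, 12)).tolist() == [0, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..11"):
            binarize_labels([0, 3])


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_tie_convention(self):
        assert auc([0.5, 0.5], [1, 0]) == 0.5

    def test_hand_enumerated_pairs(self):
        assert auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 40)
        scores = rng.choice(np.linspace(0, 1, 11), n)  # deliberate ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=40))
    def test_complement_under_score_negation(self, scores):
        labels = np.arange(len(scores)) % 2
        scores = np.asarray(scores) + 1e-3 * np.arange(len(scores))  # break ties
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


class TestSpearman:
    def test_monotone_map_gives_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(np.exp(x), x) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        assert spearman([4, 3, 2, 1], [1, 2, 3, 4]) == pytest.approx(-1.0)

    def test_single_swap_rank_formula(self):
        assert spearman([1, 2, 3, 5, 4], [1, 2, 3, 4, 5]) == pytest.approx(0.9)

    def test_constant_vector_signalled(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRepeatedCV:
    def test_separable_data_saturates_auc(self):
        fm = binormal_matrix(100, [6.0], seed=0)
        for family in ("logistic_regression", "naive_bayes"):
            res = repeated_cv(fm, ModelSpec(family), repeats=3, seed=0)
            assert res.mean >= 0.99

    def test_pairing_contract_across_models(self):
        fm = binormal_matrix(120, [1.0], seed=1)
        a = repeated_cv(fm, ModelSpec("logistic_regression"), repeats=4, seed=9)
        b = repeated_cv(fm, ModelSpec("naive_bayes"), repeats=4, seed=9)
        assert a.fingerprint == b.fingerprint
        c = repeated_cv(fm, ModelSpec("naive_bayes"), repeats=4, seed=10)
        assert a.fingerprint != c.fingerprint

    def test_values_shape_and_mean(self):
        fm = binormal_matrix(100, [1.0], seed=2)
        res = repeated_cv(fm, ModelSpec("logistic_regression"), repeats=5, seed=0)
        assert res.values.shape == (5, 10)
        assert res.mean == pytest.approx(np.nanmean(res.values))
        frame = res.long_frame()
        assert len(frame) == 50 and set(frame["fold"]) == set(range(1, 11))

    def test_stratified_fold_balance(self):
        fm = binormal_matrix(103, [1.0], pos_fraction=0.3, seed=3)
        from sepsisphase.modeling import _fold_plan
        y = fm.y.to_numpy()
        plan, _ = _fold_plan(y, stratify=True, repeats=2, folds=10, seed=0)
        for splits in plan:
            for _, test_idx in splits:
                n_pos = y[test_idx].sum()
                expect = len(test_idx) * y.mean()
                assert abs(n_pos - expect) <= 1.0

    def test_too_few_per_class_rejected(self):
        fm = binormal_matrix(30, [1.0], pos_fraction=0.1, seed=0)
        with pytest.raises(ValueError, match="per class"):
            repeated_cv(fm, ModelSpec("logistic_regression"), repeats=1, folds=10)


class TestFitPredictProba:
    def test_probabilities_bounded_and_confident_in_cluster(self):
        train = binormal_matrix(300, [3.0], seed=4)
        test = binormal_matrix(50, [3.0], seed=5)
        for family in ("logistic_regression", "linear_svm", "naive_bayes"):
            p = fit_predict_proba(ModelSpec(family), train, test)
            assert np.all((p >= 0) & (p <= 1))
            assert p[test.y.to_numpy() == 1].mean() > 0.5

    def test_calibration_tracks_prevalence(self):
        train = binormal_matrix(700, [1.5], pos_fraction=0.3, seed=6)
        test = binormal_matrix(1000, [1.5], pos_fraction=0.3, seed=7)
        p = fit_predict_proba(ModelSpec("linear_svm"), train, test)
        assert p.mean() == pytest.approx(0.3, abs=0.1)

    def test_deterministic_for_fixed_inputs(self):
        train = binormal_matrix(100, [1.0], seed=8)
        test = binormal_matrix(20, [1.0], seed=9)
        p1 = fit_predict_proba(ModelSpec("logistic_regression"), train, test)
        p2 = fit_predict_proba(ModelSpec("logistic_regression"), train, test)
        assert np.array_equal(p1, p2)

    def test_feature_mismatch_named(self):
        train = binormal_matrix(100, [1.0], seed=8, feature_names=["a"])
        test = binormal_matrix(20, [1.0], seed=9, feature_names=["b"])
        with pytest.raises(ValueError, match="mismatch.*'a', 'b'"):
            fit_predict_proba(ModelSpec("logistic_regression"), train, test)


class TestRegressSofa:
    @staticmethod
    def _matrix_with_target(n=200, p=24, seed=0, target="monotone"):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        idx = pd.Index([f"P{i:04d}" for i in range(n)], name="patient")
        names = [f"f{j}" for j in range(p)]
        if target == "monotone":
            t = 2.0 * X[:, 0] + 1.0        # noiseless monotone in feature 0
        else:
            t = rng.standard_normal(n)      # independent of all features
        return FeatureMatrix(X=pd.DataFrame(X, index=idx, columns=names),
                             target=pd.Series(t, index=idx, name="log_sofa"))

    def test_noiseless_monotone_target_recovered(self):
        fm = self._matrix_with_target(target="monotone")
        res = regress_sofa(fm, ModelSpec("linear_regression"), repeats=3,
                           excluded=("f23",))
        assert res.mean >= 0.99

    def test_independent_target_near_zero(self):
        # one fixed dataset carries spurious correlation of order sqrt(p/n),
        # so the null check averages a few independent datasets
        means = []
        for seed in (1, 2, 3):
            fm = self._matrix_with_target(n=400, target="null", seed=seed)
            res = regress_sofa(fm, ModelSpec("linear_regression"), repeats=10,
                               excluded=("f23",))
            means.append(res.mean)
        assert abs(np.mean(means)) <= 0.1

    def test_default_exclusions_leave_23_of_31(self):
        from sepsisphase.features import build_feature_matrix
        from sepsisphase.synthetic import SimulationConfig, generate_cohort
        cohort = generate_cohort(SimulationConfig(n_patients=60, seed=2))
        fm = build_feature_matrix(cohort)
        keep = [f for f in fm.feature_names if f not in set(DEFAULT_SOFA_EXCLUSIONS)]
        assert len(fm.feature_names) == 31 and len(keep) == 23

    def test_fewer_than_23_candidates_warns(self):
        fm = self._matrix_with_target(p=10)
        with pytest.warns(UserWarning, match="candidate features"):
            regress_sofa(fm, ModelSpec("linear_regression"), repeats=2,
                         excluded=("f0", "f1"))

    def test_classifier_family_rejected(self):
        fm = self._matrix_with_target()
        with pytest.raises(ValueError, match="regression"):
            regress_sofa(fm, ModelSpec("linear_svm"))
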