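import numpy as np
import pandas as pd
import pytest

from habhet.modeling import (
    ALGORITHMS,
    ModelSuite,
    evaluate,
    expected_calibration_error,
    icc_filter,
    metrics_from_confusion,
    select_features,
    stratified_split,
    tree_topk,
    univariate_filter,
)


def make_cohort(n=200, n_features=10, shift=2.0, prevalence=0.3, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.uniform(size=n) < prevalence).astype(int)
    X = rng.standard_normal((n, n_features))
    X[:, 0] += shift * y
    X[:, 1] -= shift * y
    cols = [f"f{i}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), pd.Series(y)


class TestSplit:
    def test_published_cohort_arithmetic(self):
        # 275 cases, 65 positive -> train 192 (45 pos), test 83 (20 pos)
        y = pd.Series([1] * 65 + [0] * 210)
        split = stratified_split(y, ratio=0.7, seed=0)
        assert (split == "train").sum() == 192
        assert (split == "test").sum() == 83
        assert ((split == "train") & (y == 1)).sum() == 45
        assert ((split == "test") & (y == 1)).sum() == 20

    def test_small_balanced_cohort(self):
        y = pd.Series([0, 1] * 5)
        split = stratified_split(y, ratio=0.7, seed=1)
        assert (split == "test").sum() == 3
        assert set(y[split == "test"]) <= {0, 1}

    def test_seeds_change_membership_not_sizes(self):
        y = pd.Series([1] * 30 + [0] * 70)
        s1 = stratified_split(y, seed=1)
        s2 = stratified_split(y, seed=2)
        assert (s1 == "test").sum() == (s2 == "test").sum()
        assert not (s1 == s2).all()
        pd.testing.assert_series_equal(s1, stratified_split(y, seed=1))

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(pd.Series([0] * 10 + [1]))


class TestICCFilter:
    def test_identical_ratings_retained(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (20, 4)), columns=list("abcd"))
        keep, table = icc_filter({"intra": [df, df.copy()]})
        assert keep == list("abcd")
        np.testing.assert_allclose(table["intra"], 1.0)

    def test_shuffled_ratings_excluded(self, rng):
        base = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("abc"))
        shuffled = base.sample(frac=1, random_state=9).reset_index(drop=True)
        keep, _ = icc_filter({"inter": [base, shuffled]})
        assert keep == []

    def test_single_rating_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="repeats"):
            icc_filter({"intra": [df]})


class TestUnivariateFilter:
    def test_null_type_I_rate(self):
        rng = np.random.default_rng(11)
        n, m = 120, 1000
        y = pd.Series(([0] * 60) + ([1] * 60))
        X = pd.DataFrame(rng.standard_normal((n, m)),
                         columns=[f"n{i}" for i in range(m)])
        keep, _ = univariate_filter(X, y)
        assert 0.03 <= len(keep) / m <= 0.07

    def test_strong_shift_always_retained(self):
        rng = np.random.default_rng(2)
        y = pd.Series([1] * 45 + [0] * 147)
        X = pd.DataFrame({"sig": rng.standard_normal(len(y)) + 2.0 * y})
        keep, pvals = univariate_filter(X, y)
        assert keep == ["sig"]
        assert pvals["sig"] < 1e-6

    def test_constant_feature_excluded(self):
        y = pd.Series([0] * 10 + [1] * 10)
        X = pd.DataFrame({"const": np.ones(20)})
        keep, _ = univariate_filter(X, y)
        assert keep == []


class TestTreeTopK:
    def test_returns_exactly_k(self):
        X, y = make_cohort(n=150, n_features=40)
        names = tree_topk(X, y, k=20, seed=0)
        assert len(names) == 20
        assert len(set(names)) == 20

    def test_separating_feature_ranks_first(self):
        rng = np.random.default_rng(4)
        y = pd.Series([0] * 50 + [1] * 50)
        X = pd.DataFrame(rng.standard_normal((100, 10)),
                         columns=[f"f{i}" for i in range(10)])
        X["perfect"] = y * 10.0
        names = tree_topk(X, y, k=3, seed=0)
        assert names[0] == "perfect"

    def test_k_equal_to_input_is_identity(self):
        X, y = make_cohort(n=60, n_features=5)
        assert tree_topk(X, y, k=5) == sorted(X.columns)


class TestSelectionPipeline:
    def test_counts_non_increasing_and_final_20(self):
        X, y = make_cohort(n=200, n_features=60, shift=1.5)
        noisy = X + np.random.default_rng(1).normal(0, 0.05, X.shape)
        report = select_features(X, y, rating_sets={"intra": [X, noisy]})
        assert report.n_input >= report.n_after_icc >= report.n_after_univariate
        assert report.n_final == min(20, report.n_after_univariate)
        assert report.retained == sorted(report.retained, key=report.retained.index)


class TestSuiteAndEvaluation:
    def test_separable_fixture_high_train_auc(self):
        X, y = make_cohort(n=150, n_features=2, shift=5.0)
        suite = ModelSuite(list(X.columns), seed=0).fit(X, y)
        for algo in ALGORITHMS:
            rep = evaluate(suite, algo, X, y)
            assert rep.auc > 0.95, algo

    def test_shuffled_labels_near_chance(self):
        X, y = make_cohort(n=200, n_features=5, shift=0.0)
        tr = X.index < 140
        suite = ModelSuite(list(X.columns), seed=0).fit(X[tr], y[tr])
        aucs = [evaluate(suite, algo, X[~tr], y[~tr]).auc for algo in ALGORITHMS]
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_same_seed_identical_dnn_predictions(self):
        X, y = make_cohort(n=120, n_features=4)
        p1 = ModelSuite(list(X.columns), seed=3, algorithms=("DNN",)).fit(X, y) \
            .predict_proba("DNN", X)
        p2 = ModelSuite(list(X.columns), seed=3, algorithms=("DNN",)).fit(X, y) \
            .predict_proba("DNN", X)
        np.testing.assert_array_equal(p1, p2)

    def test_confusion_matrix_metrics_worked_example(self):
        # TP=20, FN=0, TN=46, FP=17 -> sensitivity 100.0%, specificity 73.0%
        m = metrics_from_confusion(tn=46, fp=17, fn=0, tp=20)
        assert m["sensitivity"] * 100 == pytest.approx(100.0)
        assert m["specificity"] * 100 == pytest.approx(73.0, abs=0.05)
        assert m["recall"] == m["sensitivity"]
        f1 = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        assert m["f1"] == pytest.approx(f1, rel=1e-12)

    def test_single_class_split_rejected(self):
        X, y = make_cohort(n=60, n_features=3)
        suite = ModelSuite(list(X.columns), seed=0).fit(X, y)
        with pytest.raises(ValueError):
            evaluate(suite, "LG", X, pd.Series(np.zeros(len(y), int)))

    def test_no_leakage_from_test_rows(self):
        X, y = make_cohort(n=200, n_features=6, shift=1.0)
        tr = X.index < 140
        suite1 = ModelSuite(list(X.columns), seed=0).fit(X[tr], y[tr])
        m1 = evaluate(suite1, "LG", X[tr], y[tr])
        # permute the held-out rows; train metrics must be unchanged
        perm = X[~tr].sample(frac=1, random_state=8)
        suite2 = ModelSuite(list(X.columns), seed=0).fit(X[tr], y[tr])
        _ = evaluate(suite2, "LG", perm, y[~tr].sample(frac=1, random_state=8))
        m2 = evaluate(suite2, "LG", X[tr], y[tr])
        assert m1.to_dict() == m2.to_dict()


class TestCalibration:
    def test_perfect_probabilities_zero_ece(self):
        y = np.array([0, 0, 1, 1])
        prob = np.array([0.0, 0.0, 1.0, 1.0])
        assert expected_calibration_error(y, prob) == 0.0

    def test_constant_half_on_balanced_labels(self):
        y = np.array([0, 1] * 50)
        prob = np.full(100, 0.5)
        assert expected_calibration_error(y, prob) == pytest.approx(0.0)

    def test_overconfident_probabilities_penalized(self):
        y = np.array([0, 1] * 50)
        prob = np.where(y == 1, 0.99, 0.01) * 0 + 0.99  # always confident positive
        assert expected_calibration_error(y, prob) == pytest.approx(0.49)
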