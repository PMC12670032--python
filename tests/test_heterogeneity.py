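import numpy as np
import pandas as pd
import pytest

from habhet.heterogeneity import (
    REGION_ORDER,
    cv,
    heterogeneity_vector,
    icc_2_1,
    stability_analysis,
)


class TestCV:
    def test_hand_arithmetic(self):
        # sample SD of (1,2,3) is 1, mean 2
        assert cv([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_homogeneous_values_give_zero(self):
        assert cv([4.0] * 10) == 0.0

    def test_scale_invariance(self, rng):
        v = rng.uniform(1, 5, 20)
        for c in (0.01, 3.0, 1e4):
            assert cv(c * v) == pytest.approx(cv(v), rel=1e-12)

    def test_permutation_invariance(self, rng):
        v = rng.uniform(1, 5, 15)
        assert cv(v) == pytest.approx(cv(rng.permutation(v)), rel=1e-12)

    def test_near_zero_mean_flagged_missing(self):
        assert np.isnan(cv([-1.0, 1.0]))

    def test_pairwise_missing_exclusion(self):
        assert cv([1.0, np.nan, 2.0, 3.0]) == pytest.approx(0.5)
        assert np.isnan(cv([np.nan, np.nan, 1.0]))  # <2 survivors


class TestVector:
    @staticmethod
    def _tables(rng, n_hab=5, n_cols=3):
        cols = [f"AP_firstorder_F{i}" for i in range(n_cols)]
        return {r: pd.DataFrame(rng.uniform(1, 2, (n_hab, n_cols)), columns=cols)
                for r in REGION_ORDER}

    def test_length_is_4x_columns(self, rng):
        tables = self._tables(rng)
        vec = heterogeneity_vector(tables)
        assert len(vec) == 4 * 3
        assert vec.index.is_unique
        assert all(n.startswith(("ITH_", "PTH_Peri")) for n in vec.index)

    def test_identical_rows_give_zero_vector(self):
        cols = ["T2_firstorder_Mean"]
        row = pd.DataFrame([[2.0]] * 6, columns=cols)
        vec = heterogeneity_vector({r: row.copy() for r in REGION_ORDER})
        assert (vec == 0).all()

    def test_row_permutation_invariance(self, rng):
        tables = self._tables(rng)
        vec1 = heterogeneity_vector(tables)
        shuffled = {r: t.sample(frac=1, random_state=1) for r, t in tables.items()}
        vec2 = heterogeneity_vector(shuffled)
        pd.testing.assert_series_equal(vec1, vec2, rtol=1e-12)

    def test_missing_region_named(self, rng):
        tables = self._tables(rng)
        del tables["Peri5"]
        with pytest.raises(ValueError, match="Peri5"):
            heterogeneity_vector(tables)

    def test_full_pipeline_vector_is_1712(self, normalized_case):
        from habhet.pipeline import process_case

        stack, tumor = normalized_case
        res = process_case(stack, tumor)
        assert len(res["th"]) == 1712
        assert res["th"].index.is_unique
        finite = res["th"].dropna()
        assert (finite >= 0).all()


class TestICC:
    def test_closed_form_anova_worked_example(self):
        # 4 targets x 2 raters: ((1,2),(2,3),(3,4),(4,6))
        data = np.array([[1, 2], [2, 3], [3, 4], [4, 6.0]])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((data - data.mean(1, keepdims=True) - data.mean(0) + grand) ** 2
               ).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_2_1(data) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, (8, 3)) + rng.normal(0, 2, (8, 1))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(8), 3),
            "raters": np.tile(np.arange(3), 8),
            "scores": data.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="scores")
        # ICC(A,1): two-way random effects, absolute agreement, single rater
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc_2_1(data) == pytest.approx(icc2, rel=1e-9)

    def test_perfect_agreement(self):
        base = np.arange(1.0, 7.0)
        data = np.column_stack([base, base, base])
        assert icc_2_1(data) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self, rng):
        data = rng.standard_normal((50, 5))
        assert abs(icc_2_1(data)) < 0.2


class TestStability:
    def test_constant_across_K_gives_icc_one(self, rng):
        base = pd.DataFrame({"f": rng.uniform(1, 3, 20)})
        vectors = {K: base.copy() for K in (30, 40, 50)}
        icc = stability_analysis(vectors)
        assert icc["f"] == pytest.approx(1.0)

    def test_rerandomized_per_K_gives_icc_near_zero(self, rng):
        vectors = {K: pd.DataFrame({"f": rng.standard_normal(50)})
                   for K in (30, 40, 50, 60, 70)}
        icc = stability_analysis(vectors)
        assert abs(icc["f"]) < 0.2

    def test_requires_two_settings(self, rng):
        with pytest.raises(ValueError):
            stability_analysis({50: pd.DataFrame({"f": rng.standard_normal(5)})})
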