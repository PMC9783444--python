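"""Statistical battery: asymmetry, outlier screening, regression models, tests."""

import numpy as np
import pandas as pd
import pytest

from ribbonfd import (
    DegenerateTestError,
    SingularDesignError,
    add_asymmetry_columns,
    age_subgroup_analysis,
    asymmetry_index,
    compare_models_aic,
    fit_asymmetry_model,
    fit_fd_model,
    fit_interaction_model,
    fit_sex_stratified,
    fit_threeway_asymmetry_model,
    paired_t,
    remove_extreme_outliers,
    welch_t,
)
from conftest import make_noiseless_table


class TestAsymmetryIndex:
    def test_symmetric_inputs_give_zero(self):
        assert asymmetry_index(2.4, 2.4) == 0.0

    def test_direct_evaluation(self):
        assert asymmetry_index(2.43, 2.42) == pytest.approx(2 * 0.01 / 4.85, rel=1e-12)

    def test_antisymmetry_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        left = rng.uniform(1.5, 3.0, 500)
        right = rng.uniform(1.5, 3.0, 500)
        np.testing.assert_allclose(
            asymmetry_index(left, right), -asymmetry_index(right, left), atol=1e-15
        )
        np.testing.assert_allclose(
            asymmetry_index(3.7 * left, 3.7 * right), asymmetry_index(left, right), atol=1e-12
        )

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_index(1.0, -1.0)

    def test_sign_convention_left_dominant_is_positive(self):
        assert asymmetry_index(2.5, 2.3) > 0  # leftward
        assert asymmetry_index(2.3, 2.5) < 0  # rightward


class TestOutlierRemoval:
    def _table(self, col):
        return pd.DataFrame({"id": [f"s{i}" for i in range(len(col))], "fd_lh": col})

    def test_identical_values_nothing_removed(self):
        out, log = remove_extreme_outliers(self._table([2.4] * 12), columns=("fd_lh",))
        assert log.empty and out["fd_lh"].notna().all()

    def test_hand_computed_fences(self):
        # 1..10 + 1000: Q1=3.5, Q3=8.5 (linear interpolation), IQR=5,
        # fences [-11.5, 23.5] -> only 1000 is extreme
        col = list(range(1, 11)) + [1000]
        out, log = remove_extreme_outliers(self._table(col), columns=("fd_lh",))
        assert len(log) == 1
        assert log.iloc[0]["value"] == 1000
        assert out["fd_lh"].isna().sum() == 1

    def test_per_measure_screening_keeps_other_columns(self):
        df = self._table(list(range(1, 11)) + [1000])
        df["fd_rh"] = 2.4
        out, log = remove_extreme_outliers(df, columns=("fd_lh", "fd_rh"))
        assert out["fd_rh"].notna().all()
        assert set(log["measure"]) == {"fd_lh"}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            remove_extreme_outliers(pd.DataFrame())


class TestFDModel:
    def test_noiseless_exact_recovery(self, noiseless_table):
        res = fit_fd_model(noiseless_table, "fd_a")
        assert res.intercept.estimate == pytest.approx(2.4, abs=1e-8)
        assert res.terms["age"].estimate == pytest.approx(-3e-4, abs=1e-10)
        assert res.terms["sex"].estimate == pytest.approx(4e-3, abs=1e-10)
        assert res.terms["tbv"].estimate == pytest.approx(2e-8, rel=1e-6)
        assert res.adj_r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_quadratic_exact_recovery(self, noiseless_table):
        res = fit_fd_model(noiseless_table, "fd_b", include_quadratic=True)
        assert res.terms["age2"].estimate == pytest.approx(1e-5, abs=1e-10)

    def test_recovery_within_2_se_at_n2000(self, cohort_2000):
        table, truth = cohort_2000
        for col in ("fd_lh", "fd_lp"):
            p = truth["region_params"][col]
            res = fit_fd_model(table, col)
            for name, true_val in (("age", p.beta_age), ("sex", p.beta_sex), ("tbv", p.beta_tbv)):
                t = res.terms[name]
                assert abs(t.estimate - true_val) < 2 * t.se, (col, name)

    def test_aic_arithmetic_identity(self, cohort_2000):
        # AIC = n log(RSS/n) + n(log 2pi + 1) + 2k with k = coefficients + 1
        table, _ = cohort_2000
        res = fit_fd_model(table, "fd_lh")
        import statsmodels.api as sm

        data = table[["fd_lh", "age", "sex", "tbv"]].dropna()
        X = sm.add_constant(data[["age", "sex", "tbv"]].to_numpy())
        fit = sm.OLS(data["fd_lh"].to_numpy(), X).fit()
        n, k = len(data), 5
        expect = n * np.log(fit.ssr / n) + n * (np.log(2 * np.pi) + 1) + 2 * k
        assert res.aic == pytest.approx(expect, abs=1e-6)

    def test_useless_regressor_costs_at_most_2_aic(self, cohort_2000):
        table, _ = cohort_2000
        lin = fit_fd_model(table, "fd_lh")
        quad = fit_fd_model(table, "fd_lh", include_quadratic=True)  # true beta_age2 = 0
        assert quad.aic - lin.aic <= 2.0 + 1e-9

    def test_constant_shift_moves_only_intercept(self, cohort_2000):
        table, _ = cohort_2000
        shifted = table.copy()
        shifted["fd_lh"] = shifted["fd_lh"] + 0.5
        a, b = fit_fd_model(table, "fd_lh"), fit_fd_model(shifted, "fd_lh")
        assert b.intercept.estimate - a.intercept.estimate == pytest.approx(0.5, abs=1e-9)
        for name in ("age", "sex", "tbv"):
            assert b.terms[name].estimate == pytest.approx(a.terms[name].estimate, abs=1e-12)

    def test_rank_deficient_design_rejected(self, noiseless_table):
        df = noiseless_table.copy()
        df["age"] = 60.0  # constant regressor collinear with intercept
        with pytest.raises(SingularDesignError):
            fit_fd_model(df, "fd_a")


class TestModelComparison:
    def test_tie_prefers_linear(self, noiseless_table):
        res = fit_fd_model(noiseless_table, "fd_a")
        cmp_ = compare_models_aic(res, res)
        assert cmp_.delta_aic == 0.0 and cmp_.preferred == "linear"

    def test_row_mismatch_rejected(self, cohort_2000):
        table, _ = cohort_2000
        lin = fit_fd_model(table, "fd_lh")
        quad = fit_fd_model(table.iloc[:-5], "fd_lh", include_quadratic=True)
        with pytest.raises(ValueError, match="identical rows"):
            compare_models_aic(lin, quad)

    def test_true_quadratic_detected(self, noiseless_table):
        lin = fit_fd_model(noiseless_table, "fd_b")
        quad = fit_fd_model(noiseless_table, "fd_b", include_quadratic=True)
        assert compare_models_aic(lin, quad).preferred == "quadratic"


class TestSexStratified:
    def test_noiseless_distinct_slopes_recovered(self):
        df = make_noiseless_table(60)
        df["fd_s"] = np.where(
            df["sex"] == 0,
            2.4 - 2e-4 * df["age"] + 2e-8 * df["tbv"],
            2.4 - 5e-4 * df["age"] + 2e-8 * df["tbv"],
        )
        female, male = fit_sex_stratified(df, "fd_s")
        assert female.terms["age"].estimate == pytest.approx(-2e-4, abs=1e-10)
        assert male.terms["age"].estimate == pytest.approx(-5e-4, abs=1e-10)

    def test_equal_parameters_differ_only_by_noise(self, cohort_2000):
        table, truth = cohort_2000
        female, male = fit_sex_stratified(table, "fd_rh")
        diff = abs(female.terms["age"].estimate - male.terms["age"].estimate)
        pooled_se = np.hypot(female.terms["age"].se, male.terms["age"].se)
        assert diff < 4 * pooled_se

    def test_single_sex_table_flags_missing_stratum(self, noiseless_table):
        df = noiseless_table[noiseless_table["sex"] == 0]
        female, male = fit_sex_stratified(df, "fd_a")
        assert female is not None and male is None


class TestInteractionModel:
    def test_noiseless_interaction_recovered_exactly(self, noiseless_table):
        res = fit_interaction_model(noiseless_table, "fd_c")
        assert res.terms["age_sex"].estimate == pytest.approx(-5e-5, abs=1e-10)

    def test_single_sex_design_is_singular(self, noiseless_table):
        df = noiseless_table[noiseless_table["sex"] == 0]
        with pytest.raises(SingularDesignError):
            fit_interaction_model(df, "fd_a")


def _paired_table(n=60, seed=3):
    rng = np.random.default_rng(seed)
    df = make_noiseless_table(n, seed)
    df["fd_lh"] = 2.43 + 0.01 * rng.standard_normal(n)
    df["fd_rh"] = df["fd_lh"] - 0.005 + 0.004 * rng.standard_normal(n)
    for key in ("lf", "rf", "lt", "rt", "lp", "rp", "lo", "ro"):
        df[f"fd_{key}"] = 2.35 + 0.01 * rng.standard_normal(n)
    return df


class TestAsymmetryModels:
    def test_noiseless_exact_recovery(self):
        df = make_noiseless_table(50)
        df["fd_lh"] = 2.43 + 1e-4 * df["age"]
        df["fd_rh"] = df["fd_lh"]
        df = add_asymmetry_columns(_with_all_regions(df))
        df["ai_hemisphere"] = 0.01 - 2.5e-5 * df["age"] + 3e-4 * df["sex"] + 1e-9 * df["tbv"]
        res = fit_asymmetry_model(df, "hemisphere")
        assert res.terms["age"].estimate == pytest.approx(-2.5e-5, abs=1e-12)
        assert res.terms["sex"].estimate == pytest.approx(3e-4, abs=1e-12)

    def test_simulated_recovery_within_2_se(self):
        rng = np.random.default_rng(9)
        n = 2000
        df = make_noiseless_table(n, seed=9)
        age = rng.uniform(45, 79, n)
        df["age"] = age
        ai = 0.004 - 2.5e-5 * age + rng.normal(0, 0.003, n)
        df["ai_hemisphere"] = ai
        df["fd_lh"] = 2.43 * (1 + ai / 2)
        df["fd_rh"] = 2.43 * (1 - ai / 2)
        res = fit_asymmetry_model(df, "hemisphere")
        t = res.terms["age"]
        assert abs(t.estimate - (-2.5e-5)) < 2 * t.se

    def test_threeway_constant_ai_is_singular(self):
        df = _with_all_regions(make_noiseless_table(40))
        df["fd_lh"] = 2.4
        df["fd_rh"] = 2.4  # ai identically zero
        with pytest.raises(SingularDesignError):
            fit_threeway_asymmetry_model(df, "hemisphere")

    def test_threeway_noiseless_main_effects_exact(self):
        rng = np.random.default_rng(4)
        n = 200
        df = make_noiseless_table(n, seed=4)
        ai = rng.normal(0, 0.003, n)
        df["ai_hemisphere"] = ai
        df["fd_lh"] = 2.4 - 2e-4 * df["age"] - 1e-3 * df["sex"] + 0.5 * ai
        df["fd_rh"] = df["fd_lh"]
        res = fit_threeway_asymmetry_model(df, "hemisphere")
        assert res.terms["age"].estimate == pytest.approx(-2e-4, abs=1e-9)
        assert res.terms["ai_hemisphere"].estimate == pytest.approx(0.5, abs=1e-6)
        assert res.terms["age_sex_ai"].estimate == pytest.approx(0.0, abs=1e-6)
        assert "tbv" not in res.terms  # three-way model excludes TBV

    def test_threeway_null_interactions_rarely_reject(self):
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            n = 400
            df = make_noiseless_table(n, seed=rep)
            df["age"] = rng.uniform(45, 79, n)
            df["sex"] = rng.integers(0, 2, n)
            df["fd_lh"] = 2.43 + rng.normal(0, 0.01, n)
            df["fd_rh"] = 2.43 + rng.normal(0, 0.01, n)
            df = add_asymmetry_columns(_with_all_regions(df))
            res = fit_threeway_asymmetry_model(df, "hemisphere")
            if res.terms["age_sex_ai"].p_value < 0.005:
                hits += 1
        assert hits <= 2  # >= 95% of null replicates stay below threshold


def _with_all_regions(df):
    for key in ("lh", "rh", "lf", "rf", "lt", "rt", "lp", "rp", "lo", "ro"):
        if f"fd_{key}" not in df.columns:
            df = df.assign(**{f"fd_{key}": 2.35 + 0.001 * np.arange(len(df))})
    return df


class TestAgeSubgroups:
    def test_boundary_age_falls_in_upper_bin(self):
        df = make_noiseless_table(80, seed=1)
        df["age"] = np.concatenate([np.full(40, 50.0), np.linspace(50.1, 54.9, 40)])
        subs = age_subgroup_analysis(df, "fd_a", min_n=10)
        bin_45 = next(s for s in subs if s.age_lo == 45)
        bin_50 = next(s for s in subs if s.age_lo == 50)
        assert bin_45.n == 0 and bin_50.n == 80

    def test_uniform_ages_produce_seven_bins(self):
        df = make_noiseless_table(700, seed=2)
        df["age"] = np.linspace(45, 79.9, 700)
        subs = age_subgroup_analysis(df, "fd_a")
        assert len(subs) == 7
        assert all(s.result is not None for s in subs)

    def test_small_bin_flagged_and_skipped(self):
        df = make_noiseless_table(30, seed=3)
        df["age"] = np.linspace(45, 49.9, 30)
        subs = age_subgroup_analysis(df, "fd_a", min_n=10)
        assert subs[0].result is not None
        assert all(s.result is None and s.n == 0 for s in subs[1:])

    def test_injected_steep_bin_is_most_negative(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            n = 1400
            df = make_noiseless_table(n, seed=rep)
            age = rng.uniform(45, 79.99, n)
            df["age"] = age
            slope = np.where((age >= 60) & (age < 65), -4e-3, -2e-4)
            df["fd_a"] = 2.4 + slope * age + rng.normal(0, 0.01, n)
            subs = age_subgroup_analysis(df, "fd_a")
            ests = {s.age_lo: s.result.terms["age"].estimate for s in subs if s.result}
            if min(ests, key=ests.get) == 60:
                hits += 1
        assert hits >= 18  # steep bin detected in >= 90% of replicates


class TestTTests:
    def test_paired_hand_computed(self):
        # pairs (1,2), (2,2), (3,5): diffs -1, 0, -2 -> mean -1, sd 1,
        # t = -1 / (1/sqrt(3)) = -sqrt(3)
        t, p, direction = paired_t([1, 2, 3], [2, 2, 5])
        assert t == pytest.approx(-np.sqrt(3), rel=1e-12)
        assert direction == "rightward"
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(np.sqrt(3), df=2), rel=1e-12)

    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_t([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])

    def test_constant_offset_degenerate(self):
        left = np.linspace(2.4, 2.5, 10)
        with pytest.raises(DegenerateTestError):
            paired_t(left + 0.01, left)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1, 2], [2, 3])

    def test_welch_identical_groups_give_zero(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_hand_computed(self):
        # means 2 and 3, each var 1, n 3: t = -1 / sqrt(2/3), df = 4
        t, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1 / np.sqrt(2 / 3), rel=1e-12)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=4), rel=1e-12)

    def test_welch_minimum_group_size(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
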