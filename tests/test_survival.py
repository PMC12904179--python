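import math

import numpy as np
import pandas as pd
import pytest

from dietspan.survival import (
    ModelSpec,
    cause_specific_fit,
    fit_cox,
    food_group_effects,
    interaction_analysis,
    joint_groups,
    leave_one_out_substitution,
    quintile_medians,
    rcs_basis,
    reri_from_hrs,
    spline_dose_response,
    stratified_analysis,
    trend_test,
)

from conftest import make_analysis_cohort
from _oracles import rank_points

M1 = ModelSpec(covariates="model1")


class TestFitCox:
    def test_two_level_exponential_matches_rate_ratio_oracle(self):
        """With exponential survival and no covariates, the Cox HR must agree
        with the events/person-years ratio estimator."""
        rng = np.random.default_rng(17)
        n = 8000
        group = rng.integers(0, 2, n).astype(float)
        rate = 0.05 * np.exp(math.log(1.6) * group)
        t = rng.exponential(1.0 / rate)
        cohort = pd.DataFrame(
            {"time_years": np.minimum(t, 8.0), "event": t <= 8.0}
        )
        hrs = fit_cox(cohort, pd.Series(group), ModelSpec(covariates="model1"),
                      n_groups=2)
        lv = hrs.levels.set_index("level")
        oracle = (lv.loc[2, "n_events"] / lv.loc[2, "person_years"]) / (
            lv.loc[1, "n_events"] / lv.loc[1, "person_years"]
        )
        assert lv.loc[2, "hr"] == pytest.approx(oracle, rel=0.02)

    def test_quintile_output_contract(self, analysis_cohort):
        cohort, _ = analysis_cohort
        hrs = fit_cox(cohort, "latent_diet", M1)
        lv = hrs.levels.set_index("level")
        assert lv.loc[1, "hr"] == 1.0
        assert (lv["hr"] > 0).all()
        nonref = lv.loc[2:]
        assert (nonref["ci_low"] <= nonref["hr"]).all()
        assert (nonref["hr"] <= nonref["ci_high"]).all()
        assert lv["n"].sum() == len(cohort)
        assert lv["person_years"].sum() == pytest.approx(
            cohort["time_years"].sum()
        )

    def test_protective_effect_recovered(self, analysis_cohort):
        cohort, params = analysis_cohort
        hrs = fit_cox(cohort, "latent_diet", M1)
        assert hrs.per_sd_hr < 1.0
        assert hrs.p_trend < 0.05
        lo, hi = hrs.per_sd_ci
        assert lo <= math.exp(params.log_hr_per_sd_diet) * 1.06
        assert hi >= math.exp(params.log_hr_per_sd_diet) * 0.94

    def test_zero_event_level_rejected(self):
        rng = np.random.default_rng(1)
        cohort = pd.DataFrame(
            {
                "time_years": rng.uniform(1, 10, 200),
                "event": np.zeros(200, dtype=bool),
            }
        )
        cohort.loc[:39, "event"] = True
        score = pd.Series(np.arange(200, dtype=float))
        cohort.loc[160:, "event"] = False  # top quintile has no events
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(cohort, score, M1)

    def test_time_scaling_and_covariate_shift_invariance(self, analysis_cohort):
        cohort, _ = analysis_cohort
        base = fit_cox(cohort, "latent_diet", M1)
        scaled = cohort.copy()
        scaled["time_years"] = scaled["time_years"] * 3.0
        shifted = cohort.copy()
        shifted["age"] = shifted["age"] + 5.0
        for variant in (scaled, shifted):
            hrs = fit_cox(variant, "latent_diet", M1)
            assert hrs.per_sd_hr == pytest.approx(base.per_sd_hr, rel=1e-6)
            assert hrs.levels["hr"].to_numpy() == pytest.approx(
                base.levels["hr"].to_numpy(), rel=1e-6
            )


class TestTrend:
    def test_median_coding_matches_bruteforce(self, analysis_cohort):
        cohort, _ = analysis_cohort
        s = cohort["latent_diet"]
        groups = np.array(rank_points(list(s), 5))
        meds = quintile_medians(s, groups)
        for q in range(1, 6):
            assert meds[q] == pytest.approx(
                float(np.median(s[groups == q])), abs=1e-12
            )

    def test_trend_p_small_under_monotone_effect(self, analysis_cohort):
        cohort, _ = analysis_cohort
        assert trend_test(cohort, "latent_diet", M1) < 0.05


class TestSplines:
    def test_basis_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        t1, t2, t3 = np.percentile(x, [10, 50, 90])

        def plus3(u):
            return np.maximum(u, 0.0) ** 3

        expected = (
            plus3(x - t1)
            - plus3(x - t2) * (t3 - t1) / (t3 - t2)
            + plus3(x - t3) * (t2 - t1) / (t3 - t2)
        ) / (t3 - t1) ** 2
        B = rcs_basis(x, [t1, t2, t3])
        assert np.allclose(B[:, 0], x)
        assert np.allclose(B[:, 1], expected)

    def test_basis_linear_beyond_boundary_knots(self):
        # second differences of the nonlinear term vanish outside the knots
        knots = [0.0, 1.0, 2.0]
        x = np.linspace(3, 6, 50)
        nl = rcs_basis(x, knots)[:, 1]
        assert np.allclose(np.diff(nl, 2), 0.0, atol=1e-9)

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError, match="knots"):
            rcs_basis(np.arange(5.0), [1.0, 1.0, 2.0])

    def test_null_exposure_gives_flat_curve(self):
        cohort, _ = make_analysis_cohort(
            n=3000, seed=31, log_hr_per_sd_diet=0.0, log_hr_per_sd_prs=0.0
        )
        curve, p_nl = spline_dose_response(cohort, "latent_diet", M1)
        assert ((curve["ci_low"] <= 0) & (0 <= curve["ci_high"])).all()
        assert p_nl > 0.01
        # curve is referenced to the median score
        mid = curve.iloc[(curve["score"] - np.median(cohort["latent_diet"])).abs().idxmin()]
        assert abs(mid["log_hr"]) < 0.05


class TestInteraction:
    def test_reri_algebraic_identities(self):
        # pure multiplicative joint effect
        hr10, hr01 = 0.8, 0.9
        hr11 = hr10 * hr01
        assert reri_from_hrs(hr10, hr01, hr11) == pytest.approx(
            hr10 * hr01 - hr10 - hr01 + 1
        )
        # perfectly additive excess risks -> RERI exactly 0 (dyadic values)
        hr10, hr01 = 0.75, 0.5
        hr11 = hr10 + hr01 - 1
        assert reri_from_hrs(hr10, hr01, hr11) == 0.0

    def test_point_estimates_satisfy_reri_identity(self, analysis_cohort):
        cohort, _ = analysis_cohort
        res = interaction_analysis(cohort, "latent_diet", spec=M1)
        assert res.reri == reri_from_hrs(res.hr10, res.hr01, res.hr11)
        assert 0.0 <= res.p_multiplicative <= 1.0
        assert res.reri_ci[0] <= res.reri <= res.reri_ci[1]
        assert set(res.stratum_hrs) == {"low", "intermediate", "high"}
        for hrs in res.stratum_hrs.values():
            assert hrs.levels.set_index("level").loc[1, "hr"] == 1.0


class TestJointGroups:
    def test_fifteen_cells_partition_cohort(self, analysis_cohort):
        cohort, _ = analysis_cohort
        res = joint_groups(cohort, "latent_diet", spec=M1)
        assert len(res.levels) == 15
        assert res.levels["n"].sum() == len(cohort)
        ref = res.levels.set_index("level").loc["Q1_low"]
        assert ref["hr"] == 1.0
        # favourable diet and PRS should have HR below 1 under the defaults
        assert res.levels.set_index("level").loc["Q5_high", "hr"] < 1.0


class TestStratified:
    def test_single_stratum_reduces_to_plain_fit(self, analysis_cohort):
        cohort, _ = analysis_cohort
        one = cohort.copy()
        one["grp"] = "all"
        results, p_int = stratified_analysis(one, "latent_diet", "grp", M1)
        assert p_int is None
        plain = fit_cox(cohort, "latent_diet", M1)
        got = results["all"].levels["hr"].to_numpy()
        assert got == pytest.approx(plain.levels["hr"].to_numpy(), rel=1e-9)

    def test_multi_stratum_contract(self, analysis_cohort):
        cohort, _ = analysis_cohort
        results, p_int = stratified_analysis(cohort, "latent_diet", "smoking", M1)
        assert set(results) == {"never", "former", "current"}
        assert 0.0 <= p_int <= 1.0


class TestFoodGroups:
    def test_monotone_transform_of_exposure_has_unit_rank_correlation(
        self, analysis_cohort
    ):
        cohort, _ = analysis_cohort
        cohort = cohort.copy()
        cohort["food_a"] = np.exp(cohort["latent_diet"])
        rng = np.random.default_rng(3)
        cohort["food_b"] = rng.normal(size=len(cohort))
        scores = pd.DataFrame({"latent": cohort["latent_diet"]})
        table, corr = food_group_effects(
            cohort, ["food_a", "food_b"], scores=scores, spec=M1
        )
        assert corr.loc["food_a", "latent"] == pytest.approx(1.0)
        assert abs(corr.loc["food_b", "latent"]) < 0.1
        row_b = table.set_index("food").loc["food_b"]
        assert row_b["ci_low"] < 1.0 < row_b["ci_high"]  # null food covers 1
        assert row_b["sd"] == pytest.approx(
            cohort["food_b"].std(ddof=1), abs=1e-12
        )

    def test_constant_food_rejected(self, analysis_cohort):
        cohort, _ = analysis_cohort
        cohort = cohort.copy()
        cohort["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            food_group_effects(cohort, ["flat"], spec=M1)


class TestSubstitution:
    def test_null_foods_substitute_at_unit_hr(self, analysis_cohort):
        cohort, _ = analysis_cohort
        cohort = cohort.copy()
        rng = np.random.default_rng(9)
        cohort["food_a"] = rng.normal(size=len(cohort))
        cohort["food_b"] = rng.normal(size=len(cohort))
        m = leave_one_out_substitution(cohort, ["food_a", "food_b"], M1)
        assert m.shape == (2, 2)
        assert np.isnan(m.loc["food_a", "food_a"])
        assert m.loc["food_a", "food_b"] == pytest.approx(1.0, abs=0.15)
        assert m.loc["food_b", "food_a"] == pytest.approx(1.0, abs=0.15)

    def test_unknown_food_rejected(self, analysis_cohort):
        cohort, _ = analysis_cohort
        with pytest.raises(KeyError, match="nonexistent"):
            leave_one_out_substitution(cohort, ["latent_diet", "nonexistent"], M1)


class TestCauseSpecific:
    def test_single_cause_equals_all_cause(self):
        cohort, _ = make_analysis_cohort(
            n=3000, seed=23,
            cause_mix={"CVD": 1.0, "cancer": 0.0, "neurodegenerative": 0.0,
                       "respiratory": 0.0, "other": 0.0},
        )
        all_cause = fit_cox(cohort, "latent_diet", M1)
        cvd = cause_specific_fit(cohort, "CVD", "latent_diet", M1)
        assert cvd.levels["hr"].to_numpy() == pytest.approx(
            all_cause.levels["hr"].to_numpy(), rel=1e-9
        )
        assert cvd.levels["n_events"].sum() == all_cause.levels["n_events"].sum()

    def test_other_causes_censored(self, analysis_cohort):
        cohort, _ = analysis_cohort
        cvd = cause_specific_fit(cohort, "CVD", "latent_diet", M1)
        n_cvd = (cohort["cause"] == "CVD").sum()
        assert cvd.levels["n_events"].sum() == n_cvd

    def test_unknown_cause_rejected(self, analysis_cohort):
        cohort, _ = analysis_cohort
        with pytest.raises(ValueError, match="unknown cause"):
            cause_specific_fit(cohort, "accidents", "latent_diet", M1)
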