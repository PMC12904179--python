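import math

import numpy as np
import pandas as pd
import pytest

from dietspan.lifetable import (
    ci_monte_carlo,
    expand_prevalence,
    group_death_probabilities,
    life_expectancy,
    reference_hazard,
    run_life_expectancy,
    validate_prevalence,
    years_gained,
)


def flat_life_table(q=0.02, sexes=("male",), ages=range(40, 101)):
    return pd.concat(
        [pd.DataFrame({"sex": s, "age": list(ages), "qx": q}) for s in sexes],
        ignore_index=True,
    )


def uniform_prevalence(groups, sexes=("male",), bands=(40, 50, 60, 70, 80, 90)):
    rows = [
        {"sex": s, "age_band": b, "group": g, "prevalence": 1.0 / len(groups)}
        for s in sexes
        for b in bands
        for g in groups
    ]
    return pd.DataFrame(rows)


def constant_q_le(q, start, end=100):
    """Closed form: LE = (1 - q/2) * (1 - (1-q)^(N+1)) / q for N = end-start."""
    n_terms = end - start + 1
    return (1 - q / 2) * (1 - (1 - q) ** n_terms) / q


class TestReferenceHazard:
    def test_unit_hazard_ratios_reproduce_population_table(self):
        lt = flat_life_table(q=0.015)
        prev = uniform_prevalence(["a", "b", "c"])
        out = reference_hazard(lt, prev, {"a": 1.0, "b": 1.0, "c": 1.0}, "male")
        for g in ("a", "b", "c"):
            assert np.allclose(out[f"q_{g}"], 0.015, atol=1e-12)
        assert np.allclose(out["m_ref"], -math.log(1 - 0.015), atol=1e-12)

    def test_two_group_algebra(self):
        # m = 0.01, p = (1/2, 1/2), HR = (1, 2) -> m_ref = 0.01/1.5
        q = 1 - math.exp(-0.01)
        lt = flat_life_table(q=q)
        prev = uniform_prevalence(["ref", "exposed"])
        out = reference_hazard(lt, prev, {"ref": 1.0, "exposed": 2.0}, "male")
        assert np.allclose(out["m_ref"], 0.01 / 1.5, atol=1e-12)
        assert np.allclose(out["q_exposed"], 1 - math.exp(-0.02 / 1.5), atol=1e-12)

    def test_marginal_mortality_conserved(self):
        rng = np.random.default_rng(11)
        lt = flat_life_table(q=0.03)
        lt["qx"] = rng.uniform(0.005, 0.2, len(lt))
        groups = ["g1", "g2", "g3", "g4"]
        prev = uniform_prevalence(groups)
        p = rng.dirichlet(np.ones(4), size=6)  # random prevalences per band
        for i, b in enumerate((40, 50, 60, 70, 80, 90)):
            for j, g in enumerate(groups):
                prev.loc[
                    (prev["age_band"] == b) & (prev["group"] == g), "prevalence"
                ] = p[i, j]
        hrs = {g: hr for g, hr in zip(groups, [1.0, 0.8, 1.4, 2.2])}
        out = reference_hazard(lt, prev, hrs, "male")
        prev_wide = expand_prevalence(prev, out["age"].to_numpy(), "male")
        recon = sum(
            prev_wide[g].to_numpy()
            * (-np.log1p(-out[f"q_{g}"].to_numpy()))
            for g in groups
        )
        assert np.allclose(recon, out["m"], atol=1e-9)

    def test_missing_hr_rejected(self):
        lt = flat_life_table()
        prev = uniform_prevalence(["a", "b"])
        with pytest.raises(ValueError, match="hazard ratio"):
            reference_hazard(lt, prev, {"a": 1.0}, "male")

    def test_prevalence_not_summing_rejected(self):
        prev = uniform_prevalence(["a", "b"])
        prev.loc[0, "prevalence"] = 0.7
        with pytest.raises(ValueError, match="sum to 1"):
            validate_prevalence(prev)

    def test_missing_group_in_band_rejected(self):
        prev = uniform_prevalence(["a", "b"])
        prev.loc[(prev["age_band"] == 50) & (prev["group"] == "b"), "prevalence"] = 0
        prev.loc[(prev["age_band"] == 50) & (prev["group"] == "a"), "prevalence"] = 1
        prev = prev.drop(
            prev[(prev["age_band"] == 50) & (prev["group"] == "b")].index
        )
        with pytest.raises(ValueError, match="absent"):
            validate_prevalence(prev)


class TestLifeExpectancy:
    def test_certain_death_gives_half_year(self):
        q = pd.Series(1.0, index=range(45, 101))
        assert life_expectancy(q, 45) == pytest.approx(0.5)

    def test_no_mortality_reaches_table_close(self):
        q = pd.Series(0.0, index=range(45, 101))
        assert life_expectancy(q, 45) == pytest.approx(101 - 45)

    @pytest.mark.parametrize("qval,start", [(0.02, 45), (0.05, 50), (0.001, 60)])
    def test_constant_hazard_closed_form(self, qval, start):
        q = pd.Series(qval, index=range(start, 101))
        assert life_expectancy(q, start) == pytest.approx(
            constant_q_le(qval, start), abs=1e-9
        )

    def test_age_gap_rejected(self):
        q = pd.Series(0.01, index=[45, 46, 48, 49, 50])
        with pytest.raises(ValueError, match="missing"):
            life_expectancy(q, 45)

    def test_le_strictly_decreasing_in_hazard_ratio(self):
        lt = flat_life_table(q=0.02)
        prev = uniform_prevalence(["ref", "grp"])
        les = []
        for hr in (0.7, 1.0, 1.5, 2.5):
            out = reference_hazard(lt, prev, {"ref": 1.0, "grp": hr}, "male")
            q = pd.Series(out["q_grp"].to_numpy(), index=out["age"].to_numpy())
            les.append(life_expectancy(q, 45))
        assert all(a > b for a, b in zip(les, les[1:]))


class TestYearsGained:
    def test_antisymmetry_and_zero(self):
        assert years_gained(35.0, 35.0) == 0.0
        assert years_gained(36.0, 34.0) == -years_gained(34.0, 36.0)

    def test_protective_group_gains(self):
        lt = flat_life_table(q=0.03)
        prev = uniform_prevalence(["ref", "better"])
        out = reference_hazard(lt, prev, {"ref": 1.0, "better": 0.8}, "male")
        le = {
            g: life_expectancy(
                pd.Series(out[f"q_{g}"].to_numpy(), index=out["age"].to_numpy()), 45
            )
            for g in ("ref", "better")
        }
        assert years_gained(le["better"], le["ref"]) > 0

    def test_two_group_constant_hazard_gain_matches_closed_form(self):
        m = 0.02
        lt = flat_life_table(q=1 - math.exp(-m))
        prev = uniform_prevalence(["ref", "grp"])
        hr = 0.75
        out = reference_hazard(lt, prev, {"ref": 1.0, "grp": hr}, "male")
        m_ref = m / ((1 + hr) / 2)
        gains = []
        for rate in (m_ref, hr * m_ref):
            gains.append(constant_q_le(1 - math.exp(-rate), 45))
        got_ref = life_expectancy(
            pd.Series(out["q_ref"].to_numpy(), index=out["age"].to_numpy()), 45
        )
        got_grp = life_expectancy(
            pd.Series(out["q_grp"].to_numpy(), index=out["age"].to_numpy()), 45
        )
        assert got_grp - got_ref == pytest.approx(gains[1] - gains[0], abs=1e-9)


def hr_frame(hr, lo, hi):
    return pd.DataFrame(
        {
            "group": ["ref", "grp"],
            "hr": [1.0, hr],
            "ci_low": [1.0, lo],
            "ci_high": [1.0, hi],
        }
    )


class TestMonteCarloCI:
    def test_degenerate_ci_has_zero_width(self):
        lt = flat_life_table()
        prev = uniform_prevalence(["ref", "grp"])
        ci, _ = ci_monte_carlo(
            hr_frame(0.8, 0.8, 0.8), lt, prev, "male", 45, "ref",
            n_draws=150, seed=1,
        )
        row = ci.set_index("group").loc["grp"]
        assert row["le_ci_low"] == pytest.approx(row["le_ci_high"], abs=1e-12)
        assert row["gain_ci_low"] == pytest.approx(row["gain_ci_high"], abs=1e-12)

    def test_deterministic_given_seed_and_stable_in_draws(self):
        lt = flat_life_table()
        prev = uniform_prevalence(["ref", "grp"])
        hrs = hr_frame(0.8, 0.7, 0.92)
        a, _ = ci_monte_carlo(hrs, lt, prev, "male", 45, "ref", n_draws=400, seed=5)
        b, _ = ci_monte_carlo(hrs, lt, prev, "male", 45, "ref", n_draws=400, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c, _ = ci_monte_carlo(hrs, lt, prev, "male", 45, "ref", n_draws=800, seed=5)
        g1 = a.set_index("group").loc["grp"]
        g2 = c.set_index("group").loc["grp"]
        assert g1["gain_ci_low"] == pytest.approx(g2["gain_ci_low"], abs=0.25)
        assert g1["gain_ci_high"] == pytest.approx(g2["gain_ci_high"], abs=0.25)

    def test_low_draw_count_warns_in_metadata(self):
        lt = flat_life_table()
        prev = uniform_prevalence(["ref", "grp"])
        _, warnings = ci_monte_carlo(
            hr_frame(0.8, 0.7, 0.92), lt, prev, "male", 45, "ref",
            n_draws=50, seed=2,
        )
        assert any("n_draws" in w for w in warnings)


class TestRunLifeExpectancy:
    def test_start_age_sweep_monotone_and_reference_zero(self):
        lt = flat_life_table(q=0.02, sexes=("male", "female"))
        prev = uniform_prevalence(
            ["ref", "grp"], sexes=("male", "female")
        )
        res = run_life_expectancy(
            lt, prev, hr_frame(0.8, 0.7, 0.92), reference="ref",
            start_ages=(45, 50, 55, 60), n_draws=120, seed=3,
        )
        t = res.table
        assert set(t["sex"]) == {"male", "female"}
        for (sex, g), grp in t.groupby(["sex", "group"]):
            le = grp.sort_values("start_age")["life_expectancy"].to_numpy()
            assert (np.diff(le) < 0).all()
        ref_rows = t[t["group"] == "ref"]
        assert (ref_rows["years_gained"] == 0).all()
        assert (ref_rows["gain_ci_low"] == 0).all()
        grp_rows = t[t["group"] == "grp"]
        assert (grp_rows["years_gained"] > 0).all()
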