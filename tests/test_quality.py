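import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from hhdiet.config import default_config
from hhdiet.exceptions import ConfigError, DegenerateInputError
from hhdiet.quality import (
    NutrientRequirement,
    dds,
    mpa,
    pa_ai,
    pa_iron,
    pa_normal,
    quality_table,
    requirements_from_config,
    standardize_to_2000,
)

NORMAL_REQ = NutrientRequirement(nutrient="zinc", kind="normal_ear", ear=10.0, cv=0.1)
IRON_REQ = NutrientRequirement(
    nutrient="iron", kind="iron_full_probability",
    median_absorbed_req=1.46, log_sd=0.39, bioavailability=0.05,
)
AI_REQ = NutrientRequirement(nutrient="calcium", kind="ai_threshold", ai=1000.0)


def pa_normal_oracle(intake, ear, cv):
    """Independent oracle: numerically integrate the normal requirement
    density below the intake."""
    sd = cv * ear
    val, _ = integrate.quad(
        lambda r: np.exp(-0.5 * ((r - ear) / sd) ** 2) / (sd * np.sqrt(2 * np.pi)),
        ear - 12 * sd,
        intake,
    )
    return val


class TestStandardize:
    def test_linear_scaling(self):
        assert standardize_to_2000(10.0, 1000.0) == 20.0

    def test_identity_at_2000(self):
        assert standardize_to_2000(7.3, 2000.0) == 7.3

    def test_zero_energy_errors(self):
        with pytest.raises(DegenerateInputError):
            standardize_to_2000(1.0, 0.0)


class TestPaNormal:
    def test_at_ear_is_half(self):
        assert pa_normal(10.0, NORMAL_REQ) == 0.5

    def test_95th_percentile(self):
        # oracle-derived: intake = EAR + 1.645 SD
        assert pa_normal(10.0 + 1.645 * 1.0, NORMAL_REQ) == pytest.approx(0.95, abs=1e-4)

    def test_deep_lower_tail(self):
        assert pa_normal(0.0, NORMAL_REQ) < 1e-15

    def test_matches_integration_oracle_grid(self):
        for intake in np.linspace(0.5, 25.0, 20):
            expected = pa_normal_oracle(intake, 10.0, 0.1)
            assert pa_normal(intake, NORMAL_REQ) == pytest.approx(expected, abs=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(
        lo=st.floats(0.0, 50.0),
        delta=st.floats(0.001, 50.0),
        cv=st.floats(0.01, 0.5),
    )
    def test_monotone_in_intake(self, lo, delta, cv):
        req = NutrientRequirement(nutrient="x", kind="normal_ear", ear=10.0, cv=cv)
        assert pa_normal(lo + delta, req) >= pa_normal(lo, req)


class TestPaIron:
    def test_median_gives_half(self):
        intake = IRON_REQ.median_absorbed_req / IRON_REQ.bioavailability
        assert pa_iron(intake, IRON_REQ) == pytest.approx(0.5, abs=1e-12)

    def test_upper_tail(self):
        intake = 100 * IRON_REQ.median_absorbed_req / IRON_REQ.bioavailability
        assert pa_iron(intake, IRON_REQ) == pytest.approx(1.0, abs=1e-6)

    def test_zero_intake(self):
        assert pa_iron(0.0, IRON_REQ) == 0.0

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(2024)
        draws = IRON_REQ.median_absorbed_req * np.exp(
            IRON_REQ.log_sd * rng.standard_normal(1_000_000)
        )
        for intake in np.linspace(5.0, 120.0, 20):
            mc = float(np.mean(draws <= intake * IRON_REQ.bioavailability))
            assert pa_iron(intake, IRON_REQ) == pytest.approx(mc, abs=5e-3)

    def test_monotone_in_intake(self):
        grid = np.linspace(0.0, 200.0, 50)
        vals = [pa_iron(x, IRON_REQ) for x in grid]
        assert (np.diff(vals) >= 0).all()


class TestPaAi:
    def test_at_threshold(self):
        assert pa_ai(1000.0, AI_REQ) == 1.0

    def test_just_below(self):
        assert pa_ai(999.0, AI_REQ) == 0.0

    def test_zero(self):
        assert pa_ai(0.0, AI_REQ) == 0.0


class TestMpa:
    @pytest.fixture()
    def reqs(self):
        return requirements_from_config(default_config())

    def test_abundant_intake_maxes_out(self, reqs):
        intakes = {n: 1e6 for n in reqs}
        res = mpa(intakes, 2000.0, reqs)
        assert res["mpa"] == pytest.approx(1.0, abs=1e-9)
        assert not res["low_mpa"]

    def test_mean_of_pa_vector(self):
        # PA vector {1, 0, 0.5, 0.5} -> MPA 0.5, sits at the cutoff
        reqs = {
            "a": NutrientRequirement("a", "ai_threshold", ai=10.0),
            "b": NutrientRequirement("b", "ai_threshold", ai=10.0),
            "c": NutrientRequirement("c", "normal_ear", ear=5.0, cv=0.1),
            "d": NutrientRequirement("d", "normal_ear", ear=7.0, cv=0.2),
        }
        intakes = {"a": 20.0, "b": 0.0, "c": 5.0, "d": 7.0}
        res = mpa(intakes, 2000.0, reqs, nutrients=("a", "b", "c", "d"))
        assert res["mpa"] == 0.5
        assert not res["low_mpa"]  # cutoff is strict: flag only below 0.5

    def test_standardizes_before_pa(self, reqs):
        intakes = {n: 5.0 for n in reqs}
        res_1000 = mpa(intakes, 1000.0, reqs)
        doubled = {n: 10.0 for n in reqs}
        res_2000 = mpa(doubled, 2000.0, reqs)
        assert res_1000["mpa"] == pytest.approx(res_2000["mpa"], rel=1e-12)

    def test_energy_density_invariance(self, reqs, rng):
        intakes = {n: float(v) for n, v in zip(reqs, rng.uniform(1, 500, len(reqs)))}
        base = mpa(intakes, 1700.0, reqs)
        factor = 3.7
        scaled = mpa({n: v * factor for n, v in intakes.items()}, 1700.0 * factor, reqs)
        assert scaled["mpa"] == pytest.approx(base["mpa"], rel=1e-12)

    def test_permutation_invariance(self, reqs, rng):
        intakes = {n: float(v) for n, v in zip(reqs, rng.uniform(1, 500, len(reqs)))}
        order = list(reqs)
        res1 = mpa(intakes, 2000.0, reqs, nutrients=order)
        res2 = mpa(intakes, 2000.0, reqs, nutrients=order[::-1])
        assert res1["mpa"] == pytest.approx(res2["mpa"], rel=1e-15)

    def test_missing_requirement_named(self, reqs):
        intakes = {n: 1.0 for n in reqs}
        intakes["selenium"] = 1.0
        with pytest.raises(ConfigError, match="selenium"):
            mpa(intakes, 2000.0, reqs, nutrients=list(reqs) + ["selenium"])

    def test_fixture_matches_per_nutrient_oracle(self, worked_example, reqs):
        """Brute-force oracle: compute each PA with scipy directly."""
        from hhdiet.afe import per_afe_intake

        we = worked_example
        p = per_afe_intake(we.households[0], we.consumption, we.fct, we.groupmap, we.ereq)
        res = mpa(p.nutrient_intake, p.energy, reqs)
        expected = []
        for n, req in reqs.items():
            x = p.nutrient_intake[n] * 2000.0 / p.energy
            if req.kind == "normal_ear":
                expected.append(stats.norm.cdf((x - req.ear) / (req.cv * req.ear)))
            elif req.kind == "iron_full_probability":
                absorbed = x * req.bioavailability
                expected.append(
                    stats.norm.cdf(
                        (np.log(absorbed) - np.log(req.median_absorbed_req)) / req.log_sd
                    )
                )
            else:
                expected.append(1.0 if x >= req.ai else 0.0)
        assert res["mpa"] == pytest.approx(np.mean(expected), rel=1e-12)


class TestDds:
    def test_worked_example_hand_counts(self, worked_example):
        from hhdiet.afe import per_afe_intake

        we = worked_example
        for hh in we.households:
            p = per_afe_intake(hh, we.consumption, we.fct, we.groupmap, we.ereq)
            score, met = dds(p.item_intake, we.groupmap)
            assert score == we.expected["dds"][hh.household_id]
            assert met == we.expected["mdd_met"][hh.household_id]

    def test_exactly_15g_scores(self, worked_example):
        score, met = dds({"I01": 15.0}, worked_example.groupmap)
        assert score == 1
        assert not met

    def test_just_below_threshold_everywhere(self, worked_example):
        gm = worked_example.groupmap
        # one item per MDD-W group at 14.9 g
        items = {}
        for code in gm.index:
            g = gm.loc[code, "mddw_group"]
            if isinstance(g, str) and g not in [
                gm.loc[c, "mddw_group"] for c in items
            ]:
                items[code] = 14.9
        score, met = dds(items, gm)
        assert score == 0 and not met

    def test_all_groups_max(self, small_survey):
        gm = small_survey["groupmap"]
        items = {code: 100.0 for code in gm.index}
        score, met = dds(items, gm)
        assert score == 10 and met

    def test_condiment_contributes_nothing(self, worked_example):
        score, _ = dds({"I12": 500.0}, worked_example.groupmap)
        assert score == 0

    def test_small_addition_stability(self, worked_example):
        """Adding < 15 g to an empty group never changes DDS; >= 15 g adds
        at most one point."""
        gm = worked_example.groupmap
        base_items = {"I01": 100.0}
        base, _ = dds(base_items, gm)
        with_small = dict(base_items, I08=14.0)
        assert dds(with_small, gm)[0] == base
        with_large = dict(base_items, I08=15.0)
        assert dds(with_large, gm)[0] == base + 1


class TestQualityTable:
    def test_matches_scalar_path(self, small_survey):
        from hhdiet.afe import per_afe_intake

        s = small_survey
        reqs = requirements_from_config(default_config())
        table = quality_table(s["per_afe"], s["items"], s["groupmap"], reqs)
        assert len(table) == len(s["households"])
        assert table["mpa"].between(0, 1).all()
        assert table["dds"].between(0, 10).all()
        assert (table["mdd_met"] == (table["dds"] >= 5)).all()
        hh = s["households"][42]
        p = per_afe_intake(hh, s["consumption"], s["fct"], s["groupmap"],
                           __import__("hhdiet.afe", fromlist=["EnergyRequirementTable"])
                           .EnergyRequirementTable.default())
        row = table[table["household_id"] == hh.household_id].iloc[0]
        scalar = mpa(p.nutrient_intake, p.energy, reqs)
        assert row["mpa"] == pytest.approx(scalar["mpa"], rel=1e-12)
        assert row["dds"] == dds(p.item_intake, s["groupmap"])[0]
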