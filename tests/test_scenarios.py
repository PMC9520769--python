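"""Scenario registry, geometry validity, serialization and random fixtures."""

import pytest
from hypothesis import given, settings, strategies as st

from npmicroenv import (
    CultureScenario,
    ScenarioBounds,
    named_scenario,
    random_scenario,
    scenario_names,
    vessel,
)
from npmicroenv.exceptions import ScenarioError, ScenarioLookupError


class TestRegistry:
    def test_registry_size(self):
        assert len(scenario_names()) >= 20

    def test_single_bead_configuration(self):
        s = named_scenario("bead_24w_LG_NX_8M")
        assert s.construct.sphere_radius_mm == pytest.approx(1.93, abs=0.005)
        assert s.vessel.media_volume_ml == 2.0
        assert s.glucose_mm == 5.5
        assert s.construct.density_mcells_per_ml == 8.0

    def test_cylindrical_construct_configuration(self):
        s = named_scenario("cyl_3mm_20M_PX")
        assert s.construct.radius_mm == 2.5
        assert s.construct.height_mm == 3.0
        assert s.construct.density_mcells_per_ml == 20.0
        assert s.params.oxygen_regime == "PX"

    def test_pellet_configuration(self):
        s = named_scenario("pellet_eppendorf_250k")
        assert s.construct.cell_count == 250_000
        assert s.vessel.media_volume_ml == 1.0
        assert s.vessel.shape == "truncated_cone"
        assert s.glucose_mm == 25.0  # pellet culture literature reports HG only

    def test_unknown_name_lists_valid_ids(self):
        with pytest.raises(ScenarioLookupError, match="bead_24w_LG_NX_8M"):
            named_scenario("no_such_scenario")

    def test_all_entries_pass_geometric_validity(self):
        for name in scenario_names():
            s = named_scenario(name)
            s.validate()  # raises on any invariant violation
            if s.construct is not None:
                total = s.construct_count * s.construct.construct_volume_ul
                assert total < s.vessel.media_volume_ml * 1000.0

    def test_vessel_working_volumes(self):
        # standard working volumes used by the monolayer models
        for kind, volume in (("well6", 2.0), ("T25", 5.0), ("T75", 10.0), ("T175", 20.0)):
            assert vessel(kind).media_volume_ml == volume

    def test_eppendorf_fill_height(self):
        v = vessel("eppendorf")
        h = v.fill_height_mm()
        # 1 ml fills a 1.5 ml conical tube most of the way up
        assert 25.0 < h < 45.0
        assert float(v.radius_at_mm(h)) > v.cone_tip_radius_mm


class TestSerialization:
    @pytest.mark.parametrize(
        "name",
        ["bead_24w_LG_NX_8M", "mono_T175_HG_HX_deg", "cyl_1p5mm_20M_HX_HG",
         "pellet_eppendorf_250k", "beads10_12w_HG_PX"],
    )
    def test_yaml_round_trip_identity(self, name):
        s = named_scenario(name)
        assert CultureScenario.from_yaml(s.to_yaml()) == s

    def test_json_export_is_deterministic(self):
        s = named_scenario("bead_24w_LG_NX_4M")
        assert s.to_json() == s.to_json()


class TestRandomScenarios:
    def test_deterministic_for_seed(self):
        assert random_scenario(7) == random_scenario(7)

    def test_batch_validity(self):
        for seed in range(100):
            s = random_scenario(seed)
            s.validate()

    def test_zero_density_bound_gives_null_metabolism(self):
        bounds = ScenarioBounds(density_mcells_per_ml=(0.0, 0.0), kinds=("bead",))
        s = random_scenario(3, bounds)
        assert s.construct.density_mcells_per_ml == 0.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ScenarioError):
            ScenarioBounds(density_mcells_per_ml=(0.0, 80.0)).validate()
        with pytest.raises(ScenarioError):
            ScenarioBounds(media_volume_ml=(0.0, 1.0)).validate()

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_any_seed_yields_valid_scenario(self, seed):
        s = random_scenario(seed)
        assert s.seed == seed
        s.validate()


class TestScheduleInvariants:
    def test_exchange_times_must_increase(self):
        s = named_scenario("bead_24w_LG_NX_4M")
        import dataclasses

        with pytest.raises(ScenarioError):
            dataclasses.replace(s, exchange_times_d=(2.0, 1.0))
        with pytest.raises(ScenarioError):
            dataclasses.replace(s, exchange_times_d=(5.0,), horizon_d=3.0)
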