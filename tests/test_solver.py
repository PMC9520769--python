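"""Transient and steady solver behaviour: oracles, conservation, events,
monotonicity and determinism."""

import dataclasses

import numpy as np
import pytest

from npmicroenv import (
    BufferModel,
    SolverOptions,
    apply_media_exchange,
    build_mesh,
    build_spherical_mesh,
    compartment_multibead,
    dissolved_oxygen,
    metabolic_params,
    named_scenario,
    percent_o2_equivalent,
    run_transient,
    steady_state,
)
from npmicroenv.mesh import build_slab_mesh
from npmicroenv.scenarios import ALGINATE_DIFFUSIVITIES, MEDIA_DIFFUSIVITIES
from npmicroenv.solver import oxygen_flux_balance, steady_oxygen_field


def _min_o2_percent(result):
    state = result.pre_exchange_snapshot()
    mask = result.mesh.region == 1
    return percent_o2_equivalent(state.o2_um[mask].min(), result.scenario.environment)


@pytest.fixture(scope="module")
def bead_run(coarse_options):
    return run_transient(named_scenario("bead_24w_LG_NX_8M"), options=coarse_options)


class TestClosedFormOracles:
    def test_zero_order_sphere(self):
        """Centre-to-surface deficit of a uniformly consuming sphere is
        q R^2 / (6 D)."""
        radius_mm, q_um_h = 1.93, 100.0
        mesh = build_spherical_mesh(radius_mm, ALGINATE_DIFFUSIVITIES, n=100)
        c = steady_oxygen_field(mesh, 180.0, np.full(mesh.n_cells, q_um_h), 1e-9)
        analytic = (q_um_h / 3600.0) * (radius_mm * 1e-3) ** 2 / (
            6.0 * ALGINATE_DIFFUSIVITIES["o2"]
        )
        assert 180.0 - c[0] == pytest.approx(analytic, rel=0.01)

    def test_zero_order_slab_with_media_column(self):
        """Base deficit of a consuming layer of thickness h under a media
        column: q h^2/(2 D_c) + q h (L - h)/D_m."""
        length_mm, h_mm, q = 5.0, 1.0, 120.0
        mesh = build_slab_mesh(
            length_mm, 1.9, MEDIA_DIFFUSIVITIES, construct_height_mm=h_mm, n=200
        )
        for s in mesh.diff:
            mesh.diff[s][mesh.frac > 0] = ALGINATE_DIFFUSIVITIES[s]
        c = steady_oxygen_field(mesh, 180.0, np.where(mesh.frac > 0, q, 0.0), 1e-9)
        qs, hm, lm = q / 3600.0, h_mm * 1e-3, length_mm * 1e-3
        analytic = qs * hm**2 / (2 * ALGINATE_DIFFUSIVITIES["o2"]) + qs * hm * (
            lm - hm
        ) / MEDIA_DIFFUSIVITIES["o2"]
        assert 180.0 - c[0] == pytest.approx(analytic, rel=0.01)

    def test_monolayer_flux_deficit(self):
        """A constant areal flux j across a media column of height L gives
        the steady surface deficit j L / D."""
        s = named_scenario("mono_well6_LG_NX")
        # constant population and saturated, pH-independent kinetics
        pop = dataclasses.replace(
            s.population, areal_density0=28571.0, growth_rate_per_day=0.0
        )
        params = metabolic_params("NX", ocr_km_um=1e-6)
        s = dataclasses.replace(
            s, population=pop, params=params,
            buffer=BufferModel(slope_ph_per_mm=0.0),
        )
        mesh = build_mesh(s, resolution=40)
        state = steady_state(s, mesh=mesh)
        bc = dissolved_oxygen(s.environment)
        j = 28571 / 1e6 * 17.0 * (7.4 - 4.95)  # nmol/cm^2/h
        j_si = j * 1e-9 * 1e4 / 3600.0  # mol/m^2/s
        length = mesh.total_volume_m3 / mesh.base_area_m2
        analytic_um = j_si * length / MEDIA_DIFFUSIVITIES["o2"] * 1e3
        assert bc - state.o2_um[mesh.base_cell] == pytest.approx(analytic_um, rel=0.01)


class TestConservation:
    def test_glucose_and_lactate_ledger_balance(self, bead_run):
        led = bead_run.ledger[0]
        for inv, flow, sign in (
            ("glucose", "glucose_consumed", -1.0),
            ("lactate", "lactate_produced", +1.0),
        ):
            change = led["final"][inv] - led["initial"][inv]
            assert change == pytest.approx(sign * led[flow], rel=1e-3, abs=1e-18)

    def test_oxygen_inventory_matches_influx_minus_consumption(self, bead_run):
        led = bead_run.ledger[0]
        change = led["final"]["o2"] - led["initial"]["o2"]
        assert change == pytest.approx(
            led["o2_influx"] - led["o2_consumed"], rel=1e-6, abs=1e-15
        )

    def test_steady_flux_balance(self, coarse_options):
        s = named_scenario("bead_24w_LG_NX_4M")
        mesh = build_mesh(s, resolution=16)
        state = steady_state(s, mesh=mesh, options=coarse_options)
        influx, consumed = oxygen_flux_balance(s, mesh, state)
        assert influx == pytest.approx(consumed, rel=5e-3)


class TestNullAndEvents:
    def test_zero_density_fields_stay_at_boundary_values(self, coarse_options):
        s = named_scenario("bead_24w_LG_NX_4M")
        s = dataclasses.replace(
            s, construct=dataclasses.replace(s.construct, density_mcells_per_ml=0.0)
        )
        r = run_transient(s, options=coarse_options)
        final = r.states[-1]
        bc = dissolved_oxygen(s.environment)
        assert final.o2_um == pytest.approx(bc, rel=1e-9)
        assert final.glucose_mm == pytest.approx(s.glucose_mm, rel=1e-9)
        assert np.all(final.lactate_mm == 0.0)

    def test_media_exchange_resets_media_only(self, bead_run):
        s = bead_run.scenario
        state = bead_run.pre_exchange_snapshot()
        fresh = apply_media_exchange(state, s, bead_run.mesh)
        media = bead_run.mesh.region == 0
        construct = ~media
        assert np.all(fresh.glucose_mm[media] == s.glucose_mm)
        assert np.all(fresh.lactate_mm[media] == 0.0)
        assert np.all(fresh.o2_um[media] == dissolved_oxygen(s.environment))
        assert np.array_equal(fresh.glucose_mm[construct], state.glucose_mm[construct])
        assert np.array_equal(fresh.lactate_mm[construct], state.lactate_mm[construct])

    def test_media_exchange_idempotent(self, bead_run):
        state = bead_run.pre_exchange_snapshot()
        once = apply_media_exchange(state, bead_run.scenario, bead_run.mesh)
        twice = apply_media_exchange(once, bead_run.scenario, bead_run.mesh)
        for attr in ("o2_um", "glucose_mm", "lactate_mm"):
            assert np.array_equal(getattr(once, attr), getattr(twice, attr))

    def test_positivity(self, coarse_options):
        # deep-depletion scenario stays non-negative everywhere
        r = run_transient(named_scenario("bead_24w_LG_NX_8M_deg"), options=coarse_options)
        for st in r.states:
            assert st.o2_um.min() >= 0.0
            assert st.glucose_mm.min() >= 0.0
            assert st.lactate_mm.min() >= 0.0


class TestCrossValidation:
    def test_transient_approaches_steady_state(self, coarse_options):
        # with a rigid (zero-slope) buffer the day-3 transient oxygen field
        # matches the steady solve of the same discretisation
        s = named_scenario("bead_24w_LG_NX_4M")
        s = dataclasses.replace(s, buffer=BufferModel(slope_ph_per_mm=0.0))
        mesh = build_mesh(s, resolution=16)
        steady = steady_state(s, mesh=mesh)
        transient = run_transient(s, mesh=mesh, options=coarse_options)
        mask = mesh.region == 1
        a = percent_o2_equivalent(steady.o2_um[mask].min(), s.environment)
        b = percent_o2_equivalent(
            transient.pre_exchange_snapshot().o2_um[mask].min(), s.environment
        )
        assert a == pytest.approx(b, abs=0.1)

    def test_compartment_matches_axisymmetric_single_bead(self, coarse_options):
        s = dataclasses.replace(
            named_scenario("beads4_12w_LG_NX"), construct_count=1
        )
        ax = run_transient(s, options=coarse_options)
        cp = compartment_multibead(s, options=coarse_options)
        ax_state, cp_state = ax.pre_exchange_snapshot(), cp.pre_exchange_snapshot()
        ax_mask, cp_mask = ax.mesh.region == 1, cp.mesh.region == 1
        d_o2 = abs(
            percent_o2_equivalent(ax_state.o2_um[ax_mask].min(), s.environment)
            - percent_o2_equivalent(cp_state.o2_um[cp_mask].min(), s.environment)
        )
        d_glc = abs(
            ax_state.glucose_mm[ax_mask].min() - cp_state.glucose_mm[cp_mask].min()
        )
        assert d_o2 <= 1.5
        assert d_glc <= 0.3


class TestMultibead:
    def test_more_beads_deplete_further(self, coarse_options):
        minima = {}
        for n in (4, 10):
            r = run_transient(named_scenario(f"beads{n}_12w_LG_NX"), options=coarse_options)
            st = r.pre_exchange_snapshot()
            mask = r.mesh.region == 1
            ph = np.asarray(st.ph(r.scenario.buffer))
            minima[n] = (float(st.glucose_mm[mask].min()), float(ph[mask].min()))
        assert minima[10][0] < minima[4][0]
        assert minima[10][1] < minima[4][1]

    def test_zero_density_beads_do_not_deplete(self, coarse_options):
        s = named_scenario("beads10_12w_LG_NX")
        s = dataclasses.replace(
            s, construct=dataclasses.replace(s.construct, density_mcells_per_ml=0.0)
        )
        r = run_transient(s, options=coarse_options)
        final = r.states[-1]
        assert final.glucose_mm == pytest.approx(s.glucose_mm, rel=1e-9)
        assert np.all(final.lactate_mm == 0.0)


class TestMonotonicityAndDeterminism:
    def test_minimum_oxygen_decreases_with_density_and_vmax(self, quick_options):
        base = named_scenario("bead_24w_LG_NX_4M")
        def min_o2(density=4.0, vmax=17.0):
            s = dataclasses.replace(
                base,
                construct=dataclasses.replace(base.construct, density_mcells_per_ml=density),
                params=dataclasses.replace(base.params, ocr_vmax=vmax),
                construct_count=1,
            )
            return _min_o2_percent(compartment_multibead(s, options=quick_options))

        by_density = [min_o2(density=d) for d in (2.0, 4.0, 8.0)]
        assert by_density[0] > by_density[1] > by_density[2]
        by_vmax = [min_o2(vmax=v) for v in (17.0, 35.0, 62.0)]
        assert by_vmax[0] > by_vmax[1] > by_vmax[2]

    def test_bit_identical_reruns(self, quick_options):
        s = named_scenario("bead_24w_LG_NX_4M")
        r1 = run_transient(s, options=quick_options)
        r2 = run_transient(s, options=quick_options)
        assert np.array_equal(r1.times_h, r2.times_h)
        for a, b in zip(r1.states, r2.states):
            assert np.array_equal(a.o2_um, b.o2_um)
            assert np.array_equal(a.glucose_mm, b.glucose_mm)
            assert np.array_equal(a.lactate_mm, b.lactate_mm)


class TestMonolayer:
    def test_surface_oxygen_declines_with_confluency(self, coarse_options):
        from npmicroenv.reporting import cell_surface_series

        r = run_transient(named_scenario("mono_well6_LG_NX_deg"), options=coarse_options)
        series = cell_surface_series(r)
        bc = percent_o2_equivalent(
            dissolved_oxygen(r.scenario.environment), r.scenario.environment
        )
        assert series["o2_percent"].iloc[0] == pytest.approx(bc, abs=0.05)
        # strictly lower at confluency than at seeding
        assert series["o2_percent"].iloc[-1] < series["o2_percent"].iloc[0]
        # glucose falls, lactate rises, pH falls
        assert series["glucose_mM"].iloc[-1] < series["glucose_mM"].iloc[0]
        assert series["pH"].iloc[-1] < 7.4
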