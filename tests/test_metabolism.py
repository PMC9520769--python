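"""Cell-level rate laws: OCR, GCR, LPR, pH buffer and proliferation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npmicroenv import (
    BufferModel,
    CellPopulation,
    gcr,
    growth_rate_from_doubling,
    lpr,
    metabolic_params,
    ocr,
    ph_from_lactate,
    population,
)
from npmicroenv.exceptions import DomainError
from npmicroenv.metabolism import DEFAULT_EXPANSION, lpr_ph_multiplier


@pytest.fixture(scope="module")
def animal_nx():
    return metabolic_params("NX", "LG", "animal_healthy")


class TestOCR:
    def test_tabulated_vmax_parameter(self, animal_nx):
        assert animal_nx.ocr_vmax == 17.0
        assert metabolic_params(phenotype="degenerated").ocr_vmax == 62.0

    def test_saturating_rate_at_reference_ph(self, animal_nx):
        # Vmax * (7.4 - 4.95) at saturating oxygen
        assert ocr(1e9, 7.4, animal_nx) == pytest.approx(17.0 * 2.45, rel=1e-6)

    def test_acidic_shutoff(self, animal_nx):
        assert ocr(100.0, 4.95, animal_nx) == 0.0
        assert ocr(100.0, 4.0, animal_nx) == 0.0

    def test_half_saturation_at_effective_km(self, animal_nx):
        km_eff = 12.0 * (7.4 - 4.59)
        assert ocr(km_eff, 7.4, animal_nx) == pytest.approx(17.0 * 2.45 / 2)

    def test_negative_oxygen_rejected(self, animal_nx):
        with pytest.raises(DomainError):
            ocr(-1.0, 7.4, animal_nx)

    @settings(max_examples=50, derandomize=True)
    @given(
        o2=st.floats(0.0, 300.0),
        d_o2=st.floats(0.1, 100.0),
        ph=st.floats(5.0, 7.4),
        d_ph=st.floats(0.01, 1.0),
    )
    def test_monotone_in_oxygen_and_ph(self, o2, d_o2, ph, d_ph):
        p = metabolic_params()
        assert ocr(o2 + d_o2, ph, p) >= ocr(o2, ph, p)
        assert ocr(o2, min(ph + d_ph, 7.4), p) >= ocr(o2, ph, p)


class TestGCR:
    @pytest.mark.parametrize("regime,vmax", [("NX", 143.0), ("PX", 103.0), ("HX", 165.0)])
    def test_regime_vmax(self, regime, vmax):
        p = metabolic_params(regime)
        assert gcr(1e9, p) == pytest.approx(vmax, rel=1e-6)

    def test_half_saturation_at_2mM(self):
        assert gcr(2.0, metabolic_params("NX")) == pytest.approx(71.5)

    def test_zero_glucose(self):
        assert gcr(0.0, metabolic_params()) == 0.0

    def test_negative_glucose_rejected(self):
        with pytest.raises(DomainError):
            gcr(-0.1, metabolic_params())


class TestLPR:
    def test_ratio_times_gcr_at_fresh_ph(self):
        p = metabolic_params("NX")
        assert lpr(1e9, 7.4, p) == pytest.approx(1.4 * 143.0, rel=1e-6)  # ~200

    def test_measured_acidic_rates(self):
        # ~150 nmol/1e6 cells/h at pH 6.7 and ~50 at pH 6.2
        p = metabolic_params("NX")
        assert lpr(1e9, 6.7, p) == pytest.approx(150.0, abs=1.0)
        assert lpr(1e9, 6.2, p) == pytest.approx(50.0, abs=1.0)

    def test_zero_glucose(self):
        assert lpr(0.0, 7.4, metabolic_params()) == 0.0

    def test_regime_ordering(self):
        # lac:gluc ratio orders HX > PX > NX; the LPR itself is highest
        # under hypoxia and lowest under physioxia (no positive Pasteur
        # effect in the compiled rates: PX carries the lowest GCR)
        params = {r: metabolic_params(r) for r in ("NX", "PX", "HX")}
        ratios = [params[r].lac_gluc_ratio for r in ("NX", "PX", "HX")]
        assert ratios[2] > ratios[1] > ratios[0]
        rates = {r: lpr(3.0, 7.2, p) for r, p in params.items()}
        assert rates["HX"] > rates["NX"] > rates["PX"]

    def test_multiplier_clamped(self):
        p = metabolic_params()
        assert lpr_ph_multiplier(8.0, p) == 1.0
        assert lpr_ph_multiplier(5.0, p) == 0.25

    def test_ratio_recovered_exactly_above_reference_ph(self):
        p = metabolic_params("PX")
        for glc in (0.5, 2.0, 10.0):
            assert lpr(glc, 7.4, p) / gcr(glc, p) == pytest.approx(1.6, rel=1e-12)

    def test_table_mode_uses_independent_vmax(self):
        p = metabolic_params("NX", lpr_mode="table")
        assert lpr(1e9, 7.4, p) == pytest.approx(207.0, rel=1e-6)


class TestBuffer:
    def test_fresh_media(self):
        assert ph_from_lactate(0.0) == 7.4

    def test_linear_slope_then_floor(self):
        b = BufferModel(slope_ph_per_mm=0.2, floor=6.0)
        assert ph_from_lactate(2.0, b) == pytest.approx(7.0)
        assert ph_from_lactate(100.0, b) == 6.0

    @settings(max_examples=30, derandomize=True)
    @given(lac=st.floats(0.0, 50.0), d=st.floats(0.0, 5.0))
    def test_monotone_decreasing(self, lac, d):
        assert ph_from_lactate(lac + d) <= ph_from_lactate(lac)


class TestProliferation:
    def test_initial_count(self):
        assert population(0.0, DEFAULT_EXPANSION) == 5000.0

    def test_expansion_reaches_confluency_density(self):
        # 5e3 cells/cm^2 at k = 0.348/d gives ~28571 cells/cm^2 in 5 days
        assert population(5.0, DEFAULT_EXPANSION) == pytest.approx(28571, rel=5e-3)

    def test_confluency_cap(self):
        assert population(30.0, DEFAULT_EXPANSION) == DEFAULT_EXPANSION.confluency_cap

    def test_doubling_time(self):
        assert math.log(2) / 0.348 == pytest.approx(1.99, abs=0.01)

    def test_growth_rate_closed_form(self):
        k = growth_rate_from_doubling(5000, 28571, 5.0)
        assert k == pytest.approx(0.3486, abs=5e-4)

    def test_growth_rate_degenerate_and_slow(self):
        assert growth_rate_from_doubling(5000, 5000, 3.0) == 0.0
        # slower doubling to 80% confluency in ~13.5 days
        assert growth_rate_from_doubling(5000, 28571, 13.5) == pytest.approx(0.129, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            growth_rate_from_doubling(0, 28571, 5.0)
        with pytest.raises(DomainError):
            growth_rate_from_doubling(5000, 28571, 0.0)
        with pytest.raises(DomainError):
            CellPopulation(growth_rate_per_day=-0.1)
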