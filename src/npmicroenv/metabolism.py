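"""Cell-level metabolic rate laws for nucleus pulposus cells.

Per-cell rates (nmol per million cells per hour) follow Michaelis-Menten
kinetics with environmental coupling:

* **OCR** (oxygen consumption) follows the pH-coupled Michaelis-Menten
  law established for disc cells,
  ``OCR = Vmax * (pH - 4.95) * C / (Km * (pH - 4.59) + C)``:
  both the effective maximal rate and the effective half-saturation
  constant scale with local pH, so respiration shuts down as the
  microenvironment acidifies toward pH ~5.  ``Km = 12 uM``; a "lower"
  Vmax of 17 describes animal and healthy human cells, a "higher" Vmax of
  62 the degenerated human phenotype.
* **GCR** (glucose consumption) saturates with ``Km = 2 mM``; its Vmax
  depends on the external oxygen setting (NX 143, PX 103, HX 165).
* **LPR** (lactate production) is tied to glycolysis through the lac:gluc
  ratio of the oxygen setting (NX 1.4, PX 1.6, HX 1.8) and is reduced at
  acidic pH through a piecewise-linear multiplier anchored at
  (7.4, 1.0), (6.7, 0.75), (6.2, 0.25) and clamped to [0.25, 1].

Local pH is derived from lactate accumulation with a single-slope linear
buffer model, and monolayer expansion follows first-order proliferation
kinetics ``N(t) = N0 * exp(k t)`` capped at confluency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

from .exceptions import DomainError

OXYGEN_REGIMES = ("NX", "PX", "HX")
GLUCOSE_REGIMES = ("LG", "HG")
PHENOTYPES = ("animal_healthy", "degenerated")

#: Saturating OCR Vmax, nmol/10^6 cells/h, by phenotype.
OCR_VMAX = {"animal_healthy": 17.0, "degenerated": 62.0}
#: GCR Vmax, nmol/10^6 cells/h, keyed by external oxygen setting.
GCR_VMAX = {"NX": 143.0, "PX": 103.0, "HX": 165.0}
#: lac:gluc production ratio keyed by external oxygen setting.
LAC_GLUC_RATIO = {"NX": 1.4, "PX": 1.6, "HX": 1.8}
#: Independently tabulated LPR Vmax (optional alternative to ratio * GCR).
LPR_VMAX = {"NX": 207.0, "PX": 168.0, "HX": 296.0}

#: pH anchors for the LPR multiplier: 1.0 at pH 7.4, 0.75 at 6.7, 0.25 at 6.2.
DEFAULT_LPR_PH_ANCHORS = ((6.2, 0.25), (6.7, 0.75), (7.4, 1.0))

#: Frozen slope of the linear lactate -> pH buffer model (pH units per mM
#: lactate).  Calibrated once against the bead solver so that a 30 ul
#: alginate bead with 8e6 cells/ml under HX/LG reaches a minimum pH of
#: ~7.0 at the day-3 pre-exchange snapshot.
BUFFER_SLOPE_PH_PER_MM = 0.140


@dataclass(frozen=True)
class MetabolicParams:
    """Rate constants for one (oxygen regime, glucose regime, phenotype) cell.

    ``lpr_mode`` selects between the default coupling of lactate production
    to instantaneous glycolysis (``"ratio"``: LPR = ratio * GCR * m(pH)) and
    the independently tabulated saturating LPR (``"table"``).
    """

    oxygen_regime: str = "NX"
    glucose_regime: str = "LG"
    phenotype: str = "animal_healthy"
    ocr_vmax: float = OCR_VMAX["animal_healthy"]
    ocr_km_um: float = 12.0
    ocr_ph_offset: float = 4.95
    ocr_km_ph_offset: float = 4.59
    ocr_ph_ref: float = 7.4
    gcr_vmax: float = GCR_VMAX["NX"]
    gcr_km_mm: float = 2.0
    lac_gluc_ratio: float = LAC_GLUC_RATIO["NX"]
    lpr_vmax: float = LPR_VMAX["NX"]
    lpr_mode: str = "ratio"
    lpr_ph_anchors: tuple = DEFAULT_LPR_PH_ANCHORS

    def __post_init__(self) -> None:
        if min(self.ocr_vmax, self.gcr_vmax, self.ocr_km_um, self.gcr_km_mm) <= 0:
            raise DomainError("all Vmax and Km values must be positive")
        if not 1.0 <= self.lac_gluc_ratio <= 2.0:
            raise DomainError("lac:gluc ratio must lie in [1, 2]")
        phs = [a[0] for a in self.lpr_ph_anchors]
        mults = [a[1] for a in self.lpr_ph_anchors]
        if sorted(phs) != phs or sorted(mults) != mults:
            raise DomainError("LPR pH anchors must be monotone non-decreasing")
        if self.lpr_mode not in ("ratio", "table"):
            raise DomainError(f"unknown lpr_mode {self.lpr_mode!r}")


def metabolic_params(
    oxygen_regime: str = "NX",
    glucose_regime: str = "LG",
    phenotype: str = "animal_healthy",
    **overrides,
) -> MetabolicParams:
    """Look up the default parameter set for a boundary-condition regime.

    The registry carries one glycolytic column per oxygen setting; the HG
    regimes reuse the LG constants (no clear difference between 5.5 and
    25 mM media exists in the compiled measurements) but any constant can
    be overridden by keyword.
    """
    ox = oxygen_regime.upper()
    if ox not in OXYGEN_REGIMES:
        raise DomainError(f"unknown oxygen regime {oxygen_regime!r}")
    if glucose_regime.upper() not in GLUCOSE_REGIMES:
        raise DomainError(f"unknown glucose regime {glucose_regime!r}")
    if phenotype not in PHENOTYPES:
        raise DomainError(f"unknown phenotype {phenotype!r}")
    params = MetabolicParams(
        oxygen_regime=ox,
        glucose_regime=glucose_regime.upper(),
        phenotype=phenotype,
        ocr_vmax=OCR_VMAX[phenotype],
        gcr_vmax=GCR_VMAX[ox],
        lac_gluc_ratio=LAC_GLUC_RATIO[ox],
        lpr_vmax=LPR_VMAX[ox],
    )
    return replace(params, **overrides) if overrides else params


def ocr_coefficients(ph, params: MetabolicParams):
    """pH-dependent pieces of the OCR law.

    Returns ``(ph_factor, km_eff_um)`` such that the per-cell rate is
    ``Vmax * ph_factor * C / (km_eff + C)``.  The pH factor
    ``max(pH - 4.95, 0)`` vanishes at the acidic shut-off, and the
    effective half-saturation constant is ``Km * (pH - 4.59)``.
    """
    ph = np.asarray(ph, dtype=float)
    ph_factor = np.clip(ph - params.ocr_ph_offset, 0.0, None)
    km_eff = params.ocr_km_um * np.clip(ph - params.ocr_km_ph_offset, 1e-9, None)
    return ph_factor, km_eff


def ocr(o2_um, ph, params: MetabolicParams):
    """Oxygen consumption rate, nmol/10^6 cells/h.

    ``Vmax * (pH - 4.95) * C / (Km * (pH - 4.59) + C)``, clamped at zero
    for pH at or below the shut-off offset.  At the fresh-media reference
    pH of 7.4 the saturating rate is ``Vmax * 2.45``.  Vectorized over
    ``o2_um`` and ``ph``.
    """
    o2_um = np.asarray(o2_um, dtype=float)
    if np.any(o2_um < 0):
        raise DomainError("oxygen concentration must be non-negative")
    ph_factor, km_eff = ocr_coefficients(ph, params)
    rate = params.ocr_vmax * ph_factor * o2_um / (km_eff + o2_um)
    return rate if rate.ndim else float(rate)


def gcr(glucose_mm, params: MetabolicParams):
    """Glucose consumption rate, nmol/10^6 cells/h: ``Vmax * C/(Km + C)``."""
    glucose_mm = np.asarray(glucose_mm, dtype=float)
    if np.any(glucose_mm < 0):
        raise DomainError("glucose concentration must be non-negative")
    rate = params.gcr_vmax * glucose_mm / (params.gcr_km_mm + glucose_mm)
    return rate if rate.ndim else float(rate)


def lpr_ph_multiplier(ph, params: MetabolicParams):
    """Piecewise-linear acidity multiplier on lactate production.

    Interpolates through the anchors (clamped to the outer multipliers) so
    the source term stays continuous as the microenvironment acidifies.
    """
    phs = np.array([a[0] for a in params.lpr_ph_anchors])
    mults = np.array([a[1] for a in params.lpr_ph_anchors])
    out = np.interp(np.asarray(ph, dtype=float), phs, mults)
    return out if out.ndim else float(out)


def lpr(glucose_mm, ph, params: MetabolicParams):
    """Lactate production rate, nmol/10^6 cells/h.

    Default mode ties production to instantaneous glycolysis,
    ``ratio * GCR(glucose) * m(pH)``; ``lpr_mode="table"`` instead uses the
    independently tabulated LPR Vmax with the same glucose saturation.
    """
    if params.lpr_mode == "table":
        glucose_mm = np.asarray(glucose_mm, dtype=float)
        if np.any(glucose_mm < 0):
            raise DomainError("glucose concentration must be non-negative")
        base = params.lpr_vmax * glucose_mm / (params.gcr_km_mm + glucose_mm)
    else:
        base = params.lac_gluc_ratio * gcr(glucose_mm, params)
    rate = base * lpr_ph_multiplier(ph, params)
    return rate if np.ndim(rate) else float(rate)


@dataclass(frozen=True)
class BufferModel:
    """Linear lactate -> pH mapping with a floor.

    ``pH = max(ph_fresh - slope * lactate, floor)``; fresh media (zero
    lactate) sits at ``ph_fresh``.  The default slope is the frozen
    calibration constant :data:`BUFFER_SLOPE_PH_PER_MM`.
    """

    ph_fresh: float = 7.4
    slope_ph_per_mm: float = BUFFER_SLOPE_PH_PER_MM
    floor: float = 6.0

    def __post_init__(self) -> None:
        if self.slope_ph_per_mm < 0:
            raise DomainError("buffer slope must be non-negative")
        if self.floor > self.ph_fresh:
            raise DomainError("pH floor cannot exceed the fresh-media pH")


def ph_from_lactate(lactate_mm, buffer: BufferModel = BufferModel()):
    """Local pH as a function of accumulated lactate (mM)."""
    lactate_mm = np.asarray(lactate_mm, dtype=float)
    if np.any(lactate_mm < 0):
        raise DomainError("lactate concentration must be non-negative")
    ph = np.maximum(buffer.ph_fresh - buffer.slope_ph_per_mm * lactate_mm, buffer.floor)
    return ph if ph.ndim else float(ph)


@dataclass(frozen=True)
class CellPopulation:
    """A proliferating monolayer population (2D) or fixed 3D density.

    For monolayers the areal density grows exponentially from
    ``areal_density0`` (cells/cm^2) at rate ``growth_rate_per_day`` and is
    capped at ``confluency_cap`` (cells/cm^2, taken at the 80%-confluency
    endpoint).  For 3D constructs the volumetric ``density_mcells_per_ml``
    is constant over the short (<= 3.5 day) windows simulated.
    """

    density_mcells_per_ml: float = 0.0
    areal_density0: float = 0.0
    growth_rate_per_day: float = 0.0
    confluency_cap: float = 28571.0

    def __post_init__(self) -> None:
        if self.density_mcells_per_ml < 0 or self.areal_density0 < 0:
            raise DomainError("cell densities must be non-negative")
        if self.growth_rate_per_day < 0:
            raise DomainError("growth rate must be non-negative")


#: Default expansion kinetics: 5e3 cells/cm^2 seeded, k = 0.348/d, capped
#: at ~28571 cells/cm^2 (80% confluency).
DEFAULT_EXPANSION = CellPopulation(
    areal_density0=5.0e3, growth_rate_per_day=0.348, confluency_cap=28571.0
)


def population(t_days, pop: CellPopulation):
    """Areal cell density (cells/cm^2) after ``t_days`` of expansion.

    ``N0 * exp(k t)`` capped at the confluency limit.
    """
    t_days = np.asarray(t_days, dtype=float)
    if np.any(t_days < 0):
        raise DomainError("time must be non-negative")
    n = pop.areal_density0 * np.exp(pop.growth_rate_per_day * t_days)
    n = np.minimum(n, pop.confluency_cap)
    return n if n.ndim else float(n)


def growth_rate_from_doubling(n0: float, nt: float, t_days: float) -> float:
    """Exponential growth rate ``k = ln(Nt/N0)/t`` (1/day)."""
    if n0 <= 0 or nt <= 0 or t_days <= 0:
        raise DomainError("cell counts and time must be positive")
    return float(np.log(nt / n0) / t_days)
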