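"""Incubator gas settings and dissolved-oxygen conversion.

A humidified CO2 incubator dilutes the oxygen of dry gas: at a total
pressure ``P`` the gas phase carries ~5% CO2 (38 mmHg) and is saturated
with water vapour at 37 degC (~47 mmHg), so the oxygen partial pressure is
``f_O2 * (P - p_CO2 - p_H2O)`` where ``f_O2`` is the nominal dry-gas oxygen
fraction.  Henry's law then converts the partial pressure into the
dissolved concentration at the media free surface, using an oxygen
solubility of 1.3 uM/mmHg in culture media at 37 degC.

Three named settings cover common practice: normoxia (NX, 20.95% dry gas),
physioxia (PX, 5%) and hypoxia (HX, 2%).  Results are reported both as
dissolved concentration (uM) and as an equivalent gas-phase percentage,
"%O2", defined as the percentage of total pressure whose equilibrium
dissolved level equals the given concentration:
``%O2 = C / (solubility * P / 100)``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidEnvironmentError

#: Oxygen fraction of dry atmospheric air.
DRY_AIR_O2_FRACTION = 0.2095

#: Standard sea-level pressure, mmHg.
SEA_LEVEL_PRESSURE_MMHG = 760.0


@dataclass(frozen=True)
class GasEnvironment:
    """An incubator gas setting.

    Parameters
    ----------
    nominal_o2_fraction:
        Oxygen fraction of the dry gas mix, in [0, 0.2095].
    label:
        Short name; "NX", "PX", "HX" for the named settings.
    total_pressure_mmhg:
        Total (barometric) pressure; default sea level, 760 mmHg.
    p_co2_mmhg:
        CO2 partial pressure; default 38 mmHg (5% CO2).
    p_h2o_mmhg:
        Water-vapour partial pressure; default 47 mmHg (saturation, 37 degC).
    solubility_um_per_mmhg:
        Henry's-law oxygen solubility of the media, uM per mmHg.
    """

    nominal_o2_fraction: float
    label: str = "custom"
    total_pressure_mmhg: float = SEA_LEVEL_PRESSURE_MMHG
    p_co2_mmhg: float = 38.0
    p_h2o_mmhg: float = 47.0
    solubility_um_per_mmhg: float = 1.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.nominal_o2_fraction <= DRY_AIR_O2_FRACTION:
            raise InvalidEnvironmentError(
                f"nominal O2 fraction {self.nominal_o2_fraction} outside "
                f"[0, {DRY_AIR_O2_FRACTION}]"
            )
        if self.total_pressure_mmhg <= 0 or self.solubility_um_per_mmhg <= 0:
            raise InvalidEnvironmentError("pressure and solubility must be positive")
        if self.p_co2_mmhg < 0 or self.p_h2o_mmhg < 0:
            raise InvalidEnvironmentError("partial pressures must be non-negative")
        if self.p_co2_mmhg + self.p_h2o_mmhg >= self.total_pressure_mmhg:
            raise InvalidEnvironmentError(
                "CO2 + H2O partial pressures must be below total pressure"
            )

    @property
    def dry_gas_pressure_mmhg(self) -> float:
        """Pressure available to the dry gas mix (total minus CO2 and H2O)."""
        return self.total_pressure_mmhg - self.p_co2_mmhg - self.p_h2o_mmhg

    @property
    def po2_mmhg(self) -> float:
        """Oxygen partial pressure in the incubator gas phase."""
        return self.nominal_o2_fraction * self.dry_gas_pressure_mmhg

    @property
    def effective_percent_o2(self) -> float:
        """Gas-phase oxygen as a percentage of total pressure."""
        return 100.0 * self.po2_mmhg / self.total_pressure_mmhg


NORMOXIA = GasEnvironment(DRY_AIR_O2_FRACTION, label="NX")
PHYSIOXIA = GasEnvironment(0.05, label="PX")
HYPOXIA = GasEnvironment(0.02, label="HX")

_NAMED = {"NX": NORMOXIA, "PX": PHYSIOXIA, "HX": HYPOXIA}


def gas_environment(label: str) -> GasEnvironment:
    """Return the named incubator setting (``"NX"``, ``"PX"`` or ``"HX"``)."""
    try:
        return _NAMED[label.upper()]
    except KeyError:
        raise InvalidEnvironmentError(
            f"unknown gas setting {label!r}; expected one of {sorted(_NAMED)}"
        ) from None


def dissolved_oxygen(env: GasEnvironment) -> float:
    """Dissolved-oxygen concentration (uM) in media equilibrated with ``env``.

    Henry's law: ``C = solubility * pO2``.  This is the fixed-concentration
    boundary value applied at the media free surface.
    """
    po2 = env.po2_mmhg
    if po2 < 0:
        raise InvalidEnvironmentError(f"negative oxygen partial pressure {po2}")
    return env.solubility_um_per_mmhg * po2


def percent_o2_equivalent(concentration_um: float, env: GasEnvironment = NORMOXIA):
    """Convert a dissolved concentration (uM) to its gas-phase-equivalent %O2.

    The value is the gas percentage of total pressure whose equilibrium
    dissolved level equals the input, i.e. the inverse of
    :func:`dissolved_oxygen` composed with the fraction-of-total conversion:
    ``%O2 = C / (solubility * P / 100)``.  Accepts scalars or arrays.
    """
    scale = env.solubility_um_per_mmhg * env.total_pressure_mmhg / 100.0
    return concentration_um / scale
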