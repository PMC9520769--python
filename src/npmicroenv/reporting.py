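"""Post-processing of simulation results into summary tables and profiles.

Summaries follow a long-format schema with one row per
(scenario, time, region, solute, statistic): minima, maxima and
volume-weighted means per region, plus the cell-surface concentration for
monolayers.  Oxygen is dual-reported in uM and as the gas-phase
equivalent %O2 (the %O2 value is always the unit conversion of the uM
value, never separately computed).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import ReportingError
from .gas import percent_o2_equivalent
from .solver import FieldState, SimulationResult

SUMMARY_COLUMNS = [
    "scenario",
    "phenotype",
    "o2_regime",
    "glucose_regime",
    "time_h",
    "region",
    "solute",
    "stat",
    "value",
    "unit",
]

_REGIONS = {"media": 0, "construct": 1}


def _region_rows(result: SimulationResult, state: FieldState, region: str):
    mesh = result.mesh
    scenario = result.scenario
    mask = mesh.region == _REGIONS[region]
    if not mask.any():
        return []
    w = mesh.vol[mask]
    fields = {
        "o2": (state.o2_um[mask], "uM"),
        "glucose": (state.glucose_mm[mask], "mM"),
        "lactate": (state.lactate_mm[mask], "mM"),
        "ph": (np.asarray(state.ph(scenario.buffer))[mask], "pH"),
    }
    rows = []
    for solute, (values, unit) in fields.items():
        stats = {
            "min": float(values.min()),
            "max": float(values.max()),
            "mean": float((values * w).sum() / w.sum()),
        }
        for stat, value in stats.items():
            rows.append((region, solute, stat, value, unit))
            if solute == "o2":
                rows.append(
                    (
                        region,
                        "o2_percent",
                        stat,
                        float(percent_o2_equivalent(value, scenario.environment)),
                        "%O2",
                    )
                )
    return rows


def summarize(result: SimulationResult, times: Optional[Iterable[float]] = None):
    """Summary table over the requested sample times (default: all stored).

    Returns a :class:`pandas.DataFrame` with the schema
    ``scenario, phenotype, o2_regime, glucose_regime, time_h, region,
    solute, stat, value, unit``.
    """
    scenario = result.scenario
    if times is None:
        times = result.times_h
    records = []
    for t in times:
        horizon_h = scenario.horizon_d * 24.0
        if t < -1e-9 or t > horizon_h + 1e-9:
            raise ReportingError(f"requested time {t} h outside horizon {horizon_h} h")
        state = result.state_at(float(t))
        rows = []
        for region in _REGIONS:
            rows.extend(_region_rows(result, state, region))
        if result.scenario.mode == "monolayer":
            base = result.mesh.base_cell
            surf = {
                ("o2", "uM"): float(state.o2_um[base]),
                ("o2_percent", "%O2"): float(
                    percent_o2_equivalent(state.o2_um[base], scenario.environment)
                ),
                ("glucose", "mM"): float(state.glucose_mm[base]),
                ("lactate", "mM"): float(state.lactate_mm[base]),
                ("ph", "pH"): float(np.asarray(state.ph(scenario.buffer))[base]),
            }
            rows.extend(
                ("cell_surface", solute, "value", value, unit)
                for (solute, unit), value in surf.items()
            )
        for region, solute, stat, value, unit in rows:
            records.append(
                (
                    scenario.name,
                    scenario.params.phenotype,
                    scenario.params.oxygen_regime,
                    scenario.params.glucose_regime,
                    float(state.t_h),
                    region,
                    solute,
                    stat,
                    value,
                    unit,
                )
            )
    return pd.DataFrame.from_records(records, columns=SUMMARY_COLUMNS)


def construct_min_o2_percent(result: SimulationResult, t_h: float) -> float:
    """Minimum construct oxygen at ``t_h``, in gas-phase-equivalent %O2."""
    state = result.state_at(t_h)
    mask = result.mesh.region == 1
    if not mask.any():
        raise ReportingError("scenario has no construct region")
    return float(
        percent_o2_equivalent(state.o2_um[mask].min(), result.scenario.environment)
    )


def axial_profile(result: SimulationResult, t_h: float) -> pd.DataFrame:
    """Concentration profile along the symmetry axis (or media column).

    Columns: ``position_mm, o2_percent, glucose_mM, lactate_mM, pH``.
    Position runs upward from the vessel base (planar/axisymmetric) or
    outward from the sphere centre (spherical).
    """
    state = result.state_at(t_h)
    mesh = result.mesh
    cells = mesh.axis_cells
    position = (
        mesh.centers_r_mm[cells]
        if mesh.symmetry == "spherical1D"
        else mesh.centers_z_mm[cells]
    )
    return pd.DataFrame(
        {
            "position_mm": position,
            "o2_percent": percent_o2_equivalent(
                state.o2_um[cells], result.scenario.environment
            ),
            "glucose_mM": state.glucose_mm[cells],
            "lactate_mM": state.lactate_mm[cells],
            "pH": np.asarray(state.ph(result.scenario.buffer))[cells],
        }
    )


def cell_surface_series(result: SimulationResult) -> pd.DataFrame:
    """Monolayer cell-surface concentrations over time.

    Columns: ``time_h, o2_uM, o2_percent, glucose_mM, lactate_mM, pH``.
    """
    if result.scenario.mode != "monolayer":
        raise ReportingError("cell-surface series are defined for monolayers only")
    base = result.mesh.base_cell
    env = result.scenario.environment
    rows = []
    for state in result.states:
        o2 = float(state.o2_um[base])
        rows.append(
            (
                state.t_h,
                o2,
                float(percent_o2_equivalent(o2, env)),
                float(state.glucose_mm[base]),
                float(state.lactate_mm[base]),
                float(np.asarray(state.ph(result.scenario.buffer))[base]),
            )
        )
    return pd.DataFrame(
        rows, columns=["time_h", "o2_uM", "o2_percent", "glucose_mM", "lactate_mM", "pH"]
    )


def write_summary_csv(df: pd.DataFrame, path) -> None:
    """Write a summary table deterministically (fixed float format)."""
    df.to_csv(path, index=False, float_format="%.10g")
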