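"""Transient coupled reaction-diffusion solver with media-exchange events.

The solver integrates ``dC/dt = div(D grad C) + S(C)`` for dissolved
oxygen (uM), glucose (mM) and lactate (mM) over the finite-volume meshes
of :mod:`npmicroenv.mesh`.  Source terms come from the per-cell rate laws
of :mod:`npmicroenv.metabolism` scaled by the local cell density --
volumetric inside 3D constructs, an areal flux at the vessel base for
proliferating monolayers.  Oxygen is held at the incubator-equilibrated
dissolved value at the media free surface; every other boundary is
no-flux, and glucose/lactate see no surface flux at all.

Two integration paths are used, both implicit and stiffness-robust:

* monolayer columns (a few hundred unknowns, flux-dominated) use adaptive
  BDF with an analytic Jacobian sparsity pattern and relative tolerance
  1e-6, with cumulative-consumption states carried for exact bookkeeping;
* axisymmetric and spherical meshes use Strang splitting with
  backward-Euler diffusion half-steps (one sparse LU per step size,
  reused) and a pointwise implicit Michaelis-Menten reaction step whose
  closed-form positive root preserves positivity exactly.  The fixed step
  ramps from a short startup value to the plateau value; both are
  documented solver options.

Discrete conservation is exact: between media exchanges the inventory
change of each solute equals boundary influx minus integrated
consumption to rounding error, and the solver records that ledger per
feeding interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .exceptions import ReportingError, SolverError
from .gas import dissolved_oxygen
from .mesh import Mesh, build_compartment_mesh, build_mesh
from .metabolism import (
    lpr_ph_multiplier,
    ocr_coefficients,
    ph_from_lactate,
    population,
)
from .scenarios import CultureScenario

SNAPSHOT_LEAD_H = 1.0 / 60.0  # "just prior to media exchange" = 1 min before


@dataclass
class SolverOptions:
    """Numerical controls.

    ``resolution`` is forwarded to :func:`npmicroenv.mesh.build_mesh`.
    The split-step integrator starts at ``dt_init_h`` for the first
    ``ramp_h`` hours (the initial boundary-layer transient) and then uses
    ``dt_max_h``.  ``picard_iters`` couples pH back into the oxygen and
    lactate sources within each reaction step.
    """

    resolution: int = 40
    dt_init_h: float = 0.01
    dt_max_h: float = 0.1
    ramp_h: float = 2.0
    sample_every_h: float = 3.0
    picard_iters: int = 2
    rtol: float = 1e-6
    newton_tol: float = 1e-8
    newton_max_iter: int = 60


@dataclass
class FieldState:
    """Concentration fields at one instant."""

    t_h: float
    o2_um: np.ndarray
    glucose_mm: np.ndarray
    lactate_mm: np.ndarray

    def ph(self, buffer) -> np.ndarray:
        """pH field: a pure function of the lactate field."""
        return ph_from_lactate(self.lactate_mm, buffer)

    def copy(self) -> "FieldState":
        return FieldState(
            self.t_h,
            self.o2_um.copy(),
            self.glucose_mm.copy(),
            self.lactate_mm.copy(),
        )


@dataclass
class SimulationResult:
    """Sampled fields, conservation ledger and scenario/mesh handles."""

    scenario: CultureScenario
    mesh: Mesh
    times_h: np.ndarray
    states: List[FieldState]
    ledger: List[dict]
    options: SolverOptions

    def state_at(self, t_h: float) -> FieldState:
        """The stored state closest to ``t_h`` (must be within one minute)."""
        idx = int(np.argmin(np.abs(self.times_h - t_h)))
        if abs(self.times_h[idx] - t_h) > 1.5 * SNAPSHOT_LEAD_H:
            raise ReportingError(
                f"no stored state near t = {t_h} h (available: {self.times_h})"
            )
        return self.states[idx]

    def pre_exchange_snapshot(self, which: int = 0) -> FieldState:
        """The sample taken one minute before the ``which``-th media exchange."""
        if not self.scenario.exchange_times_d:
            raise ReportingError("scenario has no media exchanges")
        t = self.scenario.exchange_times_d[which] * 24.0 - SNAPSHOT_LEAD_H
        return self.state_at(t)


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------


def _assemble(mesh: Mesh, solute: str, dirichlet: bool):
    """Sparse rate operator ``dC/dt = A C + d * C_bc`` (per hour)."""
    n = mesh.n_cells
    t = mesh.transmissibility(solute)
    i, j = mesh.face_i, mesh.face_j
    rows = np.concatenate([i, i, j, j])
    cols = np.concatenate([i, j, j, i])
    vals = np.concatenate(
        [-t / mesh.vol[i], t / mesh.vol[i], -t / mesh.vol[j], t / mesh.vol[j]]
    )
    d = np.zeros(n)
    if dirichlet and mesh.top_cells.size:
        tt = mesh.top_transmissibility(solute)
        d[mesh.top_cells] = tt / mesh.vol[mesh.top_cells]
        rows = np.concatenate([rows, mesh.top_cells])
        cols = np.concatenate([cols, mesh.top_cells])
        vals = np.concatenate([vals, -tt / mesh.vol[mesh.top_cells]])
    a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return a, d


def _mm_implicit(c: np.ndarray, ha: np.ndarray, km) -> np.ndarray:
    """Backward-Euler step of ``dc/dt = -a c/(km + c)`` over ``h`` (ha = h*a).

    Solves ``x - c + ha x/(km + x) = 0`` for the positive root of the
    quadratic; exact positivity preservation for any step size.
    """
    b = km + ha - c
    return 0.5 * (-b + np.sqrt(b * b + 4.0 * km * c))


def apply_media_exchange(
    state: FieldState, scenario: CultureScenario, mesh: Mesh
) -> FieldState:
    """Instantaneous feed: media-region cells reset to fresh values
    (scenario glucose, zero lactate, incubator-equilibrated oxygen);
    construct-region cells keep their concentrations."""
    out = state.copy()
    media = mesh.region == 0
    out.o2_um[media] = dissolved_oxygen(scenario.environment)
    out.glucose_mm[media] = scenario.glucose_mm
    out.lactate_mm[media] = scenario.lactate_mm
    return out


# ---------------------------------------------------------------------------
# split-step path (axisymmetric2D / spherical1D)
# ---------------------------------------------------------------------------


class _ReactionStep:
    """Pointwise implicit glycolysis update on construct cells.

    Glucose takes a backward-Euler Michaelis-Menten step (closed-form
    positive root); lactate production is tied stoichiometrically to the
    glucose actually consumed, so their ledger entries balance exactly.
    The Picard loop feeds the pH of the updated lactate back into the
    production multiplier.  Oxygen is handled by the semi-implicit
    transport step, not here.
    """

    def __init__(self, scenario: CultureScenario, mesh: Mesh, picard_iters: int):
        self.p = scenario.params
        self.buffer = scenario.buffer
        self.picard = picard_iters
        self.cells = np.flatnonzero(mesh.frac > 0)
        rho_eff = scenario.construct.density_mcells_per_ml * mesh.frac[self.cells]
        # uM/h per unit of the OCR pH factor, at saturating oxygen
        self.a_o2 = self.p.ocr_vmax * rho_eff
        self.a_glc = self.p.gcr_vmax * rho_eff * 1e-3  # mM/h at saturating glucose
        self.vol = mesh.vol[self.cells]

    @property
    def active(self) -> bool:
        return self.cells.size > 0 and float(self.a_glc.max(initial=0.0)) > 0.0

    def __call__(self, state: FieldState, h: float, ledger: dict) -> None:
        if not self.active:
            return
        k = self.cells
        glc_old = state.glucose_mm[k]
        lac_old = state.lactate_mm[k]
        ph = ph_from_lactate(lac_old, self.buffer)
        glc_new, lac_new = glc_old, lac_old
        for _ in range(self.picard):
            glc_new = _mm_implicit(glc_old, h * self.a_glc, self.p.gcr_km_mm)
            dglc = glc_old - glc_new
            if self.p.lpr_mode == "table":
                produced = (
                    (self.p.lpr_vmax / self.p.gcr_vmax)
                    * dglc
                    * lpr_ph_multiplier(ph, self.p)
                )
            else:
                produced = self.p.lac_gluc_ratio * dglc * lpr_ph_multiplier(ph, self.p)
            lac_new = lac_old + produced
            ph = ph_from_lactate(lac_new, self.buffer)
        state.glucose_mm[k] = glc_new
        state.lactate_mm[k] = lac_new
        ledger["glucose_consumed"] += float(((glc_old - glc_new) * self.vol).sum())
        ledger["lactate_produced"] += float(((lac_new - lac_old) * self.vol).sum())


def _new_ledger(t_h: float, state: FieldState, mesh: Mesh) -> dict:
    return {
        "t_start_h": t_h,
        "t_end_h": t_h,
        "initial": {
            "o2": float((state.o2_um * mesh.vol).sum()),
            "glucose": float((state.glucose_mm * mesh.vol).sum()),
            "lactate": float((state.lactate_mm * mesh.vol).sum()),
        },
        "o2_consumed": 0.0,
        "glucose_consumed": 0.0,
        "lactate_produced": 0.0,
        "o2_influx": 0.0,
    }


def _close_ledger(ledger: dict, t_h: float, state: FieldState, mesh: Mesh) -> dict:
    ledger["t_end_h"] = t_h
    ledger["final"] = {
        "o2": float((state.o2_um * mesh.vol).sum()),
        "glucose": float((state.glucose_mm * mesh.vol).sum()),
        "lactate": float((state.lactate_mm * mesh.vol).sum()),
    }
    return ledger


def _boundaries(scenario: CultureScenario, options: SolverOptions):
    horizon = scenario.horizon_d * 24.0
    exchanges = [t * 24.0 for t in scenario.exchange_times_d]
    samples = set(np.arange(0.0, horizon + 1e-9, options.sample_every_h).tolist())
    samples.add(horizon)
    for ex in exchanges:
        if ex - SNAPSHOT_LEAD_H > 0:
            samples.add(ex - SNAPSHOT_LEAD_H)
        samples.add(ex)
    samples.add(min(options.ramp_h, horizon))
    return sorted(s for s in samples if 0.0 < s <= horizon), exchanges


def _run_split(
    scenario: CultureScenario, mesh: Mesh, options: SolverOptions
) -> SimulationResult:
    n = mesh.n_cells
    bc = dissolved_oxygen(scenario.environment)
    state = FieldState(
        0.0,
        np.full(n, bc),
        np.full(n, scenario.glucose_mm),
        np.full(n, scenario.lactate_mm),
    )
    ops = {
        "o2": _assemble(mesh, "o2", dirichlet=True),
        "glucose": _assemble(mesh, "glucose", dirichlet=False),
        "lactate": _assemble(mesh, "lactate", dirichlet=False),
    }
    bcs = {"o2": bc, "glucose": 0.0, "lactate": 0.0}
    react = _ReactionStep(scenario, mesh, options.picard_iters)
    lu_cache: Dict = {}
    a_o2_csc = ops["o2"][0].tocsc()
    d_o2 = ops["o2"][1]
    identity = sp.identity(n, format="csc")
    tt_top = mesh.top_transmissibility("o2") if mesh.top_cells.size else None
    sigma = np.zeros(n)
    sink_cells = react.cells
    a_sink = react.a_o2  # Vmax * rho_eff on construct cells, uM/h per pH-factor

    def oxygen_step(h: float, ledger: dict) -> None:
        """Backward-Euler transport step with the Michaelis-Menten sink
        folded into the system matrix (coefficient form sigma(c) * c),
        re-solved once more whenever the field is still moving fast.
        No operator splitting, hence no depletion-zone splitting bias and
        an exact discrete oxygen balance."""
        c_old = state.o2_um
        rhs = c_old + h * d_o2 * bc
        c_ref = c_old
        for attempt in range(3):
            if sink_cells.size:
                ph = ph_from_lactate(state.lactate_mm[sink_cells], scenario.buffer)
                ph_factor, km_eff = ocr_coefficients(ph, scenario.params)
                sigma[sink_cells] = a_sink * ph_factor / (km_eff + c_ref[sink_cells])
            m = identity - h * a_o2_csc + h * sp.diags(sigma, format="csc")
            c_new = spla.splu(m).solve(rhs)
            if (
                not sink_cells.size
                or float(np.max(np.abs(c_new - c_ref))) < 0.02 * max(bc, 1.0)
            ):
                break
            c_ref = c_new
        state.o2_um = c_new
        ledger["o2_consumed"] += float((h * sigma * c_new * mesh.vol).sum())
        if tt_top is not None:
            ledger["o2_influx"] += float(
                (tt_top * (bc - c_new[mesh.top_cells])).sum() * h
            )

    def half_diffusion(h: float) -> None:
        for s in ("glucose", "lactate"):
            a, d = ops[s]
            key = (s, round(h, 12))
            if key not in lu_cache:
                m = sp.identity(n, format="csc") - h * a.tocsc()
                lu_cache[key] = spla.splu(m)
            c = getattr(state, _FIELD[s])
            setattr(state, _FIELD[s], lu_cache[key].solve(c + h * d * bcs[s]))

    boundaries, exchanges = _boundaries(scenario, options)
    times = [0.0]
    states = [state.copy()]
    ledgers: List[dict] = []
    current = _new_ledger(0.0, state, mesh)
    sample_set = set(round(b, 9) for b in boundaries)
    exchange_set = set(round(e, 9) for e in exchanges)

    t = 0.0
    for b in boundaries:
        seg = b - t
        if seg > 1e-12:
            target = options.dt_init_h if t < options.ramp_h - 1e-9 else options.dt_max_h
            nsteps = max(int(math.ceil(seg / target - 1e-9)), 1)
            h = seg / nsteps
            for _ in range(nsteps):
                oxygen_step(h, current)
                half_diffusion(h / 2)
                react(state, h, current)
                half_diffusion(h / 2)
                t += h
        t = b
        state.t_h = t
        key = round(b, 9)
        if key in exchange_set:
            ledgers.append(_close_ledger(current, t, state, mesh))
            state = apply_media_exchange(state, scenario, mesh)
            state.t_h = t
            current = _new_ledger(t, state, mesh)
        if key in sample_set:
            times.append(t)
            states.append(state.copy())
    ledgers.append(_close_ledger(current, t, state, mesh))
    return SimulationResult(scenario, mesh, np.array(times), states, ledgers, options)


_FIELD = {"o2": "o2_um", "glucose": "glucose_mm", "lactate": "lactate_mm"}


# ---------------------------------------------------------------------------
# monolayer path (planar1D, adaptive BDF)
# ---------------------------------------------------------------------------


def _run_planar(
    scenario: CultureScenario, mesh: Mesh, options: SolverOptions
) -> SimulationResult:
    n = mesh.n_cells
    bc = dissolved_oxygen(scenario.environment)
    p = scenario.params
    pop = scenario.population
    buffer = scenario.buffer
    dz_cm = mesh.vol[mesh.base_cell] / mesh.base_area_m2 * 100.0
    v_base = mesh.vol[mesh.base_cell]

    ops = {
        "o2": _assemble(mesh, "o2", dirichlet=True),
        "glucose": _assemble(mesh, "glucose", dirichlet=False),
        "lactate": _assemble(mesh, "lactate", dirichlet=False),
    }

    def rates(t_h, o2_0, glc_0, lac_0):
        """Per-area sink rates at the cell surface, nmol/cm^2/h."""
        n_cells = population(t_h / 24.0, pop) / 1e6  # 10^6 cells/cm^2
        ph = ph_from_lactate(max(lac_0, 0.0), buffer)
        ph_factor, km_eff = ocr_coefficients(ph, p)
        o2c = max(o2_0, 0.0)
        glcc = max(glc_0, 0.0)
        r_o2 = n_cells * p.ocr_vmax * float(ph_factor) * o2c / (float(km_eff) + o2c)
        r_glc = n_cells * p.gcr_vmax * glcc / (p.gcr_km_mm + glcc)
        if p.lpr_mode == "table":
            r_lac = (
                n_cells
                * p.lpr_vmax
                * glcc
                / (p.gcr_km_mm + glcc)
                * lpr_ph_multiplier(ph, p)
            )
        else:
            r_lac = p.lac_gluc_ratio * r_glc * lpr_ph_multiplier(ph, p)
        return r_o2, r_glc, r_lac

    def rhs(t_h, y):
        o2, glc, lac = y[:n], y[n : 2 * n], y[2 * n : 3 * n]
        r_o2, r_glc, r_lac = rates(t_h, o2[0], glc[0], lac[0])
        dy = np.empty_like(y)
        a, d = ops["o2"]
        dy[:n] = a @ o2 + d * bc
        dy[0] -= r_o2 / dz_cm
        a, _ = ops["glucose"]
        dy[n : 2 * n] = a @ glc
        dy[n] -= r_glc / dz_cm / 1000.0
        a, _ = ops["lactate"]
        dy[2 * n : 3 * n] = a @ lac
        dy[2 * n] += r_lac / dz_cm / 1000.0
        # cumulative consumption, inventory units (concentration x m^3)
        dy[3 * n] = r_o2 / dz_cm * v_base
        dy[3 * n + 1] = r_glc / dz_cm / 1000.0 * v_base
        dy[3 * n + 2] = r_lac / dz_cm / 1000.0 * v_base
        return dy

    sparsity = sp.lil_matrix((3 * n + 3, 3 * n + 3))
    tri = ops["o2"][0] + sp.identity(n)
    for blk in range(3):
        sparsity[blk * n : (blk + 1) * n, blk * n : (blk + 1) * n] = tri != 0
    for row in (0, n, 2 * n, 3 * n, 3 * n + 1, 3 * n + 2):
        for col in (0, n, 2 * n):
            sparsity[row, col] = 1

    boundaries, exchanges = _boundaries(scenario, options)
    exchange_set = set(round(e, 9) for e in exchanges)
    y = np.concatenate(
        [
            np.full(n, bc),
            np.full(n, scenario.glucose_mm),
            np.full(n, scenario.lactate_mm),
            np.zeros(3),
        ]
    )
    atol = np.concatenate(
        [np.full(n, 1e-4), np.full(n, 1e-7), np.full(n, 1e-7), np.full(3, 1e-12)]
    )

    def to_state(t_h, yv) -> FieldState:
        return FieldState(
            t_h,
            np.maximum(yv[:n], 0.0).copy(),
            np.maximum(yv[n : 2 * n], 0.0).copy(),
            np.maximum(yv[2 * n : 3 * n], 0.0).copy(),
        )

    times = [0.0]
    states = [to_state(0.0, y)]
    ledgers: List[dict] = []
    current = _new_ledger(0.0, states[0], mesh)
    cum0 = y[3 * n :].copy()
    seg_edges = [0.0] + boundaries
    for t0, t1 in zip(seg_edges[:-1], seg_edges[1:]):
        if t1 - t0 > 1e-12:
            sol = solve_ivp(
                rhs,
                (t0, t1),
                y,
                method="BDF",
                jac_sparsity=sparsity.tocsr(),
                rtol=options.rtol,
                atol=atol,
            )
            if not sol.success:
                raise SolverError(f"monolayer BDF failed on [{t0}, {t1}] h: {sol.message}")
            y = sol.y[:, -1]
        st = to_state(t1, y)
        key = round(t1, 9)
        if key in exchange_set:
            cum = y[3 * n :]
            current["o2_consumed"] += cum[0] - cum0[0]
            current["glucose_consumed"] += cum[1] - cum0[1]
            current["lactate_produced"] += cum[2] - cum0[2]
            ledgers.append(_close_ledger(current, t1, st, mesh))
            st = apply_media_exchange(st, scenario, mesh)
            y = np.concatenate([st.o2_um, st.glucose_mm, st.lactate_mm, y[3 * n :]])
            cum0 = y[3 * n :].copy()
            current = _new_ledger(t1, st, mesh)
        times.append(t1)
        states.append(st)
    cum = y[3 * n :]
    current["o2_consumed"] += cum[0] - cum0[0]
    current["glucose_consumed"] += cum[1] - cum0[1]
    current["lactate_produced"] += cum[2] - cum0[2]
    ledgers.append(_close_ledger(current, times[-1], states[-1], mesh))
    return SimulationResult(scenario, mesh, np.array(times), states, ledgers, options)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def run_transient(
    scenario: CultureScenario,
    mesh: Optional[Mesh] = None,
    options: Optional[SolverOptions] = None,
) -> SimulationResult:
    """Integrate a scenario over its horizon with its feeding schedule.

    Dispatches on the scenario mode: monolayers run the 1D adaptive-BDF
    column model, single constructs the axisymmetric split-step model,
    and multi-bead wells the reduced-order compartment model.
    """
    options = options or SolverOptions()
    if scenario.mode == "multibead":
        return compartment_multibead(scenario, options=options)
    if mesh is None:
        mesh = build_mesh(scenario, resolution=options.resolution)
    if scenario.mode == "monolayer":
        return _run_planar(scenario, mesh, options)
    return _run_split(scenario, mesh, options)


def compartment_multibead(
    scenario: CultureScenario, options: Optional[SolverOptions] = None
) -> SimulationResult:
    """Reduced-order model for N identical beads in one well.

    Each bead is solved spherically symmetric; all beads share a single
    well-mixed media compartment reached through a stagnant-film
    resistance (Sherwood number 2).  This approximates the full 3D
    multi-bead layout; depletion and acidification increase strictly with
    bead count.  With N = 1 it also serves as a fast cross-check of the
    axisymmetric single-bead model.
    """
    options = options or SolverOptions()
    mesh = build_compartment_mesh(scenario, resolution=options.resolution)
    return _run_split(scenario, mesh, options)


def steady_state(
    scenario: CultureScenario,
    mesh: Optional[Mesh] = None,
    mode: str = "oxygen",
    options: Optional[SolverOptions] = None,
) -> FieldState:
    """Steady fields by damped Newton iteration.

    ``mode="oxygen"`` holds glucose and lactate at their fresh values
    (pH at the fresh-media reference) and solves the nonlinear oxygen
    balance; ``mode="full"`` instead runs the transient integrator with a
    long damping horizon and returns the final state.  Raises
    :class:`SolverError` with the residual when Newton stagnates.
    """
    options = options or SolverOptions()
    if mesh is None:
        mesh = build_mesh(scenario, resolution=options.resolution)
    if mode == "full":
        damped = replace_horizon(scenario, horizon_d=14.0, exchange_times_d=())
        return run_transient(damped, mesh=mesh, options=options).states[-1]
    if mode != "oxygen":
        raise ValueError(f"unknown steady-state mode {mode!r}")

    bc = dissolved_oxygen(scenario.environment)
    p = scenario.params
    n = mesh.n_cells
    ph = ph_from_lactate(scenario.lactate_mm, scenario.buffer)
    ph_factor, km_eff = ocr_coefficients(ph, p)
    ph_factor, km = float(ph_factor), float(km_eff)
    if scenario.construct is not None:
        sink_a = (
            p.ocr_vmax
            * ph_factor
            * scenario.construct.density_mcells_per_ml
            * mesh.frac
        )
    else:
        sink_a = np.zeros(n)
        n_cells = population(scenario.horizon_d, scenario.population) / 1e6
        dz_cm = mesh.vol[mesh.base_cell] / mesh.base_area_m2 * 100.0
        sink_a[mesh.base_cell] = n_cells * p.ocr_vmax * ph_factor / dz_cm
    c = steady_oxygen_field(mesh, bc, sink_a, km, options)
    return FieldState(
        math.inf,
        c,
        np.full(n, scenario.glucose_mm),
        np.full(n, scenario.lactate_mm),
    )


def steady_oxygen_field(
    mesh: Mesh,
    bc_um: float,
    sink_a: np.ndarray,
    km_um,
    options: Optional[SolverOptions] = None,
) -> np.ndarray:
    """Steady oxygen field for a prescribed Michaelis-Menten sink.

    Solves ``div(D grad C) - sink_a * C/(km + C) = 0`` with the
    free-surface Dirichlet value ``bc_um`` by damped Newton iteration.
    ``sink_a`` is the saturating volumetric rate per cell (uM/h); a very
    small ``km_um`` recovers a zero-order sink, which is how the
    closed-form verification problems are posed.
    """
    options = options or SolverOptions()
    a, d = _assemble(mesh, "o2", dirichlet=True)
    a_csc = a.tocsc()
    n = mesh.n_cells
    km = np.asarray(km_um, dtype=float)
    c = np.full(n, bc_um)
    for _ in range(options.newton_max_iter):
        sink = sink_a * c / (km + c)
        f = a @ c + d * bc_um - sink
        jac = a_csc - sp.diags(sink_a * km / (km + c) ** 2)
        delta = spla.splu(jac.tocsc()).solve(-f)
        c = np.maximum(c + delta, 0.0)
        if np.max(np.abs(delta)) < options.newton_tol * max(bc_um, 1.0):
            return c
    residual = float(np.max(np.abs(a @ c + d * bc_um - sink_a * c / (km + c))))
    raise SolverError(
        f"steady-state Newton did not converge; max residual {residual:.3e} uM/h"
    )


def replace_horizon(
    scenario: CultureScenario, horizon_d: float, exchange_times_d: tuple
) -> CultureScenario:
    """A copy of ``scenario`` with a different schedule (used for damping runs)."""
    import dataclasses

    return dataclasses.replace(
        scenario, horizon_d=horizon_d, exchange_times_d=exchange_times_d
    )


def oxygen_flux_balance(scenario: CultureScenario, mesh: Mesh, state: FieldState):
    """Surface oxygen influx and volume-integrated consumption (uM m^3/h)
    for a (near-)steady state -- the two should balance."""
    bc = dissolved_oxygen(scenario.environment)
    tt = mesh.top_transmissibility("o2")
    influx = float((tt * (bc - state.o2_um[mesh.top_cells])).sum())
    p = scenario.params
    ph = np.asarray(state.ph(scenario.buffer))
    ph_factor, km_eff = ocr_coefficients(ph, p)
    if scenario.construct is not None:
        sink = (
            p.ocr_vmax
            * ph_factor
            * scenario.construct.density_mcells_per_ml
            * mesh.frac
            * state.o2_um
            / (km_eff + state.o2_um)
        )
        consumed = float((sink * mesh.vol).sum())
    else:
        n_cells = population(scenario.horizon_d, scenario.population) / 1e6
        dz_cm = mesh.vol[mesh.base_cell] / mesh.base_area_m2 * 100.0
        c0 = state.o2_um[mesh.base_cell]
        consumed = float(
            n_cells
            * p.ocr_vmax
            * ph_factor[mesh.base_cell]
            * c0
            / (km_eff[mesh.base_cell] + c0)
            / dz_cm
            * mesh.vol[mesh.base_cell]
        )
    return influx, consumed
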