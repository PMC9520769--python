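# Methods

`npmicroenv` predicts the local nutrient microenvironment — dissolved
oxygen, glucose, lactate and pH — experienced by nucleus pulposus (NP)
cells in common in vitro culture formats.  The package couples per-cell
metabolic rate laws to reaction–diffusion transport over the culture
geometry, with the feeding schedule applied as instantaneous media-reset
events.  This note records the model, its parameters and assumptions, the
numerical choices, and what the synthetic scenarios do and do not
represent.

## Transport model

Each solute obeys

    dC/dt = div(D grad C) + S(C),    C in {O2 (uM), glucose (mM), lactate (mM)}

on the media + construct domain.  Diffusivities are constant per region
(media at 37 °C: O2 2.8e-9, glucose 5.67e-10, lactate 5.68e-10 m²/s;
alginate beads: 1.8e-9 / 5.1e-10 / 4.67e-10; cylindrical hydrogels and
pellet interiors use literature-averaged hydrogel values 2.1e-9 /
6.3e-10 / 5.1e-10).  Oxygen is held at the incubator-equilibrated
dissolved value at the media free surface (Henry's law, below); every
plastic surface and the symmetry axis is no-flux, and glucose/lactate
have no flux anywhere on the exterior — the well is a closed glucose
reservoir between feeds.  Diffusion through vessel plastic and filter
caps is neglected (orders of magnitude slower than media).

Geometries reduce to three symmetries:

* **Monolayers** — a 1D vertical media column of height
  `media volume / base area`; the adherent cells are an areal flux
  boundary condition at the base, with the areal density following
  `N(t) = N0 exp(k t)` capped at the 80 %-confluency endpoint
  (~28 571 cells/cm², from 5 000 cells/cm² at k = 0.348 d⁻¹).  Lateral
  uniformity is assumed; the model predicts only minor differences
  between vessels, consistent with that assumption.
* **Single constructs** (one bead, cylindrical hydrogel, or pellet) — an
  axisymmetric r–z domain.  Spheres rest on the vessel base with point
  contact; cylinders sit centred with a no-flux base (no diffusion
  through the plastic contact).  Eppendorf tubes are truncated cones
  (tip radius 0.6 mm, wall slope 4.1 mm per 35 mm — standard 1.5 ml tube
  interior).
* **Multi-bead wells** — a reduced-order compartment model: one
  representative spherically-symmetric bead per well coupled to a single
  well-mixed media compartment through a stagnant-film resistance
  (Sherwood number 2, film coefficient D/R), with oxygen re-supplied to
  the compartment through half the media column height.  This documented
  approximation replaces a full 3D multi-bead layout; with N = 1 it
  agrees with the axisymmetric model to ~0.2 %O2 and ~0.01 mM glucose,
  and it preserves the qualitative contract that depletion and
  acidification increase strictly with bead count.

## Gas boundary conditions

Incubator gas at total pressure P (default 760 mmHg, sea level) carries
5 % CO2 (38 mmHg) and saturated humidity (47 mmHg), so
`pO2 = f_dry * (P - 38 - 47)` and the dissolved boundary value is
`C = 1.3 uM/mmHg * pO2`.  Named settings: normoxia (NX, f = 0.2095,
183.8 uM), physioxia (PX, 0.05, 43.9 uM), hypoxia (HX, 0.02, 17.6 uM).
The NX dry-gas fraction defaults to 20.95 % (configurable; some sources
round to 21 %).  Results are reported as the gas-phase-equivalent
percentage of total pressure, `%O2 = C / (1.3 * 7.6 uM per %)`, the
convention the figures use (NX boundary = 18.6 %O2).

## Metabolic rate laws

Per-cell rates in nmol per million cells per hour, multiplied by the
local cell density (10⁶ cells/ml in constructs, cells/cm² on the base
for monolayers):

* **OCR** = `Vmax * (pH - 4.95) * C / (Km * (pH - 4.59) + C)` with
  Km = 12 uM — the pH-coupled Michaelis–Menten law established for disc
  cells.  Both the effective maximal rate and the effective
  half-saturation scale with pH; respiration shuts off entirely by
  pH 4.95.  Vmax = 17 for animal/healthy human cells, 62 for the
  degenerated phenotype.  Note the *effective* saturating rate at fresh
  media pH 7.4 is `2.45 * Vmax`; the tabulated Vmax is the equation
  parameter, not the observed plateau rate.
* **GCR** = `Vmax_g * C / (2 mM + C)`, with Vmax_g keyed to the oxygen
  setting (NX 143, PX 103, HX 165); the same constants serve LG and HG
  media (no systematic difference is resolvable in the compiled
  measurements; every constant is overridable per scenario).
* **LPR** is tied to instantaneous glycolysis as
  `ratio * GCR * m(pH)`, with the lac:gluc ratio keyed to the oxygen
  setting (NX 1.4, PX 1.6, HX 1.8) and `m` a piecewise-linear acidity
  multiplier through (7.4, 1.0), (6.7, 0.75), (6.2, 0.25), clamped to
  [0.25, 1].  This reproduces the measured production plateau (~200
  nmol/10⁶ cells/h at pH 7.4 under NX, falling to ~150 at pH 6.7 and
  ~50 at pH 6.2) while keeping the source term continuous.  An
  alternative mode drives LPR from the independently tabulated
  saturating rates (207/168/296) instead; the ratio-coupled form is the
  default because it captures glucose-rate-limited glycolysis, at the
  cost of a ≤3.5 % discrepancy against the tabulated plateau
  (1.4 × 143 = 200.2 vs 207).  GCR itself is not reduced at acidic pH —
  only lactate production is.

## Lactate → pH buffer

The titration behaviour of the buffered media is not available, so pH is
a single-slope linear map `pH = max(7.4 - s * lactate, 6.0)`.  The slope
is a frozen calibration constant, s = 0.140 pH/mM, obtained once by a
one-dimensional calibration against the bead solver: an 8·10⁶ cells/ml
30 ul bead under HX/LG reaches a minimum pH of 7.0 at the day-3
pre-exchange snapshot.  All pH outputs are therefore *qualitative*
(orderings and directions are meaningful; absolute values inherit the
uncertainty of this one-parameter model), and the automated checks
assert pH orderings only, never absolute pH.

## Feeding schedule

"Twice weekly" feeding is one exchange at the midpoint of the 7-day
expansion window (day 3.5) for monolayers and cylindrical hydrogels, and
day 3 for bead and pellet cultures, whose results are read "just prior
to a media exchange" — operationalised as exactly one minute before the
event.  An exchange instantaneously resets every media-region cell to
fresh values (scenario glucose, zero lactate, incubator-equilibrated
oxygen) and leaves construct interiors untouched.  Proliferation is
modelled in 2D only; 3D densities are constant over the ≤3.5-day windows
(the first-feed horizon is too short for meaningful 3D proliferation,
and the local microenvironment itself would modulate it).

## Numerics

Conservative finite volumes on structured graded meshes.  Cell volumes
come from exact slice volumes of the vessel solid, so the meshed volume
equals media + construct volume to rounding error at any resolution.
Spheres are represented on the r–z grid by per-cell volume fractions
(midpoint-subsampled, then normalised so the encapsulated volume — hence
the total cell number — is exact); interface-cell diffusivities are
fraction-blended.  Cylindrical constructs conform exactly to grid faces.
The default resolution is 40 cells across the smallest construct
dimension with geometric grading (ratio 1.3) into the media; halving the
spacing moves reported oxygen minima by <1 %.

Time integration is implicit and stiffness-robust, in two flavours:

* monolayer columns use adaptive BDF (SciPy) at rtol 1e-6 with an
  analytic Jacobian sparsity pattern, carrying cumulative-consumption
  states so the feeding-interval ledger is exact;
* 2D/spherical meshes advance with a fixed step (0.01 h for the first
  2 h of boundary-layer transient, then 0.1 h).  Oxygen takes a
  backward-Euler step with the Michaelis–Menten sink folded into the
  transport matrix as a Picard-lagged coefficient `sigma(C) C` —
  re-solved within the step whenever the field moves by more than 2 % of
  the boundary value.  Because transport and sink are solved together,
  there is no operator-splitting bias in depletion zones and the scheme
  is exact at steady state; the matrix is an M-matrix, so positivity is
  preserved unconditionally.  Glucose and lactate (gentle sources,
  h·Vmax ≪ Km) use Strang splitting with cached LU factors and a
  closed-form positive-root backward-Euler Michaelis–Menten step;
  lactate production is stoichiometrically tied to the glucose actually
  consumed in the step, making the glucose/lactate ledger exact by
  construction.

Steady states solve the nonlinear oxygen balance by damped Newton
iteration (convergence when the update falls below 1e-8 of the boundary
value), holding glucose/lactate at fresh values; a full-mode variant
simply damps the transient over a long horizon.  All paths are
deterministic — identical scenarios and options reproduce bit-identical
fields.

Reported problem sizes: the standard runs use ~3 000–6 500 finite-volume
cells (axisymmetric scenarios at resolution 40), 120-cell columns for
monolayers, and 40-shell compartment models for multi-bead wells; each
scenario solves in seconds to a couple of minutes on one CPU core.

## Synthetic scenarios and their limits

The registry encodes the field's most common configurations (vessel
working volumes, 30 ul beads at 2/4/8·10⁶ cells/ml, 4 or 10 beads per
12-well, r 2.5 mm cylinders of height 1.5/3 mm at 4/20·10⁶ cells/ml,
250k-cell pellets and 35k-cell microaggregates).  Values the protocols
do not report are reconstructed and exposed in config: catalogue vessel
base areas (6-well 9.6, 12-well 3.8, 24-well 1.9, 96-well 0.32 cm²),
a 24-well/2 ml default vessel for cylinders, 2 ml working volume for the
12-well, and a pellet packing density of 200·10⁶ cells/ml (250k cells →
r ≈ 0.67 mm; pellet oxygen minima are sensitive to this choice).
`random_scenario` draws invariant-satisfying perturbations of these
configurations for property tests; passing those tests demonstrates the
solver's structural properties (conservation, monotonicity, ordering),
not fidelity to any particular wet-lab system.

Known limitations: no Pasteur-effect switching (the compiled rates show
none — PX carries the lowest glycolytic rates); rates assumed
independent of culture time, biomaterial and 2D/3D context; constant
diffusivities (no reduction by deposited matrix at high density); no
CO2/bicarbonate dynamics, convection, evaporation or mechanical
deformation; multi-bead wells are a compartment approximation, not a
resolved 3D layout; and absolute pH values rest on the calibrated
one-parameter buffer model.
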