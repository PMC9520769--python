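# npmicroenv

**Nutrient-microenvironment modelling for nucleus pulposus cell culture.**

Intervertebral-disc (nucleus pulposus, NP) cells live in an avascular
tissue and are studied in vitro under a wide range of under-reported
culture conditions.  The oxygen, glucose and pH a cell actually
experiences can differ substantially from the incubator setting and the
bottle label: nutrients reach the cells by diffusion through media and
hydrogel, while the cells themselves consume oxygen and glucose and
acidify their surroundings with lactate.  `npmicroenv` quantifies that
gap.  It simulates 2D monolayer expansion and the common 3D formats —
30 µl alginate beads, cylindrical hydrogel constructs, pellets and
microaggregates — under configurable incubator gas settings, media
glucose levels, vessel geometries, seeding densities and feeding
schedules, and reports the resulting local microenvironment.

## Model

Solute fields obey coupled reaction–diffusion equations

    ∂C/∂t = ∇·(D∇C) + S(C),   C ∈ {O₂, glucose, lactate}

with cell metabolism entering through Michaelis–Menten rate laws:

* oxygen consumption `OCR = Vmax (pH − 4.95) · C / (Km (pH − 4.59) + C)`,
  Km = 12 µM, Vmax = 17 (animal/healthy) or 62 (degenerated human)
  nmol/10⁶ cells/h;
* glucose consumption `GCR = Vmax_g · C / (2 mM + C)` with Vmax_g = 143 /
  103 / 165 nmol/10⁶ cells/h under normoxia / physioxia / hypoxia;
* lactate production tied to glycolysis through the lac:gluc ratio
  (1.4 / 1.6 / 1.8) with a piecewise-linear acidity cut-off;
* pH derived from lactate accumulation by a calibrated linear buffer;
* monolayer proliferation `N(t) = N₀ e^{kt}` (k = 0.348 d⁻¹) capped at
  80 % confluency.

Incubator settings convert to dissolved-oxygen boundary values via
Henry's law with humidity and CO₂ correction
(`pO₂ = f·(760 − 38 − 47) mmHg`, 1.3 µM/mmHg), and results are reported
in gas-phase-equivalent %O₂.  The solver is a conservative finite-volume
scheme (planar, axisymmetric r–z, and spherical symmetries) with
implicit, positivity-preserving time stepping and instantaneous
media-exchange events.  See `docs/methods.md` for the full model and
numerics.

## Worked example

Minimum oxygen inside a single 30 µl alginate bead (8·10⁶ cells/ml,
low-glucose media, 24-well with 2 ml, normoxic incubator) at day 3, just
before the first feed:

```python
from npmicroenv import (named_scenario, run_transient, percent_o2_equivalent)

scenario = named_scenario("bead_24w_LG_NX_8M")
result = run_transient(scenario)
state = result.pre_exchange_snapshot()
bead = result.mesh.region == 1
print(f"min O2  : {percent_o2_equivalent(state.o2_um[bead].min()):.1f} %O2")
print(f"min glc : {state.glucose_mm[bead].min():.2f} mM")
print(f"min pH  : {state.ph(scenario.buffer)[bead].min():.2f}")
```

```
min O2  : 11.0 %O2
min glc : 3.96 mM
min pH  : 7.12
```

Although the incubator is "normoxic" (18.6 %O₂ dissolved-equivalent at
the media surface), the bead interior sits at ~11 %O₂; glucose remains
far from limiting, and the bead core acidifies mildly between feeds.
The same pipeline is exposed on the command line:

```bash
npmicroenv list-scenarios
npmicroenv run --scenario bead_24w_LG_NX_8M --out out/
npmicroenv sweep --base bead_24w_LG_NX --axis density=2,4,8 --out sweep/
```

`run` writes a resolved-scenario echo (JSON), a long-format summary CSV,
an axial profile CSV, the full fields as HDF5, and a solver log.

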