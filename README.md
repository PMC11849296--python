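# dmfsimoa

Simulators of digital-microfluidic (DMF) bead processing for single-molecule
array (digital ELISA) immunoassays.

Ultrasensitive digital immunoassays need two things that conventional DMF
devices are bad at: **large sample volumes** (at 1 aM, a 1 uL droplet holds
fewer than one analyte molecule — 100 uL holds ~60) and **small bead numbers**
(~5000 beads maximize molecules per bead while keeping capture efficiency
acceptable).  This package implements, as a tested pure-software library, the
computational core of a DMF front-end that solves both problems:

* **Droplet-retention physics** (`dmfsimoa.device_physics`) — the
  Young–Lippmann actuation force `F = ½ (ε₀ε_r/t) V² L`, and a Laplace
  pancake-droplet model of the pressure imbalance `Δp = p_neck − p_retained`
  that decides whether a bead-densifying electrode of diameter *d* next to a
  destination electrode of width *w* cleanly splits off a ~0.2 uL
  bead-carrying droplet.  `Δp` is linear in interfacial tension σ, increases
  with the electrowetting factor *k*, and saturates with *w*.
* **Closed-loop capacitance control** (`dmfsimoa.capacitance_control`) — the
  feedback algorithm that automates stepwise loading: a *capacitance
  stability index* (rolling SD of the last 15 samples at ~40 Hz) drives a
  LOAD → SPLIT → WASTE_REMOVAL state machine that advances when, after an
  initial capacitance excursion, the index falls below 2 pF.
* **Loading-strategy simulators** (`dmfsimoa.loading_sim`) — passive
  (absorber-driven virtual channel, Darcy/Washburn wicking, Stokes-drag bead
  loss), parallel (off-chip sub-volumes at DMF-limited velocity), and
  stepwise (~9 uL segments, ~12 cycles for 100 uL, driven by the controller
  against a synthesized capacitance trace).  All runs are seeded and
  conservation-checked: volumes to 1e-9 uL, beads integer-exact.
* **Digital counting statistics** (`dmfsimoa.digital_assay`) — expected
  molecule numbers `cVN_A`, multinomial molecule-to-bead assignment, the
  Poisson-corrected readout AEB `= −ln(1 − f_on)`, bead-retention
  percentages, and the bead-number sensitivity trade-off.
* **Bead imaging** (`dmfsimoa.bead_imaging`) — synthetic brightfield images
  of 2.7 um beads plus a threshold/connected-component/area-rule counting
  pipeline.

## Worked example

```python
>>> import dmfsimoa as dm
>>> stack = dm.DielectricStack(thickness=6e-6, rel_permittivity=3.1)
>>> dm.young_lippmann_force(dm.ActuationState(140), 1.0e-3, stack) * 1e6
44.831704292144          # uN of driving force at 140 V RMS, 1 mm contact line
>>> geom = dm.DeviceGeometry(gap=190e-6, drive_width=2.2e-3, densify_minor=1e-3)
>>> fluid = dm.FluidState(sigma=42e-3, k_factor=0.6)
>>> dm.retention_pressure_imbalance(geom, fluid)
34.68410629402959        # Pa; > 0 means reliable droplet breakup
>>> dm.plan_segments(100, 9)
[9, 9, 9, 9, 9, 9, 9, 9, 9, 9, 9, 1]
>>> result, trace = dm.simulate_stepwise(100, 9, dm.BeadPopulation(5000), geom, fluid, seed=1)
>>> len(result.segments), result.retention_fraction, round(result.retained_droplet_ul, 3)
(12, 1.0, 0.201)
>>> dm.expected_molecules(dm.AssaySample(concentration=1e-18, volume=100e-6))
60.221407600000006
```

A 100 uL, 1 aM sample (~60 molecules) is loaded in 12 closed-loop cycles
with every one of its 5000 beads recovered in a 0.2 uL droplet — the
volume-reduction and bead-retention behaviour the stepwise strategy was
designed for.  The companion command line exposes the same operations:

```sh
dmfsimoa simulate-loading --strategy stepwise --seed 1 --out runs/demo
dmfsimoa gen-trace --volume-ul 100 --out trace.csv
dmfsimoa run-controller --trace trace.csv --cycles 12 --out cycles.jsonl
dmfsimoa assay-sim --conc 1e-18 --volume-ul 100 --beads 5000
```

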