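# Methods

This note documents the models behind `dmfsimoa`, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
design choices made where the underlying physics admits more than one
reasonable reconstruction.

## Droplet pressure model

A droplet squeezed between the plates of a two-plate DMF device (gap
`h`, default 190 um) is treated as a pancake.  Its internal overpressure is
`σ (C_inplane + C_gap)` with `C_gap = −(cos θ_top + cos θ_bottom)/h`; both
plates carry a fluorinated hydrophobic coating with resting contact angle
θ₀ = 115° (configurable), so `C_gap > 0`.  Electrowetting on an actuated
electrode lowers the apparent bottom contact angle.  We parameterize the
shift with a dimensionless factor `k ∈ (0, 1)`:

    cos θ_act = cos θ₀ + k (1 − cos θ₀)

i.e. `k` is the fractional progression from the resting angle toward
complete wetting; it grows with applied voltage and falls with surfactant
concentration.  The retained droplet on the densifying electrode (minor
axis `d`; for oval electrodes the effective in-plane curvature is taken at
the minor axis) has pressure

    p_retained = σ (2/d + C_gap(θ_act)),

and the neck connecting it to the departing liquid is a saddle over an
unactuated region, concave in plane with radius `c (w − d)/2` (`w` the
destination-electrode width, `c` a configurable proportionality constant,
default 1):

    p_neck = σ (−2 / (c (w − d)) + C_gap(θ₀)),
    Δp     = p_neck − p_retained = σ [ k (1 − cos θ₀)/h − 2/d − 2/(c (w − d)) ].

Properties, all tested: Δp is exactly linear in σ, strictly increasing in
`k` for every valid geometry, increasing in `w` with strictly diminishing
increments, and has an interior maximum near `d ≈ w/2` — at the default
geometry (w = 2.2 mm, d = 1.0 mm, σ = 42 mN/m, k = 0.6) Δp ≈ +35 Pa,
favouring breakup; a 1 mm round electrode thus sits near the optimum.
Because Δp ∝ σ, its *sign* is σ-independent: in retention-unfavourable
corners (small `w`, `d` far from `w/2`, small `k`) Δp < 0 and is
*decreasing* in σ.  The σ-monotonicity property is therefore asserted over
the device's breakup operating envelope (w 2.2–3.5 mm, d ≈ w/2, k ≥ 0.55),
not over all geometries.

The sample reservoir is a pancake of footprint radius `r = sqrt(V/(π h))`
with pressure `σ (1/r + C_gap(θ₀))`, strictly decreasing in volume — the
reason the final stepwise splitting cycles are the hard ones, and why the
segment planner offers a `merge-final` policy that folds a small remainder
into the last segment(s).

The Young–Lippmann force `F = ½ (ε₀ ε_r / t) V² L` uses the dielectric
defaults t = 6 um parylene, ε_r = 3.1; between 110 V RMS on a 0.6 mm
contact line and 140 V RMS on a 1.0 mm line it spans ≈ 17–45 uN, the
actuation range over which droplet retention becomes reliable.

## Capacitance-feedback controller

The controller consumes a ~40 Hz capacitance stream.  The *stability
index* is the rolling standard deviation of the last `window` samples
(default 15; population convention `ddof = 0`, configurable — the
streaming implementation keeps O(1) running sums).  Each loading cycle has
three phases, LOAD → SPLIT → WASTE_REMOVAL.  A phase hands over when

1. some sample has exceeded the phase-entry capacitance by `rise_delta`
   (default 20 pF; for WASTE_REMOVAL the condition is instead a *fall* to
   within `rise_delta` of the global baseline), and
2. the latest stability index is below `stability_threshold` (default 2 pF).

The rise guard prevents the quiet pre-motion plateau from triggering an
immediate transition; starvation (a stream that ends before the conditions
are met) raises an error naming the phase rather than silently skipping.

## Synthetic capacitance traces

The trace generator emits, per segment of volume `v`: baseline (100 pF) →
staircase ramp to `100 + (150/9) v` pF (250 pF for a 9 uL segment) → ramp
to the 320 pF split plateau → ramp back to baseline, with plateau holds of
1 s and optional additive Gaussian noise (default SD 0.5 pF in the
stepwise simulator).  The 100/250/320 pF signature and the 150 pF-per-9-uL
slope are device-specific *calibration fixtures*, not physics predictions,
and are fully configurable (`TraceCalibration`).

Two deliberate idealizations:

* Ramps are steep (10 pF/sample, i.e. 400 pF/s) and end-anchored so the
  last pre-plateau sample sits exactly one full step below the plateau.
  Consequently every 15-sample window overlapping motion has SD
  ≥ 10·√14/15 ≈ 2.5 pF > 2 pF, and on a noiseless trace each transition
  lands *exactly* `(window − 1)/rate = 0.35 s` after its plateau begins —
  the analytic oracle the controller tests assert.  Real traces ramp over
  tens of seconds with actuation ripple; the generator compresses motion
  into clean detectable ramps instead of modelling that ripple.
* Trace time is therefore not transport time.  `simulate_stepwise` computes
  `loading_time` from the transport model (volume over
  `v_dmf × gap × drive_width`, plus a 3 s per-cycle overhead), giving
  ≈ 4.6 min for 100 uL at the 1 mm/s default — the few-minute scale of an
  automated closed-loop run.

The default plan for (100 uL, 9 uL) is eleven 9 uL segments plus a 1 uL
remainder (12 cycles).  A 1 uL segment's load rise (16.7 pF) is below the
default 20 pF `rise_delta`, so `simulate_stepwise` caps the run's
`rise_delta` at half the smallest segment's expected rise — small final
segments are exactly where real runs needed special handling, and the
2 pF / 15-sample feedback defaults are untouched.

## Wicking and bead retention

Paper absorbers follow Darcy flow driven by the capillary pressure
`2σ/r_pore` through a capillary-bundle permeability `K = φ r_pore²/8`
(porosity φ = 0.7), against the series resistance of a wick entry length
(default 10 mm — only one ply penetrates the plate gap) plus a Washburn
imbibition length that grows with absorbed volume.  This reproduces the
qualitative catalogue behaviour: thicker papers load faster (Whatman 3,
390 um, beats Whatman 1, 180 um), fine-pored Whatman 42 is slowest, and a
15-ply stack is far faster than a single ply but nowhere near 15× — the
shared wick entry is the bottleneck (time ratio ≈ 0.17 for Whatman 42,
the same order as the roughly-halved load time observed with stacks).
Superabsorbent polymer is modelled as a near-constant sink of
`(100/30/40) uL/s per mg`, calibrated so 40 mg absorbs 100 uL in ~30 s.

A bead is retained at the magnetic trap iff its maximum magnetic force
exceeds the Stokes drag `6π μ r v`.  Per-bead forces are log-normal
(median 240 pN, log-SD 0.44).  These two parameters were calibrated
jointly, in closed form, to the study conditions: at the 25 mg SAP passive
flow (~2.1 uL/s through the 190 um × 2.2 mm channel, ~5 mm/s, with
multiplicative flow noise of log-SD 0.3 and volume-weighted bead arrival)
expected retention is

    E[retention] ≈ Φ( (ln(F_med/drag) − s²) / sqrt(σ_ln² + s²) ) ≈ 0.85,

the ~15% passive bead loss, while at the DMF-limited 1 mm/s the per-pass
retention is 1 − 1.4·10⁻⁶, giving the >99% (parallel, two passes) and
>98% (stepwise) retention of the controlled strategies.  Note the passive
figure follows the 15%-loss reading of the study conditions; the
alternative ~85%-loss reading is inconsistent with the recovered bead
counts and is not modelled.

All simulators conserve volume to 1e-9 uL (waste + retained droplet =
input) and beads integer-exactly; the retained droplet is the densifying
electrode's footprint × gap × a spread factor of 1.35 ≈ 0.2 uL.

## Digital counting

`expected_molecules = c V N_A` is carried as a real expectation (0.60 for
1 uL at 1 aM); realized counts are Poisson-sampled only inside
simulations.  Molecules are assigned to beads multinomially; with
molecules ≪ beads the per-bead counts are Poisson, and the readout
estimator `AEB = −ln(1 − f_on)` inverts the Poisson zero class (at low
`f_on`, AEB ≈ f_on).  The estimator is undefined at `f_on = 1`
(saturation error).  The capture-efficiency model behind the bead-number
trade-off, `eff(n) = 1 − exp(−n/capture_scale)`, is a saturating
reconstruction: only the two monotone trends (efficiency up, molecules
per bead down with increasing `n`) are asserted, not any particular
optimum.

## Bead imaging

The image generator renders anti-aliased dark disks (2.7 um beads,
0.33 um/px, i.e. ~4 px radius) at uniform non-overlapping positions on a
bright background with additive Gaussian noise; placement uses
grid-accelerated rejection sampling and fails loudly when the requested
density is unreachable.  The counter smooths (σ = 1 px), thresholds (Otsu,
with a median/MAD fallback when Otsu would flag an implausibly large
foreground, as on a bead-free frame), labels connected components, and
applies an area rule: an object within ±40% of `k` single-bead areas
counts as `k` beads up to a cap of 3 (`cluster_policy="split"`), or as one
object (`"single"`) — both behaviours are offered because real counting
scripts differ on this.  Coordinates are pixel-centred, top-left origin,
x rightward, y downward.  On noiseless non-overlapping images recovery is
exact up to the packing limit; with noise up to 10% of contrast it is
within ±2% for 100–1000 beads at the tested seeds.  The generator does not
emulate focus drift, uneven illumination, or out-of-plane beads, so
passing tests certify the pipeline's logic, not microscope robustness.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the stochastic checks at
deliberately desk-sized scales — 1000 randomized conservation runs at
5–40 uL, AEB recovery with 200 replicates × 5000 beads, image recovery at
up to 1000 beads in 1024² px — sizes chosen so the whole suite completes
in seconds while keeping Monte-Carlo standard errors well inside the
asserted tolerances.  Every stochastic component takes an explicit seed;
a single seed fans out to per-stage substreams (`numpy.random.SeedSequence`)
so adding a stage never perturbs earlier stages' randomness, and identical
seeds give bit-identical traces, ledgers, and images.

## Known limitations

* The Δp model is a quasi-static Laplace decomposition: no contact-angle
  saturation, AC-frequency dependence, droplet relaxation dynamics, or CFD.
* Quantities measured only experimentally in the motivating system
  (loading-time curves per absorber, retained-volume distributions,
  immunoassay calibration curves) are represented by calibration fixtures
  or qualitative orderings, not predicted.
* The magnetic lens is reduced to a per-bead force distribution; there is
  no spatial field map or bead trajectory model.
* The wicking model is one-dimensional; fan-out of large single-ply
  absorbers is folded into effective parameters.
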