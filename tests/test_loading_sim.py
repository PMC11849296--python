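"""Loading-strategy simulator tests: wicking, drag balance, conservation.

Calibration anchors (ordering of paper grades, the stack speed-up, the
passive-loading bead loss, >99% parallel and >98% stepwise retention) are
order-of-magnitude reproductions of the study conditions the simulators
emulate; exact assertions cover the conservation laws and determinism.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmfsimoa import (
    AbsorberSpec,
    BeadPopulation,
    ControllerConfig,
    FluidState,
    bead_retained_fraction,
    simulate_parallel,
    simulate_passive,
    simulate_stepwise,
    synth_capacitance_trace,
    wicking_flow_rate,
)
from dmfsimoa.errors import InvalidInputError
from dmfsimoa.loading_sim import TraceCalibration, time_to_absorb


class TestWicking:
    def test_doubling_cross_section_doubles_rate(self, fluid, geom):
        base = AbsorberSpec.whatman("42")
        thick = AbsorberSpec.whatman("42", thickness=base.thickness * 2)
        for t in (0.0, 5.0, 60.0):
            assert wicking_flow_rate(thick, fluid, geom, t) == pytest.approx(
                2 * wicking_flow_rate(base, fluid, geom, t), rel=1e-12
            )

    def test_paper_rate_decays_with_time(self, fluid, geom):
        absorber = AbsorberSpec.whatman("1")
        rates = [wicking_flow_rate(absorber, fluid, geom, t) for t in (0, 10, 60, 300)]
        assert all(b < a for a, b in zip(rates, rates[1:]))

    def test_fifteen_ply_stack_is_substantially_faster(self, fluid, geom):
        single = time_to_absorb(100.0, AbsorberSpec.whatman("42"), fluid, geom)
        stack = time_to_absorb(100.0, AbsorberSpec.whatman("42", layers=15), fluid, geom)
        # printed observation: load time roughly halved; the wick-entry
        # bottleneck keeps the ratio the same order of magnitude
        assert 0.025 < stack / single < 0.9

    def test_thicker_paper_loads_faster(self, fluid, geom):
        t_w3 = time_to_absorb(100.0, AbsorberSpec.whatman("3"), fluid, geom)
        t_w1 = time_to_absorb(100.0, AbsorberSpec.whatman("1"), fluid, geom)
        assert t_w3 < t_w1

    def test_sap_is_constant_sink_scaling_with_mass(self, fluid, geom):
        sap25 = AbsorberSpec.sap(25.0)
        sap40 = AbsorberSpec.sap(40.0)
        assert wicking_flow_rate(sap25, fluid, geom, 0.0) == pytest.approx(
            wicking_flow_rate(sap25, fluid, geom, 100.0)
        )
        assert wicking_flow_rate(sap40, fluid, geom, 0.0) > wicking_flow_rate(
            sap25, fluid, geom, 0.0
        )
        # 40 mg of sodium polyacrylate takes up 100 uL in ~30 s
        assert time_to_absorb(100.0, sap40, fluid, geom) == pytest.approx(30.0, rel=0.05)


class TestBeadRetainedFraction:
    def test_zero_velocity_retains_everything(self, fluid):
        assert bead_retained_fraction(0.0, BeadPopulation(100), fluid) == 1.0

    def test_no_trap_loses_everything(self, fluid):
        beads = BeadPopulation(100, magnetic_force_median=0.0)
        assert bead_retained_fraction(1e-3, beads, fluid) == 0.0

    def test_median_threshold_velocity_gives_half(self, fluid):
        beads = BeadPopulation(100)
        v_star = beads.magnetic_force_median / (
            3 * math.pi * fluid.viscosity * beads.diameter
        )
        assert bead_retained_fraction(v_star, beads, fluid) == pytest.approx(0.5)

    def test_negative_velocity_rejected(self, fluid):
        with pytest.raises(InvalidInputError):
            bead_retained_fraction(-1.0, BeadPopulation(10), fluid)

    @given(v=st.floats(1e-5, 1.0), dv=st.floats(1e-5, 1.0))
    def test_non_increasing_in_velocity(self, fluid, v, dv):
        beads = BeadPopulation(100)
        assert bead_retained_fraction(v + dv, beads, fluid) <= bead_retained_fraction(
            v, beads, fluid
        )

    @given(v=st.floats(1e-4, 0.5), scale=st.floats(1.1, 20.0))
    def test_non_decreasing_in_magnetic_force(self, fluid, v, scale):
        weak = BeadPopulation(100)
        strong = BeadPopulation(
            100, magnetic_force_median=weak.magnetic_force_median * scale
        )
        assert bead_retained_fraction(v, strong, fluid) >= bead_retained_fraction(
            v, weak, fluid
        )


class TestSimulatePassive:
    def test_fast_absorber_loses_beads(self, beads, geom, fluid):
        result = simulate_passive(100.0, beads, AbsorberSpec.sap(25.0), geom, fluid, seed=1)
        assert result.retention_fraction < 0.90
        assert result.beads_retained + result.beads_lost == beads.count
        assert result.waste_total_ul + result.retained_droplet_ul == pytest.approx(
            100.0, abs=1e-9
        )

    def test_zero_flow_retains_everything(self, beads, geom, fluid):
        stalled = AbsorberSpec.sap(0.0)
        result = simulate_passive(100.0, beads, stalled, geom, fluid, seed=1)
        assert result.retention_fraction == 1.0
        assert result.waste_total_ul == 0.0

    def test_no_beads_degenerate_input(self, geom, fluid):
        result = simulate_passive(
            50.0, BeadPopulation(0), AbsorberSpec.sap(25.0), geom, fluid, seed=0
        )
        assert result.beads_retained == result.beads_lost == 0
        assert result.waste_total_ul + result.retained_droplet_ul == pytest.approx(50.0)


class TestSimulateParallel:
    def test_four_subvolumes_retain_over_99_percent(self, beads, geom, fluid):
        result = simulate_parallel(100.0, 4, beads, geom, fluid, seed=1)
        assert result.retention_fraction >= 0.99

    def test_single_subvolume_matches_whole_volume_run(self, beads, geom, fluid):
        as_count = simulate_parallel(100.0, 1, beads, geom, fluid, seed=7)
        as_list = simulate_parallel(100.0, [100.0], beads, geom, fluid, seed=7)
        assert as_count == as_list

    def test_unequal_subvolumes_conserve(self, beads, geom, fluid):
        result = simulate_parallel(100.0, [10.0, 50.0, 40.0], beads, geom, fluid, seed=2)
        assert result.beads_retained + result.beads_lost == beads.count
        assert result.waste_total_ul + result.retained_droplet_ul == pytest.approx(100.0)

    def test_mismatched_subvolumes_rejected(self, beads, geom, fluid):
        with pytest.raises(InvalidInputError):
            simulate_parallel(100.0, [10.0, 50.0], beads, geom, fluid)


class TestSimulateStepwise:
    def test_100ul_gives_12_cycles_and_high_retention(self, beads, geom, fluid):
        result, trace = simulate_stepwise(100.0, 9.0, beads, geom, fluid, seed=1)
        assert len(result.segments) == 12
        assert result.retention_fraction >= 0.98
        assert len(trace) > 0

    def test_volume_equal_to_nominal_is_single_cycle(self, beads, geom, fluid):
        result, _ = simulate_stepwise(9.0, 9.0, beads, geom, fluid, seed=1)
        assert result.segments == (9.0,)

    def test_identical_seeds_bit_identical(self, beads, geom, fluid):
        r1, t1 = simulate_stepwise(100.0, 9.0, beads, geom, fluid, seed=42)
        r2, t2 = simulate_stepwise(100.0, 9.0, beads, geom, fluid, seed=42)
        assert r1 == r2
        assert np.array_equal(t1.capacitance, t2.capacitance)

    def test_custom_controller_defaults_flow_through(self, beads, geom, fluid):
        cfg = ControllerConfig(window=10, stability_threshold=3.0)
        result, _ = simulate_stepwise(
            27.0, 9.0, beads, geom, fluid, config=cfg, seed=0
        )
        assert len(result.segments) == 3


class TestSynthTrace:
    def test_zero_segments_flat_baseline(self):
        trace = synth_capacitance_trace([], noise_sd=0.0)
        assert np.all(trace.capacitance == 100.0)

    def test_half_segment_plateaus_at_175(self):
        # 150 pF per 9 uL calibration: 4.5 uL -> 175 pF load plateau
        trace = synth_capacitance_trace([4.5], noise_sd=0.0)
        assert 175.0 in trace.capacitance

    def test_nine_ul_signature_levels(self):
        trace = synth_capacitance_trace([9.0], noise_sd=0.0)
        for level in (100.0, 250.0, 320.0):
            assert np.sum(trace.capacitance == level) >= 15

    def test_seeded_noise_reproducible(self):
        t1 = synth_capacitance_trace([9.0], noise_sd=1.0, seed=9)
        t2 = synth_capacitance_trace([9.0], noise_sd=1.0, seed=9)
        assert np.array_equal(t1.capacitance, t2.capacitance)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidInputError):
            synth_capacitance_trace([9.0], noise_sd=-1.0)

    def test_calibration_is_configurable_fixture(self):
        calib = TraceCalibration(baseline_pF=80.0, split_plateau_pF=300.0)
        trace = synth_capacitance_trace([9.0], calib=calib, noise_sd=0.0)
        assert trace.capacitance[0] == 80.0
        assert np.max(trace.capacitance) == 300.0


class TestRetentionOrdering:
    def test_stepwise_and_parallel_beat_passive(self, beads, geom, fluid):
        passive = simulate_passive(
            100.0, beads, AbsorberSpec.sap(25.0), geom, fluid, seed=5
        )
        parallel = simulate_parallel(100.0, 4, beads, geom, fluid, seed=5)
        stepwise, _ = simulate_stepwise(100.0, 9.0, beads, geom, fluid, seed=5)
        assert stepwise.retention_fraction > passive.retention_fraction
        assert parallel.retention_fraction > passive.retention_fraction
        assert abs(stepwise.retention_fraction - parallel.retention_fraction) < 0.02
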