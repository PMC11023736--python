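"""CMJ feature extraction: asymmetry index algebra, phase detection, metric
computation, round-trip recovery of planted trace parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from courtwatch import cmj
from courtwatch.cmj import (CMJMetrics, ForceTrace, GRAVITY, NoMovementError,
                            UndefinedIndexError, asymmetry_index,
                            average_trials)
from courtwatch.synthetic import generate_cmj_trace

from conftest import jump_params, make_profile


class TestAsymmetryIndex:
    @pytest.mark.parametrize("left,right,expected", [
        (100.0, 100.0, 0.0),
        (110.0, 90.0, -20.0),       # left-dominant loading -> negative sign
        (90.0, 110.0, 20.0),
        (1.0, 3.0, 100.0),
    ])
    def test_mean_referenced_values(self, left, right, expected):
        assert asymmetry_index(left, right) == pytest.approx(expected)

    def test_undefined_when_sum_zero(self):
        with pytest.raises(UndefinedIndexError):
            asymmetry_index(1.0, -1.0)

    def test_max_referenced_variant(self):
        assert asymmetry_index(110.0, 90.0, method="max") == pytest.approx(
            100.0 * (90 - 110) / 110)

    @given(left=st.floats(0.1, 1e4), right=st.floats(0.1, 1e4))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry(self, left, right):
        assert asymmetry_index(left, right) == pytest.approx(
            -asymmetry_index(right, left))

    @given(left=st.floats(0.1, 1e4), right=st.floats(0.1, 1e4),
           c=st.floats(1e-3, 1e3))
    @settings(max_examples=100, derandomize=True)
    def test_scale_equivariance(self, left, right, c):
        assert asymmetry_index(c * left, c * right) == pytest.approx(
            asymmetry_index(left, right), rel=1e-9)


class TestPhaseDetection:
    def test_flat_trace_raises_no_movement(self, profile):
        n = 3000
        f = np.full(n, profile.body_mass * GRAVITY / 2.0)
        trace = ForceTrace(time=np.arange(n) / 1000.0, f_left=f, f_right=f,
                           body_mass=profile.body_mass, sample_rate=1000.0)
        with pytest.raises(NoMovementError):
            cmj.detect_phases(trace)

    def test_planted_takeoff_recovered_within_two_samples(self, profile):
        trace = generate_cmj_trace(profile, jump_params(), seed=0)
        phases = cmj.detect_phases(trace)
        assert abs(phases.takeoff - trace.meta["takeoff_idx"]) <= 2
        assert abs(phases.touchdown - trace.meta["touchdown_idx"]) <= 2
        assert abs(phases.onset - trace.meta["onset_idx"]) <= 2

    def test_braking_end_is_velocity_zero_crossing(self, profile):
        # the velocity changes sign across the detected braking end; its
        # residual magnitude is bounded by one sample of integration
        trace = generate_cmj_trace(profile, jump_params(), seed=0)
        phases = cmj.detect_phases(trace)
        v = cmj._velocity(trace, phases.onset)
        assert v[phases.braking_end - 1] < 0.0 <= v[phases.braking_end]
        assert abs(v[phases.braking_end]) < 0.02

    def test_boundaries_strictly_ordered(self, profile):
        trace = generate_cmj_trace(profile, jump_params(), seed=1)
        p = cmj.detect_phases(trace)
        assert (p.onset < p.braking_start < p.braking_end
                < p.takeoff < p.touchdown)


class TestMetrics:
    def test_jump_height_from_takeoff_velocity(self):
        # v_to = 2.215 m/s corresponds to 0.25 m by v^2 / (2 g)
        assert 2.215 ** 2 / (2 * GRAVITY) == pytest.approx(0.25, abs=5e-3)

    def test_rsi_mod_identity_and_reported_ratios(self, profile):
        # season-mean jump height / time-to-takeoff pairs: 0.24/0.84 -> 0.29
        # and 0.26/0.79 -> 0.33 at two decimals
        for jh, ttt, expected in [(0.24, 0.84, 0.29), (0.26, 0.79, 0.33)]:
            trace = generate_cmj_trace(profile,
                                       jump_params(jump_height=jh, ttt=ttt),
                                       seed=0)
            m = cmj.extract_metrics(trace)
            assert m.rsi_mod == pytest.approx(m.jump_height / m.time_to_takeoff)
            assert round(m.rsi_mod, 2) == expected

    def test_symmetric_trace_zero_asymmetries(self, profile):
        trace = generate_cmj_trace(profile, jump_params(), seed=2)
        m = cmj.extract_metrics(trace)
        for name in ("asym_peak_braking_force", "asym_peak_propulsive_force",
                     "asym_avg_braking_rfd", "asym_peak_landing_force"):
            assert abs(getattr(m, name)) < 0.5

    def test_braking_power_negative_propulsive_positive(self, profile):
        m = cmj.extract_metrics(generate_cmj_trace(profile, jump_params(), 3))
        assert m.peak_rel_braking_power < 0 < m.peak_rel_propulsive_power

    def test_scale_equivariance_of_trace_asymmetries(self, profile):
        trace = generate_cmj_trace(
            profile, jump_params(cmj_braking=-8.0, cmj_propulsive=5.0,
                                 cmj_rfd=-15.0, cmj_landing=10.0), seed=4)
        m1 = cmj.extract_metrics(trace)
        scaled = ForceTrace(time=trace.time, f_left=2.0 * trace.f_left,
                            f_right=2.0 * trace.f_right,
                            body_mass=2.0 * trace.body_mass,
                            sample_rate=trace.sample_rate)
        m2 = cmj.extract_metrics(scaled)
        for name in ("asym_peak_braking_force", "asym_peak_propulsive_force",
                     "asym_avg_braking_rfd", "asym_peak_landing_force"):
            assert getattr(m2, name) == pytest.approx(getattr(m1, name),
                                                      abs=1e-9)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_planted_parameters_recovered(self, profile, seed):
        rng = np.random.default_rng(seed)
        depth = rng.uniform(-0.34, -0.22)
        ttt = float(np.clip(0.30 + 1.9 * abs(depth) + rng.normal(0, 0.05),
                            0.70, 1.10))
        params = jump_params(
            jump_height=rng.uniform(0.16, 0.36), depth=depth, ttt=ttt,
            cmj_braking=rng.normal(0, 7), cmj_propulsive=rng.normal(0, 4.7),
            cmj_rfd=rng.normal(0, 12), cmj_landing=rng.normal(0, 14))
        trace = generate_cmj_trace(profile, params, rng)
        m = cmj.extract_metrics(trace)
        assert m.jump_height == pytest.approx(params["jump_height"], rel=0.01)
        assert m.countermovement_depth == pytest.approx(
            params["countermovement_depth"], rel=0.01)
        assert abs(m.time_to_takeoff - params["time_to_takeoff"]) <= 1e-3
        for field, channel in [("asym_peak_braking_force", "cmj_braking"),
                               ("asym_peak_propulsive_force", "cmj_propulsive"),
                               ("asym_avg_braking_rfd", "cmj_rfd"),
                               ("asym_peak_landing_force", "cmj_landing")]:
            assert getattr(m, field) == pytest.approx(
                params["asym"][channel], abs=1.0)

    def test_flight_time_height_agrees_with_impulse_height(self, profile):
        trace = generate_cmj_trace(profile, jump_params(jump_height=0.30),
                                   seed=5)
        phases = cmj.detect_phases(trace)
        m = cmj.compute_metrics(trace, phases)
        assert cmj.flight_time_height(trace, phases) == pytest.approx(
            m.jump_height, rel=0.02)

    def test_impulse_consistency(self, profile):
        # net vertical impulse over the movement equals m * v_takeoff
        trace = generate_cmj_trace(profile, jump_params(), seed=6)
        i0, i2 = trace.meta["onset_idx"], trace.meta["takeoff_idx"]
        v = np.trapezoid(trace.f_total[i0:i2] / trace.body_mass - GRAVITY,
                         dx=1.0 / trace.sample_rate)
        assert v == pytest.approx(trace.meta["v_takeoff"], rel=1e-6)


class TestAverageTrials:
    def test_single_trial_identity(self, profile):
        m = cmj.extract_metrics(generate_cmj_trace(profile, jump_params(), 7))
        assert average_trials([m]) == m

    def test_elementwise_mean_and_ratio_of_ratios(self):
        def mk(jh, ttt, rsi):
            return CMJMetrics(jump_height=jh, countermovement_depth=-0.3,
                              time_to_takeoff=ttt, peak_rel_braking_power=-10,
                              peak_rel_propulsive_power=40, rsi_mod=rsi,
                              asym_peak_braking_force=0,
                              asym_peak_propulsive_force=0,
                              asym_avg_braking_rfd=0,
                              asym_peak_landing_force=0)
        avg = average_trials([mk(0.20, 0.8, 0.28), mk(0.30, 0.9, 0.32)])
        assert avg.jump_height == pytest.approx(0.25)
        # RSImod averages per-trial ratios, not the ratio of averaged parts
        assert avg.rsi_mod == pytest.approx(0.30)
        assert avg.rsi_mod != pytest.approx(avg.jump_height
                                            / avg.time_to_takeoff)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            average_trials([])
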