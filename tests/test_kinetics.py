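import math

import numpy as np
import pytest

from burstloco.errors import NoStrideError, ValidationError
from burstloco.io import ForceTrace
from burstloco.kinematics import kinematic_velocity_window, smooth_trajectory
from burstloco.kinetics import (com_power, escape_speed, girdle_accelerations,
                                mean_acceleration, optimize_v0, process_trial,
                                segment_stride, stance_threshold_n,
                                work_energy_acceleration)
from burstloco.simulate import TrialSimParams, simulate_trial

from conftest import level_trial


def _pulse_trace(on=0.10, off=0.35, peak=10.0, rate=500.0, total=0.5):
    t = np.arange(int(total * rate) + 1) / rate
    f_v = np.where((t >= on) & (t <= off), peak, 0.0)
    return ForceTrace(time=t, f_fa=np.zeros_like(t), f_v=f_v)


class TestSegmentStride:
    def test_all_zero_trace_raises(self):
        t = np.arange(100) / 500.0
        trace = ForceTrace(time=t, f_fa=np.zeros(100), f_v=np.zeros(100))
        with pytest.raises(NoStrideError):
            segment_stride(trace, threshold_n=1.0)

    def test_single_stance_pulse_boundaries(self):
        stride = segment_stride(_pulse_trace(), threshold_n=1.0)
        assert stride.t0 == pytest.approx(0.10, abs=0.002)
        assert stride.t_end == pytest.approx(0.35, abs=0.002)
        assert stride.fore_interval is None  # single stance -> hindlimb
        assert stride.stroke_duration == pytest.approx(0.25, abs=0.004)

    def test_two_plate_girdle_assignment(self, clean_trial):
        bundle, truth = clean_trial
        stride = segment_stride(bundle.force, stance_threshold_n(1.0))
        assert stride.fore_plate == 1
        assert stride.hind_plate == 2
        assert stride.fore_interval[0] == pytest.approx(
            truth.fore_stance_s[0], abs=0.002)
        assert stride.hind_interval[1] == pytest.approx(
            truth.hind_stance_s[1], abs=0.002)

    def test_detection_robust_to_broadband_noise(self, noisy_trial):
        bundle, truth = noisy_trial
        stride = segment_stride(bundle.force,
                                stance_threshold_n(bundle.body_mass))
        assert stride.t0 == pytest.approx(truth.stride_t0_s, abs=0.01)
        assert stride.t_end == pytest.approx(truth.stride_t_end_s, abs=0.01)


class TestMeanAcceleration:
    def test_constant_force_quotient(self, clean_trial):
        bundle, _ = clean_trial
        stride = segment_stride(bundle.force, stance_threshold_n(1.0))
        assert mean_acceleration(stride, bundle.force, 1.0) == pytest.approx(
            4.0, rel=1e-6)
        assert mean_acceleration(stride, bundle.force, 2.0) == pytest.approx(
            2.0, rel=1e-6)

    def test_half_sine_matches_truth(self):
        bundle, truth = simulate_trial(TrialSimParams(
            accel_mean_m_s2=6.0, accel_profile="half-sine", seed=3))
        stride = segment_stride(bundle.force, stance_threshold_n(0.8))
        a = mean_acceleration(stride, bundle.force, 0.8)
        assert a == pytest.approx(truth.accel_mean_m_s2, rel=0.01)

    def test_zero_force_zero_accel(self):
        trace = _pulse_trace()
        stride = segment_stride(trace, threshold_n=1.0)
        assert mean_acceleration(stride, trace, 1.0) == 0.0


class TestEscapeSpeed:
    def test_rectangle_impulse(self):
        bundle = level_trial(mass=1.0, accel=5.0, stride=0.2)
        stride = segment_stride(bundle.force, stance_threshold_n(1.0))
        assert escape_speed(stride, bundle.force, 1.0, v0=0.5) == \
            pytest.approx(1.5, rel=1e-6)
        assert escape_speed(stride, bundle.force, 1.0, v0=0.0) == \
            pytest.approx(1.0, rel=1e-6)

    def test_matches_truth_noiseless(self):
        bundle, truth = simulate_trial(TrialSimParams(
            accel_mean_m_s2=5.0, v0_m_s=0.3, accel_profile="half-sine",
            body_mass_kg=0.8, seed=6))
        stride = segment_stride(bundle.force, stance_threshold_n(0.8))
        v = escape_speed(stride, bundle.force, 0.8, v0=0.3)
        assert v == pytest.approx(truth.v_esc_m_s, abs=1e-4)


class TestOptimizeV0:
    def test_self_consistency_and_linearity(self, clean_trial):
        bundle, truth = clean_trial
        stride = segment_stride(bundle.force, stance_threshold_n(1.0))
        sm = smooth_trajectory(bundle.markers)
        prof = kinematic_velocity_window(sm, stride.t0, stride.t_end)
        # replace the kinematic profile by the kinetic one at v0 = 0.3
        from burstloco.kinetics import _kinetic_velocity_at
        prof.v_fa = 0.3 + _kinetic_velocity_at(bundle.force, stride, 1.0,
                                               prof.time)
        v0, ssd = optimize_v0(stride, bundle.force, 1.0, prof, 0.3)
        assert v0 == pytest.approx(0.3, abs=1e-9)
        assert ssd == pytest.approx(0.0, abs=1e-12)
        # shifting the kinematic profile shifts v0 exactly
        prof.v_fa = prof.v_fa + 0.2
        v0b, _ = optimize_v0(stride, bundle.force, 1.0, prof, 0.5)
        assert v0b == pytest.approx(0.5, abs=1e-9)

    def test_recovers_truth_with_marker_noise(self):
        errs = []
        for seed in range(8):
            bundle, truth = simulate_trial(TrialSimParams(
                accel_mean_m_s2=5.0, v0_m_s=0.3, marker_noise_sd_m=1e-3,
                body_mass_kg=0.8, seed=seed))
            perf = process_trial(bundle)
            errs.append(abs(perf.v0 - 0.3))
        assert np.median(errs) < 0.05


class TestComPower:
    def test_level_constant_force_work_energy(self):
        """Level trial, a = 4, M = 1, single full-stride stance of 0.25 s:
        the COM gains 0.5 J so mean power is 2 W."""
        bundle = level_trial(mass=1.0, accel=4.0, stride=0.25)
        stride = segment_stride(bundle.force, stance_threshold_n(1.0))
        p = com_power(stride, bundle.force, 1.0, v0=0.0)
        assert p == pytest.approx(2.0, rel=0.01)

    def test_zero_net_force_zero_power(self):
        bundle = level_trial(mass=1.0, accel=0.0, stride=0.25)
        stride = segment_stride(bundle.force, stance_threshold_n(1.0))
        assert com_power(stride, bundle.force, 1.0, v0=0.0) == \
            pytest.approx(0.0, abs=1e-9)

    def test_matches_delta_ke_without_vertical_motion(self):
        bundle = level_trial(mass=0.8, accel=6.0, stride=0.3, v0=0.2)
        stride = segment_stride(bundle.force, stance_threshold_n(0.8))
        v_esc = escape_speed(stride, bundle.force, 0.8, v0=0.2)
        p = com_power(stride, bundle.force, 0.8, v0=0.2)
        delta_ke = 0.5 * 0.8 * (v_esc**2 - 0.2**2)
        assert p == pytest.approx(delta_ke / stride.stroke_duration, rel=0.02)


class TestWorkEnergyAcceleration:
    def test_perfect_square(self):
        assert work_energy_acceleration(8.0, 1.0, 0.25) == pytest.approx(4.0)

    def test_sqrt_scaling(self):
        a1 = work_energy_acceleration(2.0, 1.0, 0.25)
        a2 = work_energy_acceleration(8.0, 1.0, 0.25)
        assert a2 == pytest.approx(2.0 * a1)

    def test_algebraic_inversion(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, m, t = rng.uniform(0.5, 10, 3)
            p = 2.0 * m * t * a**2
            assert work_energy_acceleration(p, m, t) == pytest.approx(a)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            work_energy_acceleration(-1.0, 1.0, 0.25)
        with pytest.raises(ValidationError):
            work_energy_acceleration(1.0, 1.0, 0.0)


class TestGirdleAccelerations:
    def test_symmetry_and_linearity(self):
        bundle = level_trial(mass=1.0, accel=4.0, stride=0.25, hind_frac=0.5)
        stride = segment_stride(bundle.force, stance_threshold_n(1.0))
        fore, hind = girdle_accelerations(stride, bundle.force, 1.0)
        assert fore == pytest.approx(hind, rel=1e-6)
        assert fore == pytest.approx(4.0, rel=1e-6)

    def test_missing_girdle_flagged_nan(self):
        bundle = level_trial(mass=1.0, accel=4.0)
        stride = segment_stride(bundle.force, stance_threshold_n(1.0))
        fore, hind = girdle_accelerations(stride, bundle.force, 1.0)
        assert math.isnan(fore)
        assert hind == pytest.approx(4.0, rel=1e-6)

    def test_stride_mean_decomposes_over_girdles(self, clean_trial):
        """Duration-weighted girdle means plus unloaded spans reproduce the
        whole-stride acceleration."""
        bundle, _ = clean_trial
        m = bundle.body_mass
        stride = segment_stride(bundle.force, stance_threshold_n(m))
        a_com = mean_acceleration(stride, bundle.force, m)
        fore, hind = girdle_accelerations(stride, bundle.force, m)
        d_f = stride.fore_interval[1] - stride.fore_interval[0]
        d_h = stride.hind_interval[1] - stride.hind_interval[0]
        # flight-phase contribution (constant profile -> same acceleration)
        d_total = stride.duration
        a_flight = 4.0
        combo = (fore * d_f + hind * d_h
                 + a_flight * (d_total - d_f - d_h)) / d_total
        assert combo == pytest.approx(a_com, rel=0.02)


class TestPipelineInvariants:
    def test_impulse_velocity_consistency(self, noisy_trial):
        """v_esc - v0 = a_COM * stride duration on any trial."""
        bundle, _ = noisy_trial
        perf = process_trial(bundle)
        stride = segment_stride(bundle.force,
                                stance_threshold_n(bundle.body_mass))
        assert perf.v_esc - perf.v0 == pytest.approx(
            perf.a_com * stride.duration, rel=0.02)

    def test_full_pipeline_noiseless_recovery(self, clean_trial):
        bundle, truth = clean_trial
        perf = process_trial(bundle)
        assert perf.a_com == pytest.approx(4.0, rel=1e-6)
        assert perf.v0 == pytest.approx(0.0, abs=5e-3)
        assert perf.v_esc == pytest.approx(truth.v_esc_m_s, rel=2e-3)
        assert perf.p_com > 0
        assert perf.stroke_duration == pytest.approx(
            truth.stroke_duration_s, abs=0.004)
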