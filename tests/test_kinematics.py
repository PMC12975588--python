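import numpy as np
import pytest
from scipy import signal

from fingerkick.errors import DataError, NoMovementError
from fingerkick.kinematics import (
    KinematicsOptions,
    detect_onset_offset,
    differentiate,
    extract_parameters,
    lateral_deviation,
    lowpass_filter,
)
from fingerkick.simulate import TrialShape, minimum_jerk, simulate_trial
from fingerkick.types import FilteredTraces, MovementSegment

FS = 70.0


def dual_pass_gain(freq_hz, fs=FS, cutoff=10.0, order=2):
    """Analytic magnitude of the discrete forward-backward Butterworth filter."""
    b, a = signal.butter(order, cutoff / (fs / 2.0))
    _, h = signal.freqz(b, a, worN=[2 * np.pi * freq_hz / fs])
    return float(np.abs(h[0]) ** 2)  # two passes


def sine_trace(freq_hz, n=700, fs=FS, amp=1.0):
    t = np.arange(n) / fs
    return np.column_stack([amp * np.sin(2 * np.pi * freq_hz * t), np.zeros(n), np.zeros(n)])


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        pos = np.full((200, 3), 50.0)
        np.testing.assert_allclose(lowpass_filter(pos, FS), pos, atol=1e-9)

    @pytest.mark.parametrize("freq", [2.0, 20.0])
    def test_matches_analytic_dual_pass_response(self, freq):
        pos = sine_trace(freq)
        out = lowpass_filter(pos, FS)
        # compare RMS in the central window to dodge edge transients
        mid = slice(150, 550)
        gain = np.sqrt(np.mean(out[mid, 0] ** 2) / np.mean(pos[mid, 0] ** 2))
        assert gain == pytest.approx(dual_pass_gain(freq), rel=0.01)

    def test_passband_amplitude_preserved(self):
        out = lowpass_filter(sine_trace(2.0), FS)
        assert np.max(np.abs(out[150:550, 0])) == pytest.approx(1.0, rel=0.01)

    def test_idempotent_in_passband(self):
        once = lowpass_filter(sine_trace(1.0), FS)
        twice = lowpass_filter(once, FS)
        a1 = np.max(np.abs(once[150:550, 0]))
        a2 = np.max(np.abs(twice[150:550, 0]))
        assert abs(a2 - a1) / a1 < 0.02

    def test_too_short_trace_rejected(self):
        with pytest.raises(DataError, match="too short"):
            lowpass_filter(np.zeros((5, 3)), FS)


class TestDifferentiate:
    def test_uniform_straight_line(self):
        n = 100
        pos = np.column_stack([np.zeros(n), np.zeros(n), 100.0 * np.arange(n) / FS])
        tr = differentiate(pos, FS)
        np.testing.assert_allclose(tr.speed, 100.0, rtol=1e-9)
        np.testing.assert_allclose(tr.accel, 0.0, atol=1e-6)

    def test_stationary(self):
        tr = differentiate(np.full((50, 3), 7.0), FS)
        np.testing.assert_allclose(tr.speed, 0.0, atol=1e-12)

    def test_minimum_jerk_peak_speed(self):
        # amplitude 100 mm in 0.5 s -> peak 1.875*100/0.5 = 375 mm/s
        n = 2000  # dense sampling so discretization error is negligible
        fs = n / 0.5
        tau = np.arange(n + 1) / n
        s, _ = minimum_jerk(tau)
        pos = np.column_stack([np.zeros(n + 1), np.zeros(n + 1), 100.0 * s])
        tr = differentiate(pos, fs)
        assert np.max(tr.speed) == pytest.approx(375.0, rel=0.01)


def _traces(speed, fs=FS):
    n = speed.size
    return FilteredTraces(pos=np.zeros((n, 3)), speed=speed, accel=np.zeros(n), fs=fs)


class TestOnsetOffset:
    def test_onset_at_first_sustained_crossing(self):
        speed = np.concatenate([np.zeros(20), np.full(40, 10.0)])
        seg = detect_onset_offset(_traces(speed))
        assert seg.onset_idx == 20
        assert seg.offset_idx == speed.size - 1  # never drops below again

    def test_short_burst_is_no_movement(self):
        speed = np.concatenate([np.zeros(20), np.full(20, 10.0), np.zeros(30)])
        with pytest.raises(NoMovementError):
            detect_onset_offset(_traces(speed))

    def test_offset_after_kick_via_target_fallback(self):
        speed = np.concatenate([np.zeros(10), np.full(40, 10.0), np.zeros(20)])
        n = speed.size
        pos = np.zeros((n, 3))
        pos[:, 2] = np.concatenate([np.zeros(10), np.linspace(0, 50, 40), np.full(20, 50.0)])
        traces = FilteredTraces(pos=pos, speed=speed, accel=np.zeros(n), fs=FS)
        seg = detect_onset_offset(traces, target=np.array([0.0, 0.0, 30.0]))
        assert seg.onset_idx == 10
        assert seg.kick_idx is not None and 10 < seg.kick_idx <= seg.offset_idx
        assert seg.offset_idx == 50  # first sub-threshold sample after the kick

    def test_synthetic_trial_events_within_one_sample(self):
        shape = TrialShape(mh=62.0, dev=-4.5, mt_nominal=0.9, mv=250.0)
        traj, truth = simulate_trial(shape, marker_noise_mm=0.2, rng=np.random.default_rng(7))
        rec = extract_parameters(traj, options=KinematicsOptions(target_mm=(0, 0, 500)))
        assert abs(rec.segment.onset_idx - truth.onset_idx) <= 1
        assert abs(rec.segment.offset_idx - truth.offset_idx) <= 1


class TestLateralDeviation:
    def test_sign_convention_left_negative(self):
        pos = np.array([[0.0, 0, 0], [-3.0, 5.0, 50.0], [0.0, 0, 100.0]])
        seg = MovementSegment(onset_idx=0, offset_idx=2, kick_idx=None, fs=FS)
        left, right, il, ir = lateral_deviation(
            pos, seg, start=np.zeros(3), target=np.array([0.0, 0.0, 100.0])
        )
        assert left == pytest.approx(-3.0)
        assert right == 0.0
        assert il == 1

    def test_path_on_line_gives_zero_both_sides(self):
        pos = np.column_stack([np.zeros(10), np.zeros(10), np.linspace(0, 100, 10)])
        seg = MovementSegment(onset_idx=0, offset_idx=9, kick_idx=None, fs=FS)
        left, right, *_ = lateral_deviation(pos, seg, np.zeros(3), np.array([0, 0, 100.0]))
        assert left == 0.0 and right == 0.0

    def test_degenerate_line_rejected(self):
        pos = np.zeros((5, 3))
        seg = MovementSegment(onset_idx=0, offset_idx=4, kick_idx=None, fs=FS)
        with pytest.raises(DataError, match="degenerate"):
            lateral_deviation(pos, seg, np.zeros(3), np.array([0.0, 10.0, 0.0]))


class TestExtractParameters:
    def test_known_vertical_maximum(self):
        shape = TrialShape(mh=74.0, dev=0.0, mt_nominal=0.9, mv=250.0)
        traj, _ = simulate_trial(shape, marker_noise_mm=0.0)
        rec = extract_parameters(traj, options=KinematicsOptions(target_mm=(0, 0, 500)))
        assert rec.MH == pytest.approx(74.0, abs=0.05)

    def test_symmetric_profile_tmv_near_half(self):
        shape = TrialShape(mh=56.0, dev=0.0, mt_nominal=1.2, mv=300.0)
        traj, _ = simulate_trial(shape, marker_noise_mm=0.0)
        rec = extract_parameters(traj, options=KinematicsOptions(target_mm=(0, 0, 500)))
        assert rec.TMV == pytest.approx(0.5, abs=0.02)

    def test_translation_invariance(self):
        shape = TrialShape(mh=62.0, dev=-4.0, mt_nominal=0.9, mv=250.0)
        traj, _ = simulate_trial(shape, marker_noise_mm=0.2, rng=np.random.default_rng(3))
        rec0 = extract_parameters(traj, options=KinematicsOptions(target_mm=(0, 0, 500)))
        shift = np.array([13.0, 20.0, -8.0])
        traj2 = type(traj)(
            participant_id=traj.participant_id, trial_id=traj.trial_id, group=traj.group,
            stimulus=traj.stimulus, fs=traj.fs, t=traj.t,
            index_xyz=traj.index_xyz + shift, ball_xyz=traj.ball_xyz + shift,
        )
        rec1 = extract_parameters(
            traj2, options=KinematicsOptions(target_mm=tuple(np.array([0, 0, 500.0]) + shift))
        )
        assert rec1.MH - rec0.MH == pytest.approx(shift[1], abs=1e-6)
        for name in ("MDevLeft", "MDevRight", "MV", "MDec", "MT", "TMV", "TMDec"):
            assert getattr(rec1, name) == pytest.approx(getattr(rec0, name), abs=1e-6)

    def test_segment_invariants_on_noisy_trials(self):
        rng = np.random.default_rng(11)
        for k in range(10):
            shape = TrialShape(
                mh=float(rng.uniform(58, 80)), dev=float(rng.uniform(-9, 3)),
                mt_nominal=float(rng.uniform(0.65, 1.2)), mv=float(rng.uniform(120, 350)),
            )
            traj, _ = simulate_trial(shape, marker_noise_mm=0.2, rng=rng,
                                     trial_id=f"T{k}")
            rec = extract_parameters(traj, options=KinematicsOptions(target_mm=(0, 0, 500)))
            seg = rec.segment
            assert seg.onset_idx < seg.offset_idx
            assert rec.MDevLeft <= 0.0 <= rec.MDevRight
            assert rec.MV > 0 and rec.MT > 0
            for t in ("TMV", "TMDec", "TMDevRight", "TMDevLeft"):
                assert 0.0 <= getattr(rec, t) <= 1.0
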