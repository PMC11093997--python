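"""Kinematics: TS/AHV definitions, event detection, main sequence, NR fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from marmonav.config import MovementConfig
from marmonav.kinematics import (KinematicSeries, PoseSeries, angular_distance,
                                 angular_head_velocity, compute_kinematics,
                                 detect_movements, fit_naka_rushton,
                                 led_pair_to_pose, main_sequence,
                                 movement_concurrency, naka_rushton,
                                 translation_speed)


def _pose_from_quats(quats, fs=60.0, pos=None):
    n = len(quats)
    pos = np.zeros((n, 3)) if pos is None else pos
    return PoseSeries(t=np.arange(n) / fs, position=pos, quaternion=quats)


def _rand_unit_quats(rng, n):
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


class TestTranslationSpeed:
    def test_stationary_pose_is_zero(self):
        pose = _pose_from_quats(np.tile([1.0, 0, 0, 0], (120, 1)))
        ts = translation_speed(pose, lowpass_hz=None)
        assert np.allclose(ts, 0.0)

    def test_three_four_five_step(self):
        # one 3-4-0 cm step over 1 s must give 5 cm/s without filtering
        pos = np.array([[0, 0, 0], [3, 4, 0.0]])
        pose = PoseSeries(t=np.array([0.0, 1.0]), position=pos,
                          quaternion=np.tile([1.0, 0, 0, 0], (2, 1)))
        assert translation_speed(pose, lowpass_hz=None)[0] == pytest.approx(5.0)

    def test_matches_finite_difference_oracle_on_smooth_input(self):
        # pre-smoothed trace: the 4 Hz filter is near-transparent, so the
        # result matches a plain finite-difference oracle
        rng = np.random.default_rng(0)
        t = np.arange(600) / 60.0
        pos = np.column_stack([np.cumsum(rng.standard_normal(600)) for _ in range(3)])
        from scipy.ndimage import gaussian_filter1d
        pos = gaussian_filter1d(pos, 10.0, axis=0)
        pose = PoseSeries(t=t, position=pos,
                          quaternion=np.tile([1.0, 0, 0, 0], (600, 1)))
        ts = translation_speed(pose, lowpass_hz=4.0)
        oracle = np.linalg.norm(np.diff(pos, axis=0), axis=1) * 60.0
        sl = slice(30, -30)  # away from filter edges
        assert np.allclose(ts[sl], oracle[sl], rtol=0.05, atol=0.05)

    def test_non_uniform_time_axis_rejected(self):
        pose = PoseSeries(t=np.array([0.0, 0.1, 0.35]), position=np.zeros((3, 3)),
                          quaternion=np.tile([1.0, 0, 0, 0], (3, 1)))
        with pytest.raises(ValueError, match="resample"):
            translation_speed(pose)


class TestAngularDistance:
    def test_identical_quaternions_give_zero(self):
        q = np.array([0.5, 0.5, 0.5, 0.5])
        assert angular_distance(q, q) == pytest.approx(0.0)

    def test_double_cover_sign_symmetry(self):
        rng = np.random.default_rng(1)
        q = _rand_unit_quats(rng, 50)
        assert np.allclose(angular_distance(q, -q), 0.0, atol=1e-6)

    def test_matches_rotation_matrix_trace_oracle(self):
        rng = np.random.default_rng(2)
        q1 = _rand_unit_quats(rng, 200)
        q2 = _rand_unit_quats(rng, 200)
        got = angular_distance(q1, q2)
        r1 = Rotation.from_quat(q1[:, [1, 2, 3, 0]])
        r2 = Rotation.from_quat(q2[:, [1, 2, 3, 0]])
        rel = (r2 * r1.inv()).as_matrix()
        tr = np.clip((np.trace(rel, axis1=1, axis2=2) - 1.0) / 2.0, -1.0, 1.0)
        assert np.allclose(got, np.degrees(np.arccos(tr)), atol=1e-8)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            angular_distance(np.zeros(4), np.array([1.0, 0, 0, 0]))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_invariant_under_global_rotation(self, seed):
        rng = np.random.default_rng(seed)
        q1, q2, g = _rand_unit_quats(rng, 3)
        rg = Rotation.from_quat(g[[1, 2, 3, 0]])
        def lmul(q):
            r = rg * Rotation.from_quat(q[[1, 2, 3, 0]])
            out = r.as_quat()
            return np.array([out[3], out[0], out[1], out[2]])
        assert angular_distance(q1, q2) == pytest.approx(
            float(angular_distance(lmul(q1), lmul(q2))), abs=1e-6)


class TestAngularHeadVelocity:
    def test_constant_rotation_rate_recovered(self):
        fs = 60.0
        angles = np.radians(90.0) * np.arange(120) / fs
        quats = np.column_stack([np.cos(angles / 2), np.zeros((120, 2)),
                                 np.sin(angles / 2)])
        _, ahv = angular_head_velocity(_pose_from_quats(quats, fs))
        assert np.all(np.abs(ahv - 90.0) < 0.1)

    def test_identity_orientation_gives_zero(self):
        _, ahv = angular_head_velocity(_pose_from_quats(np.tile([1.0, 0, 0, 0], (60, 1))))
        assert np.allclose(ahv, 0.0)

    def test_composite_rotation_matches_oracle(self):
        rng = np.random.default_rng(3)
        rots = [Rotation.identity()]
        for _ in range(119):
            step = Rotation.from_euler("zy", rng.uniform(-2, 2, 2), degrees=True)
            rots.append(step * rots[-1])
        q = np.array([[r.as_quat()[3], *r.as_quat()[:3]] for r in rots])
        _, ahv = angular_head_velocity(_pose_from_quats(q))
        oracle = np.array([(rots[i + 1] * rots[i].inv()).magnitude()
                           for i in range(119)])
        assert np.allclose(ahv, np.degrees(oracle) * 60.0, atol=1e-6)


def _pulse_kin(peaks, width=5, n=600, fs=60.0, base=0.0, kind="ahv"):
    v = np.full(n, base)
    for center, height in peaks:
        i = np.arange(n)
        v += height * np.exp(-0.5 * ((i - center) / width) ** 2)
    t = np.arange(n) / fs
    zeros = np.zeros(n)
    ts = v if kind == "ts" else zeros
    ahv = v if kind == "ahv" else zeros
    return KinematicSeries(t=t, ts=ts, ahv=ahv, ang_dist=ahv / fs, dt=1.0 / fs,
                           valid=np.ones(n, bool))


class TestDetectMovements:
    def test_single_suprathreshold_pulse_detected(self):
        kin = _pulse_kin([(300, 300.0)], width=10)
        head, body, art = detect_movements(kin)
        assert len(head) == 1 and not art
        assert head[0].amplitude > 10.0
        assert head[0].t_on < head[0].t_peak <= head[0].t_off

    def test_subthreshold_pulse_ignored(self):
        kin = _pulse_kin([(300, 150.0)], width=10)
        head, _, art = detect_movements(kin)
        assert head == [] and art == []

    def test_artifactual_velocity_excluded(self):
        kin = _pulse_kin([(300, 2500.0)], width=10)
        head, _, art = detect_movements(kin)
        assert head == [] and len(art) == 1 and art[0].artifact

    def test_raising_threshold_never_adds_events(self):
        rng = np.random.default_rng(4)
        peaks = [(c, h) for c, h in zip(range(100, 1900, 120),
                                        rng.uniform(100.0, 900.0, 15))]
        kin = _pulse_kin(peaks, width=6, n=2000)
        counts = []
        for thr in (150.0, 200.0, 300.0, 450.0):
            head, _, _ = detect_movements(
                kin, MovementConfig(head_velocity_deg_s=thr))
            counts.append(len(head))
        assert counts == sorted(counts, reverse=True)

    def test_detection_is_idempotent(self):
        kin = _pulse_kin([(150, 400.0), (400, 800.0)], width=8)
        a = detect_movements(kin)
        b = detect_movements(kin)
        assert [e.t_peak for e in a[0]] == [e.t_peak for e in b[0]]


class TestConcurrency:
    def test_all_peaks_outside_body_events(self):
        from marmonav.kinematics import MovementEvent
        head = [MovementEvent("head", t, t + 0.05, t + 0.1, 300, 20)
                for t in (1.0, 5.0, 9.0)]
        body = [MovementEvent("body", 20.0, 21.0, 22.0, 30, 60)]
        out = movement_concurrency(head, body, rng=0)
        assert out["frac_during_stops"] == 1.0

    def test_peak_at_t_off_counts_as_stop(self):
        from marmonav.kinematics import MovementEvent
        head = [MovementEvent("head", 1.9, 2.0, 2.1, 300, 20)]
        body = [MovementEvent("body", 1.0, 1.5, 2.0, 30, 60)]
        out = movement_concurrency(head, body, rng=0)
        assert out["frac_during_translation"] == 0.0

    def test_empty_head_list_rejected(self):
        with pytest.raises(ValueError, match="no head events"):
            movement_concurrency([], [], rng=0)


class TestMainSequenceAndNakaRushton:
    def test_single_amplitude_bin_zero_ci(self):
        from marmonav.kinematics import MovementEvent
        events = [MovementEvent("head", 0, 0, 0, 400.0, 25.0)] * 5
        ms = main_sequence(events, np.array([20.0, 30.0]))
        assert ms.mean_velocity[0] == pytest.approx(400.0)
        assert ms.ci_lo[0] == ms.ci_hi[0] == pytest.approx(400.0)

    def test_noiseless_events_lie_on_generating_curve(self):
        from marmonav.kinematics import MovementEvent
        amps = np.linspace(12, 80, 200)
        vels = naka_rushton(amps, 795.0, 2.0, 20.0, 50.0)
        events = [MovementEvent("head", 0, 0, 0, v, a) for a, v in zip(amps, vels)]
        edges = np.linspace(10, 90, 9)
        ms = main_sequence(events, edges)
        expected = naka_rushton(ms.bin_centers, 795.0, 2.0, 20.0, 50.0)
        # bin means of a convex-ish monotone curve stay within the bin spread
        assert np.all(np.abs(ms.mean_velocity - expected) < 30.0)
        assert np.all(np.diff(ms.mean_velocity) > 0)

    def test_parameter_recovery_noiseless(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(2, 90, 300)
        r = naka_rushton(x, 795.0, 2.0, 20.0, 50.0)
        fit = fit_naka_rushton(x, r, seed=0)
        p = fit.params
        assert p.r_max == pytest.approx(795.0, rel=1e-3)
        assert p.n == pytest.approx(2.0, rel=1e-3)
        assert p.k == pytest.approx(20.0, rel=1e-3)
        assert p.b == pytest.approx(50.0, rel=1e-3)

    def test_half_saturation_identity(self):
        # R(K) = R_max/2 + b by construction
        assert naka_rushton(20.0, 795.0, 2.0, 20.0, 50.0) == pytest.approx(
            795.0 / 2.0 + 50.0)

    def test_zero_amplitude_limit_is_offset(self):
        assert naka_rushton(0.0, 795.0, 2.0, 20.0, 50.0) == pytest.approx(50.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_naka_rushton(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))


class TestLedPair:
    def test_cardinal_yaw_conventions(self):
        front = np.array([[1.0, 0.0], [0.0, 1.0]])
        back = np.zeros((2, 2))
        pose = led_pair_to_pose(front, back, fs=60.0)
        fwd = pose.forward_axis()
        assert np.allclose(fwd[0], [1, 0, 0], atol=1e-9)   # east
        assert np.allclose(fwd[1], [0, 1, 0], atol=1e-9)   # north

    def test_rotating_pair_recovers_angular_velocity(self):
        fs = 60.0
        ang = np.radians(50.0) * np.arange(120) / fs
        front = np.column_stack([np.cos(ang), np.sin(ang)])
        pose = led_pair_to_pose(front, -front, fs)
        _, ahv = angular_head_velocity(pose)
        assert np.allclose(ahv, 50.0, atol=0.05)

    def test_coincident_leds_become_missing(self):
        front = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        back = np.array([[0.0, 0.0], [0.5, 0.5], [0.0, 0.0]])
        pose = led_pair_to_pose(front, back, fs=60.0)
        assert pose.valid.tolist() == [True, False, True]


class TestPoseValidation:
    def test_bad_quaternion_norm_rejected(self):
        q = np.tile([0.5, 0, 0, 0], (10, 1))
        with pytest.raises(ValueError, match="invalid quaternion"):
            PoseSeries(t=np.arange(10) / 60, position=np.zeros((10, 3)),
                       quaternion=q)

    def test_mild_norm_deviation_renormalized(self):
        q = np.tile([1.002, 0, 0, 0], (10, 1))
        pose = PoseSeries(t=np.arange(10) / 60, position=np.zeros((10, 3)),
                          quaternion=q)
        assert np.allclose(np.linalg.norm(pose.quaternion, axis=1), 1.0)

    def test_non_monotone_clock_rejected(self):
        with pytest.raises(ValueError, match="clock error"):
            PoseSeries(t=np.array([0.0, 0.2, 0.1]), position=np.zeros((3, 3)),
                       quaternion=np.tile([1.0, 0, 0, 0], (3, 1)))
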