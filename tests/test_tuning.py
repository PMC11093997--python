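"""View projection, rate maps, spatial information, and speed scores."""

import numpy as np
import pytest

from marmonav.config import TuningConfig
from marmonav.kinematics import PoseSeries
from marmonav.maze import MazeModel
from marmonav.tuning import (build_rate_map, classify_speed_cell,
                             project_view, sic_significance,
                             spatial_information, speed_score)


def _pose_at(position, yaw_deg=0.0, pitch_deg=0.0, n=2):
    from scipy.spatial.transform import Rotation
    r = Rotation.from_euler("zy", [np.radians(yaw_deg), -np.radians(pitch_deg)])
    q = r.as_quat()
    quat = np.tile([q[3], q[0], q[1], q[2]], (n, 1))
    return PoseSeries(t=np.arange(n) / 60.0,
                      position=np.tile(position, (n, 1)), quaternion=quat)


class TestProjectView:
    def test_center_facing_east_hits_east_wall(self):
        maze = MazeModel.default()
        pose = _pose_at([50.0, 25.0, 60.0], yaw_deg=0.0)
        vs = project_view(pose, maze)
        assert np.all(vs.face == 1)
        assert np.allclose(vs.point[0], [100.0, 25.0, 60.0], atol=1e-9)

    def test_facing_straight_up_hits_ceiling_above(self):
        maze = MazeModel.default()
        pose = _pose_at([30.0, 20.0, 50.0], pitch_deg=90.0)
        vs = project_view(pose, maze)
        assert np.all(vs.face == 5)
        assert np.allclose(vs.point[0, :2], [30.0, 20.0], atol=1e-6)

    def test_random_rays_satisfy_face_plane_and_bounds(self):
        maze = MazeModel.default()
        rng = np.random.default_rng(0)
        n = 10_000
        pos = rng.uniform([1, 1, 1], np.array(maze.extent) - 1, (n, 3))
        q = rng.standard_normal((n, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        pose = PoseSeries(t=np.arange(n) / 60.0, position=pos, quaternion=q)
        vs = project_view(pose, maze)
        assert vs.valid.all()
        ext = np.array(maze.extent)
        planes = {0: (0, 0.0), 1: (0, ext[0]), 2: (1, 0.0), 3: (1, ext[1]),
                  4: (2, 0.0), 5: (2, ext[2])}
        for f, (axis, value) in planes.items():
            sel = vs.face == f
            if sel.any():
                assert np.abs(vs.point[sel, axis] - value).max() < 1e-9
        assert np.all(vs.point >= -1e-9) and np.all(vs.point <= ext + 1e-9)


def _alternating_bins(n_frames, n_bins, run=30):
    """bin id series cycling through bins in contiguous dwells."""
    reps = np.repeat(np.arange(n_frames // run) % n_bins, run)
    return reps[:n_frames].astype(np.int64)


class TestRateMap:
    def test_uniform_occupancy_uniform_rate(self):
        dt = 1 / 60.0
        n = 6000
        bins = _alternating_bins(n, 4)
        t = np.arange(n) * dt
        # one spike per frame -> rate identically 60 Hz
        spikes = t.copy()
        rmap = build_rate_map(spikes, bins, t, dt, 4)
        assert rmap.included.all()
        assert np.allclose(rmap.rate, 60.0)
        assert spatial_information(rmap) == pytest.approx(0.0, abs=1e-12)
        assert rmap.p_occ.sum() == pytest.approx(1.0)

    def test_undersampled_bin_excluded(self):
        dt = 1 / 60.0
        n = 600
        bins = np.zeros(n, dtype=np.int64)
        # bin 1: three visits (not "more than 3") -> excluded even though
        # its total occupancy (250 ms) clears the 200 ms floor; bin 0 gets
        # four visits and stays
        bins[100:105] = 1
        bins[300:305] = 1
        bins[500:505] = 1
        t = np.arange(n) * dt
        rmap = build_rate_map(np.array([]), bins, t, dt, 2)
        assert bool(rmap.included[0]) and not bool(rmap.included[1])

    def test_two_bin_one_bit_case(self):
        # equal occupancy, all spikes in one bin: I = 1 bit/spike
        dt = 1 / 60.0
        n = 6000
        bins = _alternating_bins(n, 2)
        t = np.arange(n) * dt
        spikes = t[bins == 0]
        rmap = build_rate_map(spikes, bins, t, dt, 2)
        assert spatial_information(rmap) == pytest.approx(1.0, abs=1e-9)

    def test_sic_equals_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        dt = 1 / 60.0
        n = 84 * 120
        bins = _alternating_bins(n, 84)
        t = np.arange(n) * dt
        spikes = np.sort(rng.uniform(0, n * dt, 2000))
        rmap = build_rate_map(spikes, bins, t, dt, 84)
        got = spatial_information(rmap)
        # independent term-by-term summation from the map's own fields
        lam_bar = sum(float(rmap.p_occ[i]) * float(rmap.rate[i])
                      for i in range(84) if rmap.included[i])
        oracle = 0.0
        for i in range(84):
            if rmap.included[i] and rmap.rate[i] > 0:
                r = float(rmap.rate[i]) / lam_bar
                oracle += float(rmap.p_occ[i]) * r * np.log2(r)
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_sic_invariant_to_bin_relabeling(self):
        rng = np.random.default_rng(2)
        dt = 1 / 60.0
        n = 6000
        bins = _alternating_bins(n, 6)
        t = np.arange(n) * dt
        spikes = np.sort(rng.uniform(0, n * dt, 500))
        perm = rng.permutation(6)
        a = spatial_information(build_rate_map(spikes, bins, t, dt, 6))
        b = spatial_information(build_rate_map(spikes, perm[bins], t, dt, 6))
        assert a == pytest.approx(b, abs=1e-12)


class TestSicSignificance:
    def test_tuned_unit_detected_with_field(self, behavior_300s, predictors_300s):
        params, pose, _ = behavior_300s
        pred = predictors_300s
        maze = params.maze
        bins = maze.place_bin_of(np.column_stack(
            [pred["x"], pred["y"], pred["z"]]))
        # spikes emitted only in the most-occupied place bin (10x background)
        occ = np.bincount(bins, minlength=maze.n_place_bins)
        target = int(np.argmax(occ))
        rng = np.random.default_rng(3)
        in_field = bins == target
        p = np.where(in_field, 0.5, 0.05)
        frames = rng.uniform(size=bins.size) < p
        spikes = pred["t"][frames]
        cfg = TuningConfig(n_perm=500)
        res = sic_significance("u", spikes, bins, pred["t"], pred["dt"],
                               maze.n_place_bins, pose.duration,
                               cfg=cfg, rng=rng)
        assert res.is_selective
        assert res.significant_bins[target]

    def test_untuned_unit_not_selective(self, behavior_300s, predictors_300s):
        params, pose, _ = behavior_300s
        pred = predictors_300s
        maze = params.maze
        bins = maze.place_bin_of(np.column_stack(
            [pred["x"], pred["y"], pred["z"]]))
        rng = np.random.default_rng(4)
        spikes = np.sort(rng.uniform(0, pose.duration, 1500))
        cfg = TuningConfig(n_perm=500)
        res = sic_significance("u", spikes, bins, pred["t"], pred["dt"],
                               maze.n_place_bins, pose.duration,
                               cfg=cfg, rng=rng)
        # a single null unit is selective with probability ~0.05
        assert res.sic < np.percentile(res.null_sics, 99.9)

    def test_low_permutation_count_refused(self):
        with pytest.raises(ValueError, match="n_perm"):
            sic_significance("u", np.array([1.0]), np.zeros(10, np.int64),
                             np.arange(10) / 60, 1 / 60, 1, 10.0,
                             cfg=TuningConfig(n_perm=50), rng=0)


class TestSpeedScore:
    def _series(self, n=20_000, dt=1 / 60.0):
        t = np.arange(n) * dt
        rng = np.random.default_rng(5)
        from scipy.ndimage import gaussian_filter1d
        g = gaussian_filter1d(rng.standard_normal(n), 50)
        speed = np.abs(g) / g.std() * 40.0  # cm/s scale
        return t, speed, dt, rng

    def test_rate_proportional_to_speed_gives_unit_correlation(self):
        t, speed, dt, rng = self._series()
        # spike counts made proportional to speed give r ~ 1 after identical
        # smoothing of both series
        spikes = np.repeat(t, np.round(speed * dt * 2.0).astype(int))
        r, _ = speed_score(spikes, t, speed, dt, rng=rng)
        assert r > 0.95

    def test_anticorrelated_rate_not_classified(self):
        t, speed, dt, rng = self._series()
        inv = speed.max() - speed
        spikes = np.repeat(t, np.round(inv * dt * 2.0).astype(int))
        ahv = np.abs(rng.standard_normal(speed.size)) * 100.0
        res = classify_speed_cell("u", spikes, t, speed, ahv, dt,
                                  cfg=TuningConfig(speed_n_shift=200), rng=rng)
        assert res.score_ts < -0.9 and not res.passes_ts

    def test_independent_series_near_zero(self):
        t, speed, dt, rng = self._series(n=100_000)
        spikes = np.sort(rng.uniform(0, t[-1], 5000))
        r, null = speed_score(spikes, t, speed, dt, rng=rng)
        assert abs(r) < 0.05
        assert abs(np.mean(null)) < 0.05

    def test_affine_rescaling_invariance(self):
        t, speed, dt, rng = self._series()
        spikes = np.sort(rng.uniform(0, t[-1], 2000))
        r1, _ = speed_score(spikes, t, speed, dt, rng=1)
        r2, _ = speed_score(spikes, t, 3.0 * speed + 7.0, dt, rng=1)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_constant_series_rejected(self):
        t = np.arange(1000) / 60.0
        with pytest.raises(ValueError, match="constant"):
            speed_score(np.array([1.0, 2.0]), t, np.ones(1000), 1 / 60.0, rng=0)
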