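"""Head and body kinematics from rigid-body tracking.

Translation speed (TS) is the Euclidean step length of the low-pass filtered
3D position divided by the sampling interval.  Angular head velocity (AHV)
is the geodesic angle between consecutive unit rotation quaternions divided
by the sampling interval.  Significant head movements are epochs of AHV
above threshold with sufficient integrated amplitude; body translations are
the analogue on TS.  The amplitude/peak-velocity relation of ballistic head
movements (the main sequence) is summarized with a Naka-Rushton fit

    R(X) = R_max * X^n / (X^n + K^n) + b

whose asymptote R_max characterizes how fast a species re-aims its head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats
from scipy.spatial.transform import Rotation

from .config import MovementConfig

__all__ = [
    "PoseSeries", "KinematicSeries", "MovementEvent", "MainSequence",
    "NakaRushtonParams", "NakaRushtonFit", "translation_speed",
    "angular_distance", "angular_head_velocity", "compute_kinematics",
    "detect_movements", "movement_concurrency", "main_sequence",
    "naka_rushton", "fit_naka_rushton", "led_pair_to_pose",
]


@dataclass
class PoseSeries:
    """Synchronized 3D position (cm) and head orientation at a fixed rate.

    Quaternions are stored scalar-first ``(w, x, y, z)`` with unit norm; the
    head's forward (visual) axis is the body-frame +x axis.  ``valid`` marks
    samples where tracking was available; invalid samples propagate as
    missing through every kinematic quantity.
    """

    t: np.ndarray
    position: np.ndarray  # (n, 3) cm
    quaternion: np.ndarray  # (n, 4) scalar-first, unit norm
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("clock error: time axis must be strictly increasing")
        norms = np.linalg.norm(self.quaternion[self.valid], axis=1)
        if norms.size:
            dev = np.abs(norms - 1.0)
            if np.any(dev > 1e-2):
                raise ValueError("invalid quaternion: norm deviates by more than 1e-2")
            if np.any(dev > 1e-3):
                self.quaternion = self.quaternion.copy()
                self.quaternion[self.valid] /= norms[:, None]

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + 1.0 / self.fs)

    def forward_axis(self) -> np.ndarray:
        """Unit forward (gaze) vectors, body-frame +x rotated to world."""
        rot = Rotation.from_quat(self.quaternion[:, [1, 2, 3, 0]])
        return rot.apply(np.array([1.0, 0.0, 0.0]))


@dataclass
class KinematicSeries:
    """Per-interval TS (cm/s) and AHV (deg/s), timestamped at midpoints."""

    t: np.ndarray
    ts: np.ndarray
    ahv: np.ndarray
    ang_dist: np.ndarray
    dt: float
    valid: np.ndarray


@dataclass
class MovementEvent:
    kind: str  # "head" | "body"
    t_on: float
    t_peak: float
    t_off: float
    peak_velocity: float
    amplitude: float
    during_translation: bool | None = None
    artifact: bool = False


@dataclass
class NakaRushtonParams:
    r_max: float
    n: float
    k: float
    b: float

    def __call__(self, x):
        return naka_rushton(np.asarray(x, dtype=float), self.r_max, self.n, self.k, self.b)


@dataclass
class NakaRushtonFit:
    params: NakaRushtonParams
    residual_norm: float
    ci: dict = field(default_factory=dict)  # 95% CI per coefficient
    converged: bool = True


@dataclass
class MainSequence:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mean_velocity: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    count: np.ndarray


def _require_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0:
        raise ValueError("need at least 2 samples")
    if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0] + 1e-9:
        raise ValueError("resample required: non-uniform time axis")
    return float(dt[0])


def _valid_runs(valid: np.ndarray):
    """Yield (start, stop) half-open index ranges of contiguous valid samples."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    yield from zip(starts, stops)


def translation_speed(pose: PoseSeries, lowpass_hz: float | None = 4.0) -> np.ndarray:
    """TS per inter-sample interval (cm/s); position optionally low-passed.

    Filtering is zero-phase (4th-order Butterworth) and applied per
    contiguous valid run so occlusion gaps never leak through the filter.
    Pass ``lowpass_hz=None`` to difference the raw positions.
    """
    dt = _require_uniform(pose.t)
    pos = pose.position.astype(float).copy()
    if lowpass_hz is not None:
        fs = 1.0 / dt
        sos = signal.butter(4, lowpass_hz / (fs / 2.0), output="sos")
        padlen = 3 * 8  # conservative settle for an order-8 zero-phase response
        for a, b in _valid_runs(pose.valid):
            if b - a > padlen:
                pos[a:b] = signal.sosfiltfilt(sos, pos[a:b], axis=0)
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    ts = step / dt
    ts[~(pose.valid[:-1] & pose.valid[1:])] = np.nan
    return ts


def angular_distance(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Geodesic rotation angle between unit quaternions, in degrees.

    theta = 2 * arccos(|<q1, q2>|); the absolute value makes the result
    insensitive to the q/-q double cover.
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    for q in (q1, q2):
        n = np.linalg.norm(q, axis=-1)
        if np.any(n < 1e-12):
            raise ValueError("zero-norm quaternion")
    dot = np.abs(np.sum(q1 * q2, axis=-1))
    dot = dot / (np.linalg.norm(q1, axis=-1) * np.linalg.norm(q2, axis=-1))
    return np.degrees(2.0 * np.arccos(np.clip(dot, -1.0, 1.0)))


def angular_head_velocity(pose: PoseSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval (angular distance deg, AHV deg/s)."""
    dt = _require_uniform(pose.t)
    theta = angular_distance(pose.quaternion[:-1], pose.quaternion[1:])
    bad = ~(pose.valid[:-1] & pose.valid[1:])
    theta = theta.astype(float)
    theta[bad] = np.nan
    return theta, theta / dt


def compute_kinematics(pose: PoseSeries, cfg: MovementConfig | None = None) -> KinematicSeries:
    cfg = cfg or MovementConfig()
    dt = _require_uniform(pose.t)
    ts = translation_speed(pose, cfg.position_lowpass_hz)
    ang, ahv = angular_head_velocity(pose)
    tm = 0.5 * (pose.t[:-1] + pose.t[1:])
    valid = np.isfinite(ts) & np.isfinite(ahv)
    return KinematicSeries(t=tm, ts=ts, ahv=ahv, ang_dist=ang, dt=dt, valid=valid)


def _extend_to_minimum(v: np.ndarray, i: int, half: float, step: int) -> int:
    """Walk from i in direction step to the nearest local minimum below half."""
    n = v.size
    while True:
        j = i + step
        if j < 0 or j >= n or not np.isfinite(v[j]):
            return i
        if v[i] < half and v[j] >= v[i]:
            return i
        i = j


def _detect_one(v: np.ndarray, t: np.ndarray, dt: float, thr: float, amp_floor: float,
                artifact_ceiling: float, edge_fraction: float, kind: str):
    """Threshold-crossing event detection on one velocity series.

    Maximal supra-threshold runs are extended on both sides to the nearest
    local minimum below ``edge_fraction * thr``; amplitude is the integrated
    path (velocity * dt summed over the epoch).
    """
    above = np.isfinite(v) & (v > thr)
    half = edge_fraction * thr
    events, artifacts = [], []
    if not above.any():
        return events, artifacts
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(v.size)
    spans = []
    for a, b in zip(starts, stops):
        a2 = _extend_to_minimum(v, a, half, -1)
        b2 = _extend_to_minimum(v, b - 1, half, +1) + 1
        # adjacent events may share their boundary minimum; merge only when
        # the extended spans genuinely interleave
        if spans and a2 < spans[-1][1] - 1:
            spans[-1] = (spans[-1][0], max(spans[-1][1], b2))
        else:
            spans.append((a2, b2))
    for a, b in spans:
        seg = v[a:b]
        amp = float(np.nansum(seg) * dt)
        if amp < amp_floor:
            continue
        ipk = a + int(np.nanargmax(seg))  # earliest sample on plateaus
        ev = MovementEvent(
            kind=kind, t_on=float(t[a]), t_peak=float(t[ipk]),
            t_off=float(t[b - 1]), peak_velocity=float(v[ipk]), amplitude=amp,
        )
        if ev.peak_velocity > artifact_ceiling:
            ev.artifact = True
            artifacts.append(ev)
        else:
            events.append(ev)
    return events, artifacts


def detect_movements(kin: KinematicSeries, cfg: MovementConfig | None = None):
    """Detect significant head and body movements.

    Returns ``(head_events, body_events, artifacts)``.  Head events require
    AHV > 200 deg/s with integrated amplitude > 10 deg; body events require
    TS > 16 cm/s with path length >= 30 cm.  Peaks above 2000 deg/s (head)
    or 300 cm/s (body) are artifactual and excluded.
    """
    cfg = cfg or MovementConfig()
    head, head_art = _detect_one(
        kin.ahv, kin.t, kin.dt, cfg.head_velocity_deg_s, cfg.head_amplitude_deg,
        cfg.head_artifact_deg_s, cfg.edge_fraction, "head")
    body, body_art = _detect_one(
        kin.ts, kin.t, kin.dt, cfg.body_speed_cm_s, cfg.body_amplitude_cm,
        cfg.body_artifact_cm_s, cfg.edge_fraction, "body")
    for ev in head:
        ev.during_translation = any(b.t_on <= ev.t_peak < b.t_off for b in body)
    return head, body, head_art + body_art


def movement_concurrency(head_events, body_events, n_boot: int = 1000,
                         ci: float = 0.99, rng=None) -> dict:
    """Fraction of head movements whose peak falls inside a body translation.

    A head event counts as during-translation when its peak time lies in a
    body event's half-open [t_on, t_off).  CIs are bootstrap percentile
    intervals over head events.
    """
    if len(head_events) == 0:
        raise ValueError("undefined fractions: no head events")
    rng = np.random.default_rng(rng)
    spans = np.array([[b.t_on, b.t_off] for b in body_events]).reshape(-1, 2)
    peaks = np.array([h.t_peak for h in head_events])
    during = np.zeros(peaks.size, dtype=bool)
    for lo, hi in spans:
        during |= (peaks >= lo) & (peaks < hi)
    frac_trans = during.mean()
    boots = during[rng.integers(0, during.size, size=(n_boot, during.size))].mean(axis=1)
    q = (1.0 - ci) / 2.0
    lo_t, hi_t = np.quantile(boots, [q, 1.0 - q])
    return {
        "frac_during_translation": float(frac_trans),
        "frac_during_stops": float(1.0 - frac_trans),
        "ci_during_stops": (float(1.0 - hi_t), float(1.0 - lo_t)),
        "ci_during_translation": (float(lo_t), float(hi_t)),
        "n_head_events": int(peaks.size),
    }


def main_sequence(events, bin_edges, min_count: int = 1) -> MainSequence:
    """Amplitude-binned mean peak velocity with 95% t-based CIs."""
    bin_edges = np.asarray(bin_edges, dtype=float)
    amp = np.array([e.amplitude for e in events])
    vel = np.array([e.peak_velocity for e in events])
    nb = bin_edges.size - 1
    mean = np.full(nb, np.nan)
    lo = np.full(nb, np.nan)
    hi = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    which = np.digitize(amp, bin_edges) - 1
    for i in range(nb):
        sel = vel[which == i]
        count[i] = sel.size
        if sel.size < min_count:
            continue
        mean[i] = sel.mean()
        if sel.size > 1 and sel.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, sel.size - 1) * stats.sem(sel)
        else:
            half = 0.0
        lo[i], hi[i] = mean[i] - half, mean[i] + half
    if not np.isfinite(mean).any():
        raise ValueError("all bins empty")
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return MainSequence(bin_edges, centers, mean, lo, hi, count)


def naka_rushton(x, r_max, n, k, b):
    """R(X) = R_max * X^n / (X^n + K^n) + b."""
    x = np.asarray(x, dtype=float)
    xn = np.power(x, n)
    return r_max * xn / (xn + np.power(k, n)) + b


def fit_naka_rushton(x, r, n_starts: int = 10, seed: int = 0) -> NakaRushtonFit:
    """Multi-start non-linear least squares for the Naka-Rushton curve.

    Starts from (max(r), 2, median(x), min(r)) plus jittered restarts; the
    fit with the lowest residual norm wins.  R_max, n and K are bounded
    positive.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    p0 = np.array([max(r.max() - r.min(), 1e-6), 2.0,
                   max(np.median(x), 1e-6), r.min()])
    bounds = ([1e-9, 1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    best = None
    for i in range(n_starts):
        start = p0 if i == 0 else np.maximum(p0 * rng.lognormal(0.0, 0.3, 4), 1e-9)
        if i > 0:
            start[3] = p0[3] + rng.normal(0.0, 0.1 * (abs(p0[3]) + 1.0))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    naka_rushton, x, r, p0=start, bounds=bounds, maxfev=20000)
        except RuntimeError:
            continue
        res = float(np.linalg.norm(r - naka_rushton(x, *popt)))
        if best is None or res < best[0]:
            best = (res, popt, pcov)
    if best is None:
        raise RuntimeError("fit failed: no start converged")
    res, popt, pcov = best
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    names = ("r_max", "n", "k", "b")
    ci = {nm: (float(p - 1.96 * s), float(p + 1.96 * s))
          for nm, p, s in zip(names, popt, se)}
    return NakaRushtonFit(
        params=NakaRushtonParams(*map(float, popt)),
        residual_norm=res, ci=ci, converged=True)


def led_pair_to_pose(front_xy, back_xy, fs: float) -> PoseSeries:
    """Build a planar PoseSeries from two-LED head tracking.

    Position is the LED midpoint (z = 0); heading yaw is the front-minus-back
    direction (east = +x = 0 deg, counter-clockwise positive); pitch and roll
    are undefined and the quaternion encodes yaw only.  Coincident LEDs give
    missing samples.
    """
    front = np.asarray(front_xy, dtype=float)
    back = np.asarray(back_xy, dtype=float)
    if front.shape != back.shape or front.ndim != 2 or front.shape[1] != 2:
        raise ValueError("front/back must be matching (n, 2) arrays")
    n = front.shape[0]
    d = front - back
    norm = np.linalg.norm(d, axis=1)
    valid = norm > 1e-9
    yaw = np.arctan2(d[:, 1], d[:, 0])
    quat = np.zeros((n, 4))
    quat[:, 0] = np.cos(yaw / 2.0)
    quat[:, 3] = np.sin(yaw / 2.0)
    quat[~valid] = [1.0, 0.0, 0.0, 0.0]
    pos = np.column_stack([(front + back) / 2.0, np.zeros(n)])
    t = np.arange(n) / fs
    return PoseSeries(t=t, position=pos, quaternion=quat, valid=valid)
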