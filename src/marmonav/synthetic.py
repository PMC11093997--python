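"""Synthetic foraging sessions with known ground truth.

The generator emulates the statistical structure the analyses assume for a
freely moving primate foraging in a three-floor enclosure:

* behavior alternates locomotion bouts (straight paths between reward
  ports at 16-60 cm/s, head aligned to heading) with stationary epochs
  during which rapid ballistic head rotations occur, their peak velocity
  following a Naka-Rushton main sequence with multiplicative noise;
* spike trains are inhomogeneous Poisson with log-link tuning to place,
  view and head direction (pyramidal-type units) or to AHV and TS
  (interneuron-type units), with optional doublet injection so burst-based
  cell typing is recoverable;
* the LFP is 1/f background noise plus a theta oscillation whose phase is
  (partially) reset to a fixed value at each head-movement peak, with a
  transient amplitude bump decaying over ``reset_decay_s``.

Every random draw flows from one seed, so a fixed seed reproduces the
session bit for bit.  The ground-truth manifest records the injected
tuning, events and reset phase for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .kinematics import MovementEvent, NakaRushtonParams, PoseSeries
from .maze import MazeModel
from .events import LfpSeries
from .unit_metrics import SpikeTrain, UnitProfile

__all__ = [
    "MARMOSET_MAIN_SEQUENCE", "RAT_MAIN_SEQUENCE", "BehaviorParams",
    "LfpParams", "UnitSpec", "GeneratorParams", "SessionGroundTruth",
    "gen_main_sequence_events", "gen_behavior", "gen_spikes", "gen_lfp",
    "gen_session", "default_unit_specs", "frame_predictors", "unit_log_rate",
]

# main-sequence presets: asymptotes from head-movement kinematics of each
# species; exponent, half-saturation and offset complete a saturating curve
# rising over the 10-90 deg amplitude range
MARMOSET_MAIN_SEQUENCE = NakaRushtonParams(r_max=795.0, n=2.0, k=20.0, b=50.0)
RAT_MAIN_SEQUENCE = NakaRushtonParams(r_max=430.9, n=2.0, k=25.0, b=30.0)


@dataclass
class BehaviorParams:
    stop_duration_s: tuple[float, float] = (1.0, 6.0)      # uniform range
    locomotion_speed_cm_s: tuple[float, float] = (16.0, 60.0)
    head_event_rate_during_stops_hz: float = 1.2
    fraction_head_moves_during_stops: float = 0.8
    amplitude_log_mean: float = np.log(25.0)               # deg, log-normal
    amplitude_log_sd: float = 0.5
    amplitude_range_deg: tuple[float, float] = (10.0, 90.0)
    main_sequence: NakaRushtonParams = field(
        default_factory=lambda: MARMOSET_MAIN_SEQUENCE)
    velocity_noise: float = 0.05                           # multiplicative SD
    align_duration_s: float = 1.2   # fixed-duration sub-threshold turns
    min_event_gap_s: float = 0.4


@dataclass
class LfpParams:
    fs_hz: float = 1000.0
    aperiodic_exponent: float = 1.5
    noise_amp: float = 1.0
    theta_freq_hz: float = 7.0
    theta_amp: float = 0.5
    phase_jitter: float = 3.0       # rad/sqrt(s) phase diffusion
    reset_gain: float = 1.0         # 0 = no reset, 1 = full reset
    reset_phase: float = 0.0        # target phase at event peak
    reset_amp: float = 1.0          # transient amplitude bump
    reset_decay_s: float = 0.25


@dataclass
class UnitSpec:
    unit_id: str
    cell_type: str                  # "pyramidal" | "interneuron"
    beta0: float                    # log baseline rate (log Hz)
    terms: dict = field(default_factory=dict)
    doublet_p: float = 0.0

    @property
    def label(self) -> str:
        k = len(self.terms)
        return "none" if k == 0 else ("single" if k == 1 else "mixed")


@dataclass
class GeneratorParams:
    duration_s: float = 2400.0
    fs_hz: float = 60.0
    maze: MazeModel = field(default_factory=MazeModel.default)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    lfp: LfpParams = field(default_factory=LfpParams)
    n_pyr: int = 204
    n_int: int = 127
    unit_specs: list | None = None
    seed: int = 0


@dataclass
class SessionGroundTruth:
    unit_specs: list
    events: list
    reset_phase: float
    params: GeneratorParams

    @property
    def head_events(self):
        return [e for e in self.events if e.kind == "head"]

    @property
    def body_events(self):
        return [e for e in self.events if e.kind == "body"]

    def manifest(self) -> dict:
        return {
            "n_units": len(self.unit_specs),
            "duration_s": self.params.duration_s,
            "n_head_events": len(self.head_events),
            "n_body_events": len(self.body_events),
            "reset_phase": self.reset_phase,
            "units": [{
                "unit_id": s.unit_id, "cell_type": s.cell_type,
                "beta0": s.beta0, "label": s.label,
                "terms": sorted(s.terms.keys()),
                "doublet_p": s.doublet_p,
            } for s in self.unit_specs],
        }


def _truncated_lognormal(rng, log_mean, log_sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(log_mean, log_sd, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def gen_main_sequence_events(n: int, curve: NakaRushtonParams,
                             noise: float = 0.05, rng=None,
                             amplitude_log_mean: float = np.log(25.0),
                             amplitude_log_sd: float = 0.5,
                             amplitude_range: tuple = (10.0, 90.0)):
    """Draw (amplitudes deg, peak velocities deg/s) from a main sequence.

    Amplitudes are log-normal truncated to the given range; velocities
    follow the curve with multiplicative Gaussian noise.
    """
    rng = np.random.default_rng(rng)
    amp = _truncated_lognormal(rng, amplitude_log_mean, amplitude_log_sd,
                               *amplitude_range, size=n)
    vel = curve(amp) * (1.0 + noise * rng.standard_normal(n))
    return amp, np.clip(vel, 1.0, None)


def _heading_quat(direction: np.ndarray) -> Rotation:
    """Rotation taking body +x to the given direction with zero roll."""
    d = direction / np.linalg.norm(direction)
    yaw = np.arctan2(d[1], d[0])
    pitch = -np.arcsin(np.clip(d[2], -1.0, 1.0))
    return Rotation.from_euler("zy", [yaw, pitch])


def _event_step_angles(amp: float, vel: float, dt: float) -> np.ndarray:
    """Per-sample rotation increments of a raised-cosine velocity profile.

    The profile v(t) = (V/2)(1 - cos(2 pi t / T)) with T = 2A/V integrates
    exactly to A; increments are the exact integral over each sample.
    """
    T = 2.0 * amp / vel
    n = max(2, int(np.ceil(T / dt)))
    edges = np.linspace(0.0, T, n + 1)
    # integral of v: (V/2) (t - T/(2 pi) sin(2 pi t / T))
    F = 0.5 * vel * (edges - T / (2 * np.pi) * np.sin(2 * np.pi * edges / T))
    return np.diff(F)


def _build_schedule(params: GeneratorParams, rng):
    """Alternating stop / align / locomotion epochs covering the session.

    Alignment turns have a fixed duration so the schedule is independent of
    head state; their rotation speed never exceeds 180 deg over the window,
    i.e. stays below the head-movement detection threshold.
    """
    bp = params.behavior
    maze = params.maze
    fs = params.fs_hz
    n = int(round(params.duration_s * fs))
    ports = maze.reward_ports
    if ports.shape[0] < 2 or np.ptp(ports, axis=0).max() < 30.0:
        raise ValueError("degenerate maze: no usable path between ports")
    align_n = max(1, int(round(bp.align_duration_s * fs)))
    epochs = []
    i = 0
    port_idx = int(rng.integers(ports.shape[0]))
    cur_pos = ports[port_idx].astype(float)
    while i < n:
        stop_n = min(int(round(rng.uniform(*bp.stop_duration_s) * fs)), n - i)
        epochs.append({"kind": "stop", "i0": i, "i1": i + stop_n,
                       "pos": cur_pos.copy()})
        i += stop_n
        if i >= n:
            break
        choices = [j for j in range(ports.shape[0]) if j != port_idx]
        port_idx = int(rng.choice(choices))
        target = ports[port_idx].astype(float)
        direction = target - cur_pos
        dist = float(np.linalg.norm(direction))
        k = min(align_n, n - i)
        epochs.append({"kind": "align", "i0": i, "i1": i + k,
                       "pos": cur_pos.copy(), "direction": direction})
        i += k
        if i >= n:
            break
        speed = float(rng.uniform(*bp.locomotion_speed_cm_s))
        loco_n = min(max(2, int(round(dist / speed * fs))), n - i)
        path = cur_pos + (np.arange(1, loco_n + 1)[:, None] / loco_n) * direction
        epochs.append({"kind": "loco", "i0": i, "i1": i + loco_n,
                       "path": path, "speed": speed, "dist": dist})
        i += loco_n
        cur_pos = target
    return epochs, n


def _place_head_events(epochs, params: GeneratorParams, rng):
    """Draw head-event (start sample, amplitude, velocity, kind) tuples.

    Events during stops follow a Poisson process at the configured rate;
    the number during locomotion is then set so the overall fraction during
    stops matches ``fraction_head_moves_during_stops`` by construction.
    """
    bp = params.behavior
    fs = params.fs_hz
    dt = 1.0 / fs

    gap = int(round(bp.min_event_gap_s * fs))

    def draw_in(spans, count=None, rate=None):
        lens = np.array([b - a for a, b in spans], dtype=float)
        total = lens.sum() * dt
        if total <= 0:
            return []
        bounds = np.concatenate(([0.0], np.cumsum(lens)))
        retry = count is not None
        if count is None:
            count = rng.poisson(rate * total)

        placed: list[tuple[int, float, float]] = []
        occupied: list[tuple[int, int]] = []

        def try_place(off, amp, vel):
            e = min(int(np.searchsorted(bounds, off, side="right")) - 1,
                    len(spans) - 1)
            start = spans[e][0] + int(off - bounds[e])
            n_steps = _event_step_angles(amp, vel, dt).size
            if start + n_steps >= spans[e][1]:
                return False
            for a, b in occupied:
                if start < b + gap and a < start + n_steps + gap:
                    return False
            placed.append((start, float(amp), float(vel)))
            occupied.append((start, start + n_steps))
            return True

        amps, vels = gen_main_sequence_events(
            count, bp.main_sequence, bp.velocity_noise, rng,
            bp.amplitude_log_mean, bp.amplitude_log_sd, bp.amplitude_range_deg)
        vels = np.clip(vels, None, 1900.0)
        offs = rng.uniform(0, lens.sum(), size=count)
        for off, amp, vel in zip(offs, amps, vels):
            try_place(off, amp, vel)
        if retry:
            tries = 0
            while len(placed) < count and tries < 50 * count + 100:
                amp, vel = gen_main_sequence_events(
                    1, bp.main_sequence, bp.velocity_noise, rng,
                    bp.amplitude_log_mean, bp.amplitude_log_sd,
                    bp.amplitude_range_deg)
                try_place(rng.uniform(0, lens.sum()),
                          float(amp[0]), min(float(vel[0]), 1900.0))
                tries += 1
        placed.sort()
        return placed

    stop_spans = [(e["i0"], e["i1"]) for e in epochs if e["kind"] == "stop"]
    loco_spans = [(e["i0"], e["i1"]) for e in epochs if e["kind"] == "loco"]
    stop_events = draw_in(stop_spans, rate=bp.head_event_rate_during_stops_hz)
    f = bp.fraction_head_moves_during_stops
    n_loco = 0 if f >= 1.0 else int(round(len(stop_events) * (1.0 - f) / max(f, 1e-9)))
    loco_events = draw_in(loco_spans, count=max(n_loco, 0))
    ev = ([(s, a, v, False) for s, a, v in stop_events] +
          [(s, a, v, True) for s, a, v in loco_events])
    ev.sort()
    return ev


def gen_behavior(params: GeneratorParams, rng=None):
    """Simulate the pose trajectory; returns (PoseSeries, true event list)."""
    rng = np.random.default_rng(rng if rng is not None else params.seed)
    bp = params.behavior
    fs = params.fs_hz
    dt = 1.0 / fs
    epochs, n = _build_schedule(params, rng)
    head_plan = _place_head_events(epochs, params, rng)

    pos = np.empty((n, 3))
    quats = np.empty((n, 4))  # scalar-first
    events: list[MovementEvent] = []
    cur_rot = Rotation.identity()
    plan_idx = 0

    def set_quat(i, rot):
        q = rot.as_quat()
        quats[i] = (q[3], q[0], q[1], q[2])

    for ep in epochs:
        i0, i1 = ep["i0"], ep["i1"]
        if ep["kind"] == "stop":
            pos[i0:i1] = ep["pos"]
        elif ep["kind"] == "align":
            pos[i0:i1] = ep["pos"]
            target_rot = _heading_quat(ep["direction"])
            rotvec = (target_rot * cur_rot.inv()).as_rotvec()
            k = i1 - i0
            base = cur_rot
            for j, frac in enumerate(np.linspace(1.0 / k, 1.0, k)):
                cur_rot = Rotation.from_rotvec(frac * rotvec) * base
                set_quat(i0 + j, cur_rot)
            continue
        else:
            pos[i0:i1] = ep["path"]

        # head events inside this epoch, on top of the held orientation
        i = i0
        while plan_idx < len(head_plan) and head_plan[plan_idx][0] < i1:
            start, amp, vel, translating = head_plan[plan_idx]
            if start < i0:
                plan_idx += 1
                continue
            for j in range(i, start):
                set_quat(j, cur_rot)
            steps = _event_step_angles(amp, vel, dt)
            k = min(steps.size, i1 - start)
            axis = np.array([0.35 * rng.standard_normal(),
                             0.35 * rng.standard_normal(),
                             rng.choice([-1.0, 1.0])])
            axis /= np.linalg.norm(axis)
            for j in range(k):
                cur_rot = Rotation.from_rotvec(
                    np.radians(steps[j]) * axis) * cur_rot
                set_quat(start + j, cur_rot)
            ipk = int(np.argmax(steps))
            events.append(MovementEvent(
                kind="head", t_on=start * dt, t_peak=(start + ipk) * dt,
                t_off=(start + k - 1) * dt,
                peak_velocity=float(steps.max() / dt),
                amplitude=float(np.sum(steps[:k])),
                during_translation=translating))
            i = start + k
            plan_idx += 1
        for j in range(i, i1):
            set_quat(j, cur_rot)
        if ep["kind"] == "loco":
            events.append(MovementEvent(
                kind="body", t_on=i0 * dt, t_peak=0.5 * (i0 + i1) * dt,
                t_off=i1 * dt, peak_velocity=ep["speed"],
                amplitude=ep["dist"]))

    t = np.arange(n) / fs
    pose = PoseSeries(t=t, position=pos, quaternion=quats)
    events.sort(key=lambda e: e.t_on)
    return pose, events


def default_unit_specs(n_pyr: int, n_int: int, maze: MazeModel, rng=None,
                       tuned_fraction: float = 0.8) -> list[UnitSpec]:
    """Random tuning specifications at physiologic scales.

    Pyramidal units: low baseline rate (~1-3 Hz), tuned to a random
    non-empty subset of {place, view, head_direction} (untuned with
    probability 1 - tuned_fraction), doublets injected so the burst index
    separates cell types.  Interneurons: high baseline (~10-25 Hz), tuned to
    a subset of {ahv, ts}.
    """
    rng = np.random.default_rng(rng)
    ext = np.asarray(maze.extent)
    specs = []
    for u in range(n_pyr):
        terms = {}
        if rng.uniform() < tuned_fraction:
            options = ["place", "view", "head_direction"]
            k = int(rng.integers(1, 4))
            for name in map(str, rng.choice(options, size=k, replace=False)):
                if name == "place":
                    terms["place"] = {
                        "center": (rng.uniform(0, 1, 3) * ext).tolist(),
                        "width_cm": float(rng.uniform(12.0, 20.0)),
                        "gain": float(rng.uniform(1.5, 2.5))}
                elif name == "view":
                    face = int(rng.integers(0, 4))  # walls only
                    nu, nv, ul, vl = maze.face_grid(face)
                    terms["view"] = {
                        "face": face,
                        "center": [float(rng.uniform(0.2, 0.8) * ul),
                                   float(rng.uniform(0.2, 0.8) * vl)],
                        "width_cm": float(rng.uniform(15.0, 25.0)),
                        "gain": float(rng.uniform(1.5, 2.5))}
                else:
                    terms["head_direction"] = {
                        "mu_deg": float(rng.uniform(-180.0, 180.0)),
                        "kappa": float(rng.uniform(2.0, 4.0)),
                        "gain": float(rng.uniform(1.0, 2.0))}
        specs.append(UnitSpec(
            unit_id=f"pyr{u:03d}", cell_type="pyramidal",
            beta0=float(np.log(rng.uniform(0.8, 3.0))), terms=terms,
            doublet_p=float(rng.uniform(0.3, 0.5))))
    for u in range(n_int):
        terms = {}
        if rng.uniform() < tuned_fraction:
            for name in map(str, rng.choice(["ahv", "ts"],
                                            size=int(rng.integers(1, 3)),
                                            replace=False)):
                cap = 400.0 if name == "ahv" else 60.0
                terms[name] = {"gain": float(rng.uniform(0.8, 1.5)),
                               "cap": cap}
        specs.append(UnitSpec(
            unit_id=f"int{u:03d}", cell_type="interneuron",
            beta0=float(np.log(rng.uniform(8.0, 20.0))), terms=terms))
    return specs


def frame_predictors(pose: PoseSeries, maze: MazeModel) -> dict:
    """Frame-aligned behavioral series (one frame per tracking interval).

    Yaw/pitch come from the head's forward axis (yaw east = 0, CCW positive;
    pitch up positive); roll is the residual rotation about the forward
    axis.  Shared by the generator and the encoding designs.
    """
    from .kinematics import compute_kinematics
    from .tuning import project_view

    kin = compute_kinematics(pose)
    view = project_view(pose, maze)
    fwd = pose.forward_axis()
    yaw = np.degrees(np.arctan2(fwd[:, 1], fwd[:, 0]))
    pitch = np.degrees(np.arcsin(np.clip(fwd[:, 2], -1.0, 1.0)))
    # roll: angle of the body +y axis against the horizontal reference
    rot = Rotation.from_quat(pose.quaternion[:, [1, 2, 3, 0]])
    left = rot.apply(np.array([0.0, 1.0, 0.0]))
    horiz = np.column_stack([-np.sin(np.radians(yaw)),
                             np.cos(np.radians(yaw)),
                             np.zeros(yaw.size)])
    up = np.cross(fwd, horiz * -1.0)
    roll = np.degrees(np.arctan2((left * up).sum(axis=1) * -1.0,
                                 (left * horiz).sum(axis=1)))
    m = kin.t.size
    return {
        "t": kin.t, "dt": kin.dt,
        "x": 0.5 * (pose.position[:-1, 0] + pose.position[1:, 0]),
        "y": 0.5 * (pose.position[:-1, 1] + pose.position[1:, 1]),
        "z": 0.5 * (pose.position[:-1, 2] + pose.position[1:, 2]),
        "yaw": yaw[:m], "pitch": pitch[:m], "roll": roll[:m],
        "view_face": view.face[:m], "view_u": view.u[:m],
        "view_v": view.v[:m], "ahv": kin.ahv, "ts": kin.ts,
    }


def unit_log_rate(spec: UnitSpec, predictors: dict) -> np.ndarray:
    """Log firing rate (log Hz) over frames from a unit's tuning terms."""
    n = predictors["x"].size
    log_rate = np.full(n, spec.beta0)
    for name, p in spec.terms.items():
        if name == "place":
            c = np.asarray(p["center"])
            d2 = ((np.column_stack([predictors["x"], predictors["y"],
                                    predictors["z"]]) - c) ** 2).sum(axis=1)
            log_rate += p["gain"] * np.exp(-d2 / (2.0 * p["width_cm"] ** 2))
        elif name == "view":
            on_face = predictors["view_face"] == p["face"]
            d2 = ((predictors["view_u"] - p["center"][0]) ** 2 +
                  (predictors["view_v"] - p["center"][1]) ** 2)
            bump = np.where(on_face, np.exp(-d2 / (2.0 * p["width_cm"] ** 2)), 0.0)
            log_rate += p["gain"] * np.nan_to_num(bump)
        elif name == "head_direction":
            ang = np.radians(predictors["yaw"] - p["mu_deg"])
            log_rate += p["gain"] * (np.exp(p["kappa"] * (np.cos(ang) - 1.0)))
        elif name in ("ahv", "ts"):
            x = np.clip(predictors[name], 0.0, p["cap"]) / p["cap"]
            log_rate += p["gain"] * np.nan_to_num(x)
        else:
            raise ValueError(f"unknown term {name!r}")
    return log_rate


def gen_spikes(pose: PoseSeries, specs: list[UnitSpec],
               params: GeneratorParams, rng=None,
               predictors: dict | None = None):
    """Inhomogeneous-Poisson spike trains from log-link tuning.

    Returns ``(list of UnitProfile, predictors)`` where predictors are the
    frame-aligned behavioral series used to drive the rates (reusable for
    encoding designs).
    """
    from .kinematics import compute_kinematics
    from .tuning import project_view

    rng = np.random.default_rng(rng if rng is not None else params.seed + 1)
    if predictors is None:
        predictors = frame_predictors(pose, params.maze)
    dt = predictors["dt"]
    t = predictors["t"]
    profiles = []
    for spec in specs:
        lr = unit_log_rate(spec, predictors)
        rate = np.exp(np.nan_to_num(lr, nan=spec.beta0))
        if np.nanmax(rate) > 500.0:
            raise ValueError(f"tuning too strong for {spec.unit_id}: "
                             f"rate {np.nanmax(rate):.0f} Hz")
        counts = rng.poisson(rate * dt)
        reps = np.repeat(np.arange(t.size), counts)
        times = t[reps] - dt / 2.0 + rng.uniform(0.0, dt, reps.size)
        if spec.doublet_p > 0 and times.size:
            extra = times[rng.uniform(size=times.size) < spec.doublet_p]
            extra = extra + rng.uniform(0.002, 0.015, extra.size)
            times = np.concatenate((times, extra))
        times = np.sort(times)
        times = times[(times >= 0) & (times < pose.duration)]
        profiles.append(UnitProfile(
            train=SpikeTrain(unit_id=spec.unit_id, times=times),
            meta={"cell_type_true": spec.cell_type, "label_true": spec.label}))
    return profiles, predictors


def gen_lfp(event_times: np.ndarray, params: GeneratorParams, rng=None) -> LfpSeries:
    """1/f background plus theta with event-locked phase resetting."""
    lp = params.lfp
    if lp.fs_hz < 40.0:
        raise ValueError("fs too low for theta")
    rng = np.random.default_rng(rng if rng is not None else params.seed + 2)
    n = int(round(params.duration_s * lp.fs_hz))
    dt = 1.0 / lp.fs_hz

    # spectrally shaped background: |FFT| ~ f^(-alpha/2)
    white = rng.standard_normal(n)
    F = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, dt)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-lp.aperiodic_exponent / 2.0)
    shape[0] = 0.0
    bg = np.fft.irfft(F * shape, n=n)
    sd = bg.std()
    if sd > 0:
        bg *= lp.noise_amp / sd

    phase = np.empty(n)
    phase[0] = rng.uniform(-np.pi, np.pi)
    dphi = 2.0 * np.pi * lp.theta_freq_hz * dt + \
        lp.phase_jitter * np.sqrt(dt) * rng.standard_normal(n - 1)
    ev_idx = np.round(np.asarray(event_times, dtype=float) * lp.fs_hz).astype(int)
    ev_idx = np.unique(ev_idx[(ev_idx >= 0) & (ev_idx < n)])
    ev_set = set(ev_idx.tolist())
    increments = np.concatenate(([0.0], dphi))
    phase = np.cumsum(increments) + phase[0]
    if lp.reset_gain > 0:
        # apply resets sequentially: a reset shifts all later phase by the
        # same correction, so walk events in order adjusting the tail
        for idx in ev_idx:
            err = np.angle(np.exp(1j * (lp.reset_phase - phase[idx])))
            phase[idx:] += lp.reset_gain * err

    amp = np.full(n, lp.theta_amp)
    if lp.reset_amp > 0 and ev_idx.size:
        tail = int(round(5.0 * lp.reset_decay_s * lp.fs_hz))
        kernel = lp.reset_amp * np.exp(-np.arange(tail) * dt / lp.reset_decay_s)
        spikes = np.zeros(n)
        spikes[ev_idx] = 1.0
        amp = amp + np.convolve(spikes, kernel)[:n]
    samples = bg + amp * np.cos(phase)
    return LfpSeries(fs=lp.fs_hz, samples=samples)


def gen_session(params: GeneratorParams):
    """Compose behavior, spikes and LFP into a full session bundle."""
    from .io_core import SessionBundle

    root = np.random.default_rng(params.seed)
    seeds = root.integers(0, 2 ** 31, size=4)
    pose, events = gen_behavior(params, np.random.default_rng(int(seeds[0])))
    specs = params.unit_specs
    if specs is None:
        specs = default_unit_specs(params.n_pyr, params.n_int, params.maze,
                                   np.random.default_rng(int(seeds[1])))
    profiles, predictors = gen_spikes(pose, specs, params,
                                      np.random.default_rng(int(seeds[2])))
    head_peaks = np.array([e.t_peak for e in events if e.kind == "head"])
    lfp = gen_lfp(head_peaks, params, np.random.default_rng(int(seeds[3])))
    truth = SessionGroundTruth(unit_specs=specs, events=events,
                               reset_phase=params.lfp.reset_phase,
                               params=params)
    bundle = SessionBundle(
        session_id=f"synthetic-{params.seed}",
        tracking=pose, units=profiles, lfp=[lfp], maze=params.maze,
        meta={"species": "synthetic", "tracking_fs_hz": params.fs_hz,
              "lfp_fs_hz": params.lfp.fs_hz, "seed": params.seed,
              "duration_s": params.duration_s})
    return bundle, truth
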