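"""Place and view selectivity: rate maps, spatial information, speed scores.

Spatial information content (SIC, bits/spike) over L occupancy bins is

    I = sum_i P_i * (lambda_i / lambda_bar) * log2(lambda_i / lambda_bar)

with P_i the occupancy probability of bin i, lambda_i its firing rate, and
lambda_bar = sum_i P_i lambda_i the occupancy-weighted mean rate.
Significance is assessed against a null built by circularly shifting the
unit's spike times while the occupancy stays fixed, which preserves the
spike train's autostructure but destroys its relation to behavior.

"View" is the facing location: the intersection of the head's forward ray
with the enclosure's inner faces, binned on the unwrapped walls.  Speed
tuning is the Pearson correlation between the Gaussian-smoothed firing-rate
and speed series, with a fixed threshold (0.3) and a circular-shift shuffle
criterion applied jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import TuningConfig
from .kinematics import PoseSeries
from .maze import MazeModel

__all__ = [
    "ViewSamples", "RateMap", "SelectivityResult", "SpeedScoreResult",
    "project_view", "build_rate_map", "spatial_information",
    "sic_significance", "speed_score", "classify_speed_cell",
    "binned_rate",
]


@dataclass
class ViewSamples:
    t: np.ndarray
    face: np.ndarray      # 0..5, -1 where undefined
    u: np.ndarray
    v: np.ndarray
    point: np.ndarray     # (n, 3) intersection in world coordinates
    valid: np.ndarray


@dataclass
class RateMap:
    domain: str                # "place3d" | "view2d"
    n_bins: int
    occupancy_s: np.ndarray    # per bin, s
    visits: np.ndarray         # independent (contiguous-dwell) visits per bin
    spike_count: np.ndarray
    rate: np.ndarray           # Hz, NaN on excluded bins
    included: np.ndarray       # bool mask of bins entering P_i / L
    p_occ: np.ndarray          # P_i over included bins, zeros elsewhere

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate lambda_bar."""
        return float(np.nansum(self.p_occ[self.included] * self.rate[self.included]))


@dataclass
class SelectivityResult:
    unit_id: str
    domain: str
    sic: float
    null_sics: np.ndarray
    percentile: float
    threshold: float
    is_selective: bool
    significant_bins: np.ndarray
    rate_map: RateMap | None = None


@dataclass
class SpeedScoreResult:
    unit_id: str
    score_ts: float
    score_ahv: float
    null_ts: np.ndarray
    null_ahv: np.ndarray
    passes_ts: bool
    passes_ahv: bool
    label: str  # none | TS | AHV | mixed


def project_view(pose: PoseSeries, maze: MazeModel) -> ViewSamples:
    """Facing location: first intersection of the forward ray with a face.

    Rays originate at the head position (clamped just inside the extent if
    tracking strays outside) along the rotated +x axis.  The returned (u, v)
    are in-face coordinates on the unwrapped wall.
    """
    ext = np.asarray(maze.extent, dtype=float)
    p = np.clip(pose.position, 1e-6, ext - 1e-6)
    d = pose.forward_axis()
    n = p.shape[0]

    # distance to each of the six planes along d; non-positive -> unreachable
    with np.errstate(divide="ignore", invalid="ignore"):
        t_hit = np.empty((n, 6))
        t_hit[:, 0] = (0.0 - p[:, 0]) / d[:, 0]
        t_hit[:, 1] = (ext[0] - p[:, 0]) / d[:, 0]
        t_hit[:, 2] = (0.0 - p[:, 1]) / d[:, 1]
        t_hit[:, 3] = (ext[1] - p[:, 1]) / d[:, 1]
        t_hit[:, 4] = (0.0 - p[:, 2]) / d[:, 2]
        t_hit[:, 5] = (ext[2] - p[:, 2]) / d[:, 2]
    t_hit[~np.isfinite(t_hit)] = np.inf
    t_hit[t_hit <= 0] = np.inf

    face = np.argmin(t_hit, axis=1)
    tmin = t_hit[np.arange(n), face]
    ok = np.isfinite(tmin) & pose.valid
    point = p + tmin[:, None] * d
    face = np.where(ok, face, -1)

    u = np.full(n, np.nan)
    v = np.full(n, np.nan)
    # in-face axes: walls use (horizontal-along-wall, z); floor/ceiling (x, y)
    for f, (iu, iv) in enumerate([(1, 2), (1, 2), (0, 2), (0, 2), (0, 1), (0, 1)]):
        sel = face == f
        u[sel] = point[sel, iu]
        v[sel] = point[sel, iv]
    return ViewSamples(t=pose.t, face=face, u=u, v=v, point=point, valid=ok)


def _count_visits(bin_ids: np.ndarray, n_bins: int) -> np.ndarray:
    """Independent visits: maximal contiguous dwells per bin."""
    visits = np.zeros(n_bins, dtype=np.int64)
    if bin_ids.size == 0:
        return visits
    starts = np.flatnonzero(np.diff(bin_ids) != 0) + 1
    entries = np.concatenate(([bin_ids[0]], bin_ids[starts]))
    entries = entries[entries >= 0]
    np.add.at(visits, entries, 1)
    return visits


def binned_rate(spike_times: np.ndarray, t: np.ndarray, dt: float) -> np.ndarray:
    """Spike counts per frame / dt, frames centered on sample times t."""
    edges = np.concatenate((t - dt / 2.0, [t[-1] + dt / 2.0]))
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts / dt


def _spike_bins(spike_times: np.ndarray, t: np.ndarray, dt: float,
                bin_ids: np.ndarray) -> np.ndarray:
    """Occupancy-bin id of each spike (by its enclosing tracking frame)."""
    edges = np.concatenate((t - dt / 2.0, [t[-1] + dt / 2.0]))
    fr = np.searchsorted(edges, spike_times, side="right") - 1
    fr = np.clip(fr, 0, t.size - 1)
    return bin_ids[fr]


def build_rate_map(spike_times: np.ndarray, bin_ids: np.ndarray, t: np.ndarray,
                   dt: float, n_bins: int, domain: str = "place3d",
                   cfg: TuningConfig | None = None) -> RateMap:
    """Occupancy and firing-rate map over pre-computed per-sample bin ids.

    ``bin_ids`` may contain -1 for samples with no defined bin (occlusions,
    undefined view); those samples contribute nothing.  Bins sampled on
    three or fewer independent visits, or for less than 200 ms total, are
    excluded from L and from the occupancy normalization.
    """
    cfg = cfg or TuningConfig()
    bin_ids = np.asarray(bin_ids)
    occ = np.bincount(bin_ids[bin_ids >= 0], minlength=n_bins) * dt
    visits = _count_visits(bin_ids, n_bins)
    sb = _spike_bins(np.asarray(spike_times, dtype=float), t, dt, bin_ids)
    spk = np.bincount(sb[sb >= 0], minlength=n_bins).astype(float)
    included = (visits > cfg.min_visits) & (occ >= cfg.min_occupancy_s)
    rate = np.full(n_bins, np.nan)
    rate[included] = spk[included] / occ[included]
    p_occ = np.zeros(n_bins)
    tot = occ[included].sum()
    if tot > 0:
        p_occ[included] = occ[included] / tot
    return RateMap(domain=domain, n_bins=n_bins, occupancy_s=occ, visits=visits,
                   spike_count=spk, rate=rate, included=included, p_occ=p_occ)


def spatial_information(rate_map: RateMap) -> float:
    """SIC in bits/spike; 0*log(0) terms are zero by convention."""
    lam_bar = rate_map.mean_rate
    if not np.isfinite(lam_bar) or lam_bar <= 0:
        raise ValueError("undefined SIC: mean rate is zero")
    p = rate_map.p_occ[rate_map.included]
    lam = rate_map.rate[rate_map.included]
    ratio = lam / lam_bar
    terms = np.zeros_like(ratio)
    nz = ratio > 0
    terms[nz] = p[nz] * ratio[nz] * np.log2(ratio[nz])
    return float(terms.sum())


def _null_spike_bin_counts(spike_times, t, dt, bin_ids, n_bins, duration,
                           n_perm, min_shift, rng):
    """Spike counts per occupancy bin for circularly shifted trains.

    Returns (n_perm, n_bins).  Shifts are uniform on
    [min_shift, duration - min_shift) and wrap modulo the session; spike
    count is conserved exactly.
    """
    shifts = rng.uniform(min_shift, duration - min_shift, size=n_perm)
    edges = np.concatenate((t - dt / 2.0, [t[-1] + dt / 2.0]))
    shifted = (spike_times[None, :] + shifts[:, None]) % duration
    fr = np.searchsorted(edges, shifted.ravel(), side="right") - 1
    fr = np.clip(fr, 0, t.size - 1)
    b = bin_ids[fr].reshape(n_perm, -1)
    rows = np.repeat(np.arange(n_perm), spike_times.size)
    flat = rows * (n_bins + 1) + np.where(b.ravel() >= 0, b.ravel(), n_bins)
    counts = np.bincount(flat, minlength=n_perm * (n_bins + 1))
    return counts.reshape(n_perm, n_bins + 1)[:, :n_bins].astype(float)


def sic_significance(unit_id: str, spike_times: np.ndarray, bin_ids: np.ndarray,
                     t: np.ndarray, dt: float, n_bins: int, duration: float,
                     domain: str = "place3d", cfg: TuningConfig | None = None,
                     rng=None) -> SelectivityResult:
    """SIC permutation test with circular spike-time shifts.

    The cell is selective when its SIC exceeds the configured percentile
    (default 95th) of the shuffle null.  Per-bin fields use the same null's
    per-bin rates at the Bonferroni-corrected percentile 100*(1 - 0.05/L).
    """
    cfg = cfg or TuningConfig()
    if cfg.n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable percentiles")
    rng = np.random.default_rng(rng)
    spike_times = np.asarray(spike_times, dtype=float)
    rmap = build_rate_map(spike_times, bin_ids, t, dt, n_bins, domain, cfg)
    sic = spatial_information(rmap)

    occ = rmap.occupancy_s
    inc = rmap.included
    null_counts = _null_spike_bin_counts(
        spike_times, t, dt, np.asarray(bin_ids), n_bins, duration,
        cfg.n_perm, cfg.min_shift_s, rng)
    null_rate = np.full((cfg.n_perm, n_bins), np.nan)
    null_rate[:, inc] = null_counts[:, inc] / occ[inc]
    p = rmap.p_occ[inc]
    lam = null_rate[:, inc]
    lam_bar = (p[None, :] * lam).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = lam / lam_bar[:, None]
        terms = np.where(ratio > 0, p[None, :] * ratio * np.log2(
            np.where(ratio > 0, ratio, 1.0)), 0.0)
    null_sics = terms.sum(axis=1)
    null_sics[~np.isfinite(null_sics)] = 0.0

    threshold = float(np.percentile(null_sics, cfg.cell_percentile))
    is_sel = sic > threshold
    L = int(inc.sum())
    bin_pct = 100.0 * (1.0 - cfg.bin_alpha / max(L, 1))
    sig_bins = np.zeros(n_bins, dtype=bool)
    if L:
        bin_thr = np.nanpercentile(null_rate[:, inc], bin_pct, axis=0)
        sig_bins[inc] = rmap.rate[inc] > bin_thr
    return SelectivityResult(
        unit_id=unit_id, domain=domain, sic=sic, null_sics=null_sics,
        percentile=cfg.cell_percentile, threshold=threshold,
        is_selective=bool(is_sel), significant_bins=sig_bins, rate_map=rmap)


def speed_score(spike_times: np.ndarray, t: np.ndarray, speed: np.ndarray,
                dt: float, cfg: TuningConfig | None = None, rng=None):
    """Pearson correlation between smoothed rate and speed, plus shuffle null.

    Both series are smoothed with a 1-D Gaussian (250 ms SD default) at the
    tracking rate.  The null circularly shifts the smoothed rate series 1000
    times.  Returns ``(r, null_scores)``.
    """
    cfg = cfg or TuningConfig()
    rng = np.random.default_rng(rng)
    ok = np.isfinite(speed)
    rate = binned_rate(np.asarray(spike_times, dtype=float), t, dt)
    sigma = (cfg.speed_smooth_sd_ms / 1000.0) / dt
    rate_s = gaussian_filter1d(rate, sigma, mode="nearest")
    speed_s = speed.copy()
    speed_s[~ok] = np.interp(t[~ok], t[ok], speed[ok]) if ok.any() and (~ok).any() else 0.0
    speed_s = gaussian_filter1d(speed_s, sigma, mode="nearest")
    rate_s = rate_s[ok]
    speed_s = speed_s[ok]
    if rate_s.std() == 0 or speed_s.std() == 0:
        raise ValueError("undefined correlation: constant series")
    r = float(np.corrcoef(rate_s, speed_s)[0, 1])

    n = rate_s.size
    min_shift = max(1, int(round(cfg.min_shift_s / dt)))
    shifts = rng.integers(min_shift, n - min_shift, size=cfg.speed_n_shift)
    # circular shifts of a z-scored series against the fixed speed series
    rz = (rate_s - rate_s.mean()) / rate_s.std()
    sz = (speed_s - speed_s.mean()) / speed_s.std()
    # r(shift) is a circular cross-correlation; evaluate via FFT once
    f = np.fft.rfft(rz)
    g = np.fft.rfft(sz)
    cc = np.fft.irfft(np.conj(f) * g, n=n) / n
    null = cc[shifts]
    return r, null


def classify_speed_cell(unit_id: str, spike_times, t, ts, ahv, dt,
                        cfg: TuningConfig | None = None, rng=None) -> SpeedScoreResult:
    """Dual-criterion speed-cell classification for TS and AHV.

    A unit passes for a given speed signal when its score exceeds 0.3 AND
    the 95th percentile of the 1000-shift null; passing both signals gives
    the label ``mixed``.
    """
    cfg = cfg or TuningConfig()
    rng = np.random.default_rng(rng)
    r_ts, null_ts = speed_score(spike_times, t, ts, dt, cfg, rng)
    r_ahv, null_ahv = speed_score(spike_times, t, ahv, dt, cfg, rng)
    p_ts = r_ts > cfg.speed_threshold and r_ts > np.percentile(null_ts, cfg.speed_percentile)
    p_ahv = r_ahv > cfg.speed_threshold and r_ahv > np.percentile(null_ahv, cfg.speed_percentile)
    label = {(False, False): "none", (True, False): "TS",
             (False, True): "AHV", (True, True): "mixed"}[(p_ts, p_ahv)]
    return SpeedScoreResult(unit_id=unit_id, score_ts=r_ts, score_ahv=r_ahv,
                            null_ts=null_ts, null_ahv=null_ahv,
                            passes_ts=bool(p_ts), passes_ahv=bool(p_ahv),
                            label=label)
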