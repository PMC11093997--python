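"""Pseudo-population place decoding with greedy ensemble construction.

Decoding trials are 200 ms windows centered on head "fixations" (local
minima of AHV within runs below 200 deg/s), labeled by the coarse place bin
(two bins per floor, the four best-sampled of six retained).  Features are
per-unit firing rates in the window.  A linear multi-class SVM (one-vs-one)
is evaluated with five-fold cross-validation, repeated ten times on
balanced class subsamples.  The greedy ensemble seeds with the single best
unit and grows by always adding the unit that most improves accuracy;
random same-size ensembles provide the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import DecodingConfig
from .kinematics import KinematicSeries, NakaRushtonFit, PoseSeries, fit_naka_rushton
from .maze import MazeModel

__all__ = [
    "TrialSet", "EnsembleCurve", "extract_trials", "train_decoder",
    "build_greedy_ensemble", "random_ensembles", "curve_fit_performance",
]


@dataclass
class TrialSet:
    t_center: np.ndarray
    label: np.ndarray          # class index 0..3 after retention
    rates: np.ndarray          # (n_trials, n_units) Hz
    unit_ids: list
    classes: np.ndarray        # original floor-half ids of retained classes
    class_counts: np.ndarray


@dataclass
class EnsembleCurve:
    variant: str
    members: list
    sizes: np.ndarray
    accuracy: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    fit: NakaRushtonFit | None = None


def _fixation_centers(kin: KinematicSeries, cfg: DecodingConfig) -> np.ndarray:
    """Local AHV minima inside sub-threshold runs, spaced >= window_s."""
    ahv = kin.ahv
    ok = np.isfinite(ahv) & (ahv < cfg.low_ahv_deg_s)
    centers = []
    last = -np.inf
    i = 0
    n = ahv.size
    half = cfg.window_s / 2.0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        seg = ahv[i:j]
        order = np.argsort(seg, kind="stable")
        chosen = []
        for k in order:
            tk = kin.t[i + k]
            if all(abs(tk - c) >= cfg.window_s for c in chosen):
                chosen.append(tk)
        centers.extend(chosen)
        i = j
    centers = np.sort(np.array(centers))
    keep = []
    for c in centers:
        if not keep or c - keep[-1] >= cfg.window_s:
            keep.append(c)
    out = np.array(keep)
    return out[(out - half >= kin.t[0]) & (out + half <= kin.t[-1])]


def extract_trials(pose: PoseSeries, kin: KinematicSeries,
                   spike_trains: dict, maze: MazeModel,
                   cfg: DecodingConfig | None = None) -> TrialSet:
    """Build the pseudo-population trial table.

    ``spike_trains`` maps unit id -> spike-time array.  The four retained
    classes are the floor-halves with the highest trial counts; requires at
    least ``min_trials_per_class`` trials in each.
    """
    cfg = cfg or DecodingConfig()
    centers = _fixation_centers(kin, cfg)
    if centers.size == 0:
        raise ValueError("insufficient sampling: no low-AHV trials")
    pos_idx = np.clip(np.searchsorted(pose.t, centers), 0, pose.t.size - 1)
    labels6 = maze.floor_half_of(pose.position[pos_idx])
    counts6 = np.bincount(labels6, minlength=maze.n_floors * 2)
    top4 = np.sort(np.argsort(counts6, kind="stable")[::-1][:cfg.n_classes])
    keep = np.isin(labels6, top4)
    centers = centers[keep]
    labels6 = labels6[keep]
    remap = {c: i for i, c in enumerate(top4)}
    y = np.array([remap[c] for c in labels6])
    counts = np.bincount(y, minlength=cfg.n_classes)
    if np.any(counts < cfg.min_trials_per_class):
        raise ValueError(
            f"insufficient sampling: class counts {counts.tolist()} "
            f"below {cfg.min_trials_per_class}")
    unit_ids = list(spike_trains.keys())
    half = cfg.window_s / 2.0
    rates = np.empty((centers.size, len(unit_ids)))
    for j, uid in enumerate(unit_ids):
        st = np.asarray(spike_trains[uid], dtype=float)
        lo = np.searchsorted(st, centers - half)
        hi = np.searchsorted(st, centers + half)
        rates[:, j] = (hi - lo) / cfg.window_s
    return TrialSet(t_center=centers, label=y, rates=rates, unit_ids=unit_ids,
                    classes=top4, class_counts=counts)


def _balanced_subsample(y: np.ndarray, rng) -> np.ndarray:
    """Indices subsampling every class to the minimum class count."""
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=m, replace=False))
    return np.sort(np.concatenate(idx))


def train_decoder(trials: TrialSet, members, cfg: DecodingConfig | None = None,
                  rng=None) -> tuple[float, tuple[float, float]]:
    """Mean cross-validated accuracy of a linear SVM on the member units.

    Ten balanced-subsample repeats of stratified five-fold CV; features are
    z-scored on training folds only.  Returns (mean accuracy, 95% CI over
    repeats).
    """
    cfg = cfg or DecodingConfig()
    rng = np.random.default_rng(rng)
    cols = [trials.unit_ids.index(m) for m in members]
    X = trials.rates[:, cols]
    y = trials.label
    accs = np.empty(cfg.n_repeats)
    for r in range(cfg.n_repeats):
        sub = _balanced_subsample(y, rng)
        Xs, ys = X[sub], y[sub]
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        fold_acc = []
        for tr, te in skf.split(Xs, ys):
            clf = make_pipeline(
                StandardScaler(),
                SVC(kernel="linear", C=cfg.svm_c, decision_function_shape="ovo"))
            clf.fit(Xs[tr], ys[tr])
            fold_acc.append(clf.score(Xs[te], ys[te]))
        accs[r] = np.mean(fold_acc)
    mean = float(accs.mean())
    half = 1.96 * accs.std(ddof=1) / np.sqrt(cfg.n_repeats) if cfg.n_repeats > 1 else 0.0
    return mean, (mean - half, mean + half)


def build_greedy_ensemble(trials: TrialSet, pool, cfg: DecodingConfig | None = None,
                          rng=None, variant: str = "all_units") -> EnsembleCurve:
    """Grow the best-decoding ensemble one unit at a time.

    Stops at ``max_ensemble`` or when accuracy improves by less than
    ``stop_tol`` over the last ``stop_patience`` sizes.  Ties break toward
    the lower-indexed unit for determinism.
    """
    cfg = cfg or DecodingConfig()
    rng = np.random.default_rng(rng)
    pool = list(pool)
    if not pool:
        raise ValueError("empty pool")
    members: list = []
    sizes, accs, lo, hi = [], [], [], []
    while pool and len(members) < cfg.max_ensemble:
        best = None
        for cand in pool:
            acc, ci = train_decoder(trials, members + [cand], cfg,
                                    np.random.default_rng(int(rng.integers(2 ** 31))))
            if best is None or acc > best[0]:
                best = (acc, ci, cand)
        acc, ci, winner = best
        members.append(winner)
        pool.remove(winner)
        sizes.append(len(members))
        accs.append(acc)
        lo.append(ci[0])
        hi.append(ci[1])
        if (len(accs) > cfg.stop_patience and
                accs[-1] - accs[-1 - cfg.stop_patience] < cfg.stop_tol):
            break
    return EnsembleCurve(variant=variant, members=members,
                         sizes=np.array(sizes), accuracy=np.array(accs),
                         ci_lo=np.array(lo), ci_hi=np.array(hi))


def random_ensembles(trials: TrialSet, pool, size: int,
                     cfg: DecodingConfig | None = None, rng=None) -> dict:
    """Accuracy distribution over random same-size unit combinations."""
    cfg = cfg or DecodingConfig()
    rng = np.random.default_rng(rng)
    pool = list(pool)
    if len(pool) < size:
        raise ValueError("pool smaller than requested ensemble size")
    from math import comb
    n_combos = min(cfg.n_random_combos, comb(len(pool), size))
    seen = set()
    accs = []
    while len(seen) < n_combos:
        combo = tuple(sorted(rng.choice(len(pool), size=size, replace=False)))
        if combo in seen:
            continue
        seen.add(combo)
        acc, _ = train_decoder(trials, [pool[i] for i in combo], cfg,
                               np.random.default_rng(int(rng.integers(2 ** 31))))
        accs.append(acc)
    accs = np.array(accs)
    q = np.quantile(accs, [0.025, 0.975]) if accs.size > 1 else (accs[0], accs[0])
    return {"accuracies": accs, "mean": float(accs.mean()),
            "ci": (float(q[0]), float(q[1])), "n_combos": int(accs.size)}


def curve_fit_performance(curve: EnsembleCurve, seed: int = 0) -> NakaRushtonFit:
    """Naka-Rushton fit to accuracy vs ensemble size; asymptote = r_max + b."""
    if curve.sizes.size < 4:
        raise ValueError("need at least 4 ensemble sizes")
    fit = fit_naka_rushton(curve.sizes.astype(float), curve.accuracy, seed=seed)
    curve.fit = fit
    return fit
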