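"""Mixed-selectivity encoding models with shuffle-gated forward selection.

Each unit's per-frame spike count y is modeled as an additive log-link
Poisson model

    y ~ Poisson(exp(beta_0 + f_1(x_1) + ... + f_r(x_r)))

where the candidate variables are behavioral: putative pyramidal cells are
offered place (x, y, z), view (facing location u, v) and head direction
(yaw, pitch, roll, circular); putative interneurons are offered AHV and TS.
Multi-dimensional variables enter as one additive spline term per dimension
but are selected as a unit.

Model quality is the explained deviance

    ED = 1 - D_fitted / D_null

with D_fitted the Poisson deviance of the fitted means and D_null the
deviance of the constant mean-rate model.  Forward selection accepts a
candidate only when its real ED exceeds the Bonferroni-corrected 95th
percentile of a 100-shuffle null: first-order nulls circularly shift the
spike-count vector; higher-order nulls shift only the candidate predictor,
leaving the response and the already-selected predictors intact.  Among
significant candidates the highest shuffle-normalized ED (real minus mean
null) wins.  The winning model is scored by five-fold contiguous-in-time
cross-validated prediction R^2 with an F-test at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import EncodingConfig
from .glm import (FourierBasis, SplineBasis, fit_penalized_poisson,
                  poisson_deviance)

__all__ = [
    "VARIABLE_FAMILIES", "EncodingDesign", "GamFit", "SelectionTrace",
    "build_design", "fit_poisson_gam", "explained_deviance",
    "forward_select", "evaluate_prediction", "encode_unit",
]

VARIABLE_FAMILIES = {
    "pyramidal": {
        "place": ("x", "y", "z"),
        "view": ("view_u", "view_v"),
        "head_direction": ("yaw", "pitch", "roll"),
    },
    "interneuron": {
        "ahv": ("ahv",),
        "ts": ("ts",),
    },
}

_CIRCULAR = {"yaw", "pitch", "roll"}


@dataclass
class EncodingDesign:
    """Frame-aligned spike counts and behavioral predictors for one unit."""

    y: np.ndarray                 # integer counts per frame
    predictors: dict              # column name -> array over frames
    family: str                   # "pyramidal" | "interneuron"
    frame_s: float
    t: np.ndarray

    def __post_init__(self):
        if self.y.size == 0:
            raise ValueError("empty design")
        for name, col in self.predictors.items():
            if col.shape != self.y.shape:
                raise ValueError(f"predictor {name} misaligned with target")

    @property
    def variables(self) -> dict:
        return VARIABLE_FAMILIES[self.family]


class _BasisCache:
    """Per-variable design-matrix blocks and penalties, built once."""

    def __init__(self, design: EncodingDesign, cfg: EncodingConfig):
        self.blocks: dict[str, np.ndarray] = {}
        self.penalties: dict[str, np.ndarray] = {}
        for var, cols in design.variables.items():
            mats, pens = [], []
            for c in cols:
                x = design.predictors[c]
                if c in _CIRCULAR:
                    basis = FourierBasis(order=cfg.fourier_order, period=360.0)
                else:
                    basis = SplineBasis.from_data(x, n_splines=cfg.n_splines)
                mats.append(basis.design(x))
                pens.append(basis.penalty())
            self.blocks[var] = np.hstack(mats)
            k = sum(p.shape[0] for p in pens)
            P = np.zeros((k, k))
            o = 0
            for p in pens:
                P[o:o + p.shape[0], o:o + p.shape[0]] = p
                o += p.shape[0]
            self.penalties[var] = P

    def assemble(self, variables, alpha: float, shift_rows: dict | None = None):
        """Full (X, S) for an intercept + the given variable blocks.

        ``shift_rows`` maps a variable name to an integer circular row shift
        of its block, implementing a circular shift of that predictor's time
        series (the basis is a pointwise transform, so shifting the series
        shifts the rows).
        """
        shift_rows = shift_rows or {}
        n = next(iter(self.blocks.values())).shape[0]
        parts = [np.ones((n, 1))]
        pens = [np.zeros((1, 1))]
        for var in variables:
            B = self.blocks[var]
            if var in shift_rows:
                B = np.roll(B, shift_rows[var], axis=0)
            parts.append(B)
            pens.append(alpha * self.penalties[var])
        X = np.hstack(parts)
        p = X.shape[1]
        S = np.zeros((p, p))
        o = 0
        for P in pens:
            S[o:o + P.shape[0], o:o + P.shape[0]] = P
            o += P.shape[0]
        return X, S


@dataclass
class GamFit:
    variables: tuple
    beta: np.ndarray
    mu: np.ndarray
    d_fitted: float
    d_null: float
    explained_deviance: float
    converged: bool


@dataclass
class SelectionTrace:
    family: str
    iterations: list = field(default_factory=list)
    selected: list = field(default_factory=list)
    stop_reason: str = ""
    r2_cv: float = np.nan
    f_p: float = np.nan
    encoding: bool = False


def build_design(spike_times: np.ndarray, t: np.ndarray, frame_s: float,
                 predictors: dict, family: str) -> EncodingDesign:
    """Bin spikes into tracking-locked frames and align predictors.

    ``t`` are frame centers (one per tracking interval); frames where any
    required predictor is missing are dropped from both sides.
    """
    needed = [c for cols in VARIABLE_FAMILIES[family].values() for c in cols]
    ok = np.ones(t.size, dtype=bool)
    for c in needed:
        ok &= np.isfinite(predictors[c])
    edges = np.concatenate((t - frame_s / 2.0, [t[-1] + frame_s / 2.0]))
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float), bins=edges)
    return EncodingDesign(
        y=counts[ok].astype(float),
        predictors={c: np.asarray(predictors[c], dtype=float)[ok] for c in needed},
        family=family, frame_s=frame_s, t=t[ok])


def explained_deviance(y: np.ndarray, mu: np.ndarray,
                       formula: str = "conventional") -> tuple[float, float, float]:
    """(ED, D_fitted, D_null) for fitted means mu against counts y.

    D_null is the deviance of the constant model at the mean count; the
    ``printed`` formula returns D_fitted / D_null instead of the
    conventional 1 - D_fitted / D_null.
    """
    if not np.any(y):
        raise ValueError("undefined ED: constant zero target")
    d_fit = poisson_deviance(y, mu)
    d_null = poisson_deviance(y, np.full_like(y, y.mean()))
    ed = d_fit / d_null if formula == "printed" else 1.0 - d_fit / d_null
    return float(ed), d_fit, d_null


def fit_poisson_gam(design: EncodingDesign, variables,
                    cfg: EncodingConfig | None = None,
                    cache: _BasisCache | None = None) -> GamFit:
    """Penalized Poisson fit of the requested variable set."""
    cfg = cfg or EncodingConfig()
    variables = tuple(variables)
    if not variables:
        raise ValueError("need at least one variable")
    cache = cache or _BasisCache(design, cfg)
    X, S = cache.assemble(variables, cfg.penalty)
    beta, mu, conv = fit_penalized_poisson(X, design.y, S)
    ed, d_fit, d_null = explained_deviance(design.y, mu, cfg.ed_formula)
    return GamFit(variables=variables, beta=beta, mu=mu, d_fitted=d_fit,
                  d_null=d_null, explained_deviance=ed, converged=conv)


def _fit_ed(X, S, y, formula):
    _, mu, _ = fit_penalized_poisson(X, y, S)
    ed, _, _ = explained_deviance(y, mu, formula)
    return ed


def forward_select(design: EncodingDesign, cfg: EncodingConfig | None = None,
                   rng=None) -> SelectionTrace:
    """Nested stepwise forward search over the family's variable groups."""
    cfg = cfg or EncodingConfig()
    rng = np.random.default_rng(rng)
    cache = _BasisCache(design, cfg)
    y = design.y
    n = y.size
    min_shift = max(1, int(round(cfg.min_shift_s / design.frame_s)))
    trace = SelectionTrace(family=design.family)
    remaining = list(design.variables.keys())
    selected: list[str] = []

    while remaining:
        m = len(remaining)
        pct = 100.0 * (1.0 - cfg.alpha / m)
        iter_rec = []
        best = None
        for var in remaining:
            cand = tuple(selected + [var])
            X, S = cache.assemble(cand, cfg.penalty)
            ed_real = _fit_ed(X, S, y, cfg.ed_formula)
            shifts = rng.integers(min_shift, n - min_shift, size=cfg.n_shuffle)
            null_eds = np.empty(cfg.n_shuffle)
            if not selected:
                # first order: circularly shift the response
                for i, s in enumerate(shifts):
                    null_eds[i] = _fit_ed(X, S, np.roll(y, int(s)), cfg.ed_formula)
            else:
                # higher order: shift only the candidate predictor
                for i, s in enumerate(shifts):
                    Xs, Ss = cache.assemble(cand, cfg.penalty,
                                            shift_rows={var: int(s)})
                    null_eds[i] = _fit_ed(Xs, Ss, y, cfg.ed_formula)
            thr = float(np.percentile(null_eds, pct))
            norm_ed = ed_real - float(null_eds.mean())
            sig = ed_real > thr
            iter_rec.append({"variable": var, "ed": ed_real, "threshold": thr,
                             "normalized_ed": norm_ed, "significant": sig,
                             "null_eds": null_eds})
            if sig and (best is None or norm_ed > best[0] or
                        (norm_ed == best[0] and var < best[1])):
                best = (norm_ed, var)
        trace.iterations.append(iter_rec)
        if best is None:
            trace.stop_reason = ("no significant model" if not selected
                                 else "no candidate passed the shuffle gate")
            break
        selected.append(best[1])
        remaining.remove(best[1])
    else:
        trace.stop_reason = "all variables selected"
    trace.selected = list(selected)
    return trace


def evaluate_prediction(design: EncodingDesign, variables,
                        cfg: EncodingConfig | None = None) -> dict:
    """Five-fold contiguous-in-time cross-validated prediction score.

    Each fold's held-out predicted rate is correlated with the real counts
    (R^2 = squared Pearson r); the final R^2 is the fold mean and the F-test
    on the pooled prediction tests it against zero at alpha = 0.05.
    """
    cfg = cfg or EncodingConfig()
    variables = tuple(variables)
    if not variables:
        raise ValueError("empty selection")
    cache = _BasisCache(design, cfg)
    y = design.y
    n = y.size
    bounds = np.linspace(0, n, cfg.n_folds + 1).astype(int)
    r2s, preds, reals = [], [], []
    skipped = 0
    for k in range(cfg.n_folds):
        a, b = bounds[k], bounds[k + 1]
        test = np.zeros(n, dtype=bool)
        test[a:b] = True
        if y[test].sum() == 0:
            skipped += 1
            continue
        sub = EncodingDesign(
            y=y[~test],
            predictors={c: design.predictors[c][~test] for c in design.predictors},
            family=design.family, frame_s=design.frame_s, t=design.t[~test])
        sub_cache = _BasisCache(sub, cfg)
        X, S = sub_cache.assemble(variables, cfg.penalty)
        beta, _, _ = fit_penalized_poisson(X, sub.y, S)
        # evaluate the trained bases on the held-out frames
        parts = [np.ones((test.sum(), 1))]
        for var in variables:
            mats = []
            for c in design.variables[var]:
                x = design.predictors[c][test]
                if c in _CIRCULAR:
                    basis = FourierBasis(order=cfg.fourier_order, period=360.0)
                else:
                    basis = SplineBasis.from_data(design.predictors[c][~test],
                                                  n_splines=cfg.n_splines)
                mats.append(basis.design(x))
            parts.append(np.hstack(mats))
        Xt = np.hstack(parts)
        mu = np.exp(np.clip(Xt @ beta, -30.0, 30.0))
        yt = y[test]
        if np.std(mu) == 0 or np.std(yt) == 0:
            skipped += 1
            continue
        r = np.corrcoef(mu, yt)[0, 1]
        r2s.append(r * r)
        preds.append(mu)
        reals.append(yt)
    if not r2s:
        return {"r2": np.nan, "f_p": np.nan, "folds_skipped": skipped}
    pred = np.concatenate(preds)
    real = np.concatenate(reals)
    r_all = np.corrcoef(pred, real)[0, 1]
    r2_all = r_all * r_all
    dof = pred.size - 2
    f_stat = r2_all / max(1.0 - r2_all, 1e-12) * dof
    f_p = float(stats.f.sf(f_stat, 1, dof))
    return {"r2": float(np.mean(r2s)), "f_p": f_p, "folds_skipped": skipped}


def encode_unit(design: EncodingDesign, cfg: EncodingConfig | None = None,
                rng=None) -> SelectionTrace:
    """Forward selection followed by cross-validated scoring of the winner."""
    cfg = cfg or EncodingConfig()
    trace = forward_select(design, cfg, rng)
    if trace.selected:
        score = evaluate_prediction(design, trace.selected, cfg)
        trace.r2_cv = score["r2"]
        trace.f_p = score["f_p"]
        trace.encoding = bool(np.isfinite(score["f_p"]) and score["f_p"] < cfg.alpha)
    return trace
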