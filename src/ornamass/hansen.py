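"""Multi-regime Ornstein-Uhlenbeck (generalized Hansen) models on painted trees.

A regime painting (SIMMAP-style tree) assigns every branch segment to a
selective regime; log body mass then evolves with attraction ``alpha``
(1/Ma) toward a regime optimum ``theta`` (log_e kg) at diffusion rate
``sigma2`` ((log_e kg)^2/Ma).  Model family:

========  =====================  ==========================================
model     free parameters        notes
========  =====================  ==========================================
BM1       sigma2                 plain Brownian motion
BMS       sigma2 per regime      rate shifts, no attraction
OU1       alpha, sigma2, theta   single optimum
OUM       + theta per regime     regime optima, shared alpha/sigma2
OUMV      + sigma2 per regime    the study's best model
OUMA      + alpha per regime     shared sigma2
OUMVA     everything per regime
========  =====================  ==========================================

Fossil (non-ultrametric) tips are supported: variance accumulates only over
each tip's realized lifespan.  ``root_mode='estimated'`` adds the root value
as a free parameter; ``'stationary'`` starts the root at the stationary
distribution of its regime (mean theta_root, variance sigma2/(2 alpha)).
BM models always estimate the root (no stationary distribution exists).
Optima enter the mean linearly, so they are profiled by GLS inside the
likelihood; only alpha and sigma2 are numerically optimized (multi-start,
log scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .model_eval import ModelScore, information_scores
from .trees import SimmapTree

log = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "HansenFit",
    "HansenModelAverage",
    "hansen_loglik",
    "fit_hansen",
    "hansen_model_set",
    "half_life",
    "sanity_flags",
]

MODELS = ("BM1", "BMS", "OU1", "OUM", "OUMV", "OUMA", "OUMVA")
OU_MODELS = ("OU1", "OUM", "OUMV", "OUMA", "OUMVA")
ALPHA_DEGENERATE = 1e-6


def _per_regime(model: str) -> dict:
    return {
        "alpha": model in ("OUMA", "OUMVA"),
        "sigma2": model in ("BMS", "OUMV", "OUMVA"),
        "theta": model in ("OUM", "OUMV", "OUMA", "OUMVA"),
    }


class HansenDesign:
    """Precomputed traversal schedule for one painted tree."""

    def __init__(self, smap: SimmapTree):
        self.tree = smap
        self.nodes = list(smap.postorder())
        self.index = {id(v): i for i, v in enumerate(self.nodes)}
        self.tips = smap.tips()
        self.tip_idx = np.array([self.index[id(t)] for t in self.tips])
        self.taxa = [t.label for t in self.tips]
        states = sorted({s for v in self.nodes if v.parent is not None
                         for s, _ in v.segments})
        self.regimes = states
        self.reg_idx = {s: i for i, s in enumerate(states)}
        self.root_regime = smap.root_state()
        n = len(self.tips)
        # MRCA node index per tip pair
        self.mrca = np.zeros((n, n), dtype=int)
        below: dict[int, list[int]] = {}
        for v in self.nodes:
            i = self.index[id(v)]
            if v.is_tip:
                below[id(v)] = [int(np.where(self.tip_idx == i)[0][0])]
            else:
                kids = [below[id(c)] for c in v.children]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        self.mrca[np.ix_(kids[a], kids[b])] = i
                        self.mrca[np.ix_(kids[b], kids[a])] = i
                below[id(v)] = [x for k in kids for x in k]
        for j, i in enumerate(self.tip_idx):
            self.mrca[j, j] = i

    def moments(self, alpha, sigma2, root_mode: str):
        """Per-node decay W, variance V and mean-weight rows.

        ``alpha``/``sigma2`` are arrays over regimes (use equal entries for
        shared-parameter models; alpha all zero for BM).  Mean weights span
        (root column, one column per regime): E[x] = M @ (root_or_theta).
        """
        K = len(self.regimes)
        nn = len(self.nodes)
        W = np.ones(nn)
        V = np.zeros(nn)
        Mw = np.zeros((nn, K + 1))
        ri = self.index[id(self.tree.root)]
        Mw[ri, 0] = 1.0
        if root_mode == "stationary":
            a0 = alpha[self.reg_idx[self.root_regime]]
            s0 = sigma2[self.reg_idx[self.root_regime]]
            if a0 <= 0:
                raise ValueError("stationary root undefined for alpha = 0 (use a BM model)")
            V[ri] = s0 / (2.0 * a0)
        order = [v for v in self.tree.preorder()]
        for v in order:
            if v.parent is None:
                continue
            i, p = self.index[id(v)], self.index[id(v.parent)]
            w, var = W[p], V[p]
            mrow = Mw[p].copy()
            for s, d in v.segments:
                k = self.reg_idx[s]
                a, s2 = alpha[k], sigma2[k]
                if a > 1e-12:
                    e1 = np.exp(-a * d)
                    e2 = e1 * e1
                    var = var * e2 + s2 * (1.0 - e2) / (2.0 * a)
                    mrow = mrow * e1
                    mrow[k + 1] += 1.0 - e1
                    w = w * e1
                else:
                    var = var + s2 * d
            W[i], V[i] = w, var
            Mw[i] = mrow
        return W, V, Mw

    def cov_mean(self, alpha, sigma2, root_mode: str):
        W, V, Mw = self.moments(alpha, sigma2, root_mode)
        ti = self.tip_idx
        Wt = W[ti]
        Wa = W[self.mrca]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(Wa > 0, np.outer(Wt, Wt) / np.maximum(Wa * Wa, 1e-300), 0.0)
        Sigma = V[self.mrca] * ratio
        Sigma = 0.5 * (Sigma + Sigma.T)
        M = Mw[ti]
        return Sigma, M


def _expand(value, regimes, per_regime: bool, name: str):
    K = len(regimes)
    if np.isscalar(value) or value is None:
        if value is None:
            raise ValueError(f"missing parameter {name}")
        return np.full(K, float(value))
    if isinstance(value, dict):
        return np.array([float(value[r]) for r in regimes])
    arr = np.asarray(value, dtype=float)
    if arr.size == 1:
        return np.full(K, float(arr))
    if arr.size != K:
        raise ValueError(f"{name} needs one entry per regime ({K})")
    return arr


def _theta_vector(design: HansenDesign, M, model, theta, root_value, root_mode):
    """Assemble the (root, theta...) coefficient vector for the mean."""
    K = len(design.regimes)
    coef = np.zeros(K + 1)
    if model in ("BM1", "BMS"):
        coef[0] = root_value
        return coef
    th = _expand(theta, design.regimes, True, "theta")
    coef[1:] = th
    if root_mode == "stationary":
        coef[0] = th[design.reg_idx[design.root_regime]]
    else:
        if root_value is None:
            raise ValueError("root_mode='estimated' needs a root value")
        coef[0] = root_value
    return coef


def hansen_loglik(
    smap: SimmapTree,
    x,
    model: str = "OUMV",
    alpha=None,
    sigma2=None,
    theta=None,
    root_value=None,
    root_mode: str = "stationary",
) -> float:
    """MVN log-likelihood of tip values under a painted OU/BM model.

    ``x`` maps taxa to log_e mass.  For OU models ``alpha`` must be > 0
    (pass a BM model for the diffusion limit).  Parameters may be scalars
    (shared) or per-regime dicts/arrays where the model frees them.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    design = smap if isinstance(smap, HansenDesign) else HansenDesign(smap)
    regimes = design.regimes
    if model in ("BM1", "BMS"):
        a = np.zeros(len(regimes))
        root_mode = "estimated"
    else:
        a = _expand(alpha, regimes, _per_regime(model)["alpha"], "alpha")
        if (a <= 0).any():
            raise ValueError("alpha must be > 0 for OU models; use BM1/BMS for alpha = 0")
    s2 = _expand(sigma2, regimes, _per_regime(model)["sigma2"], "sigma2")
    if (s2 <= 0).any():
        raise ValueError("sigma2 must be > 0")
    Sigma, M = design.cov_mean(a, s2, root_mode)
    coef = _theta_vector(design, M, model, theta, root_value, root_mode)
    mu = M @ coef
    xv = np.array([x[t] for t in design.taxa], dtype=float)
    n = xv.size
    try:
        cf = cho_factor(Sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("OU covariance not positive definite") from exc
    r = xv - mu
    quad = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


@dataclass
class HansenFit:
    model: str
    root_mode: str
    alpha: dict | None
    sigma2: dict
    theta: dict | None
    root_value: float | None
    se: dict
    logL: float
    score: ModelScore
    flags: list[str] = field(default_factory=list)
    regimes: list = field(default_factory=list)


def _profile_mean(design, Sigma, M, model, root_mode):
    """GLS estimate of the linear mean coefficients given the covariance.

    Returns (coef, columns, logL_profile_parts).  Columns actually free:
    root column only for BM; for OU, theta columns (+ root if estimated;
    stationary root reuses the root-regime theta column).
    """
    K = len(design.regimes)
    if model in ("BM1", "BMS"):
        A = M[:, [0]]
        cols = ["root"]
    else:
        if _per_regime(model)["theta"]:
            A = M[:, 1:].copy()
            cols = [f"theta_{r}" for r in design.regimes]
        else:
            A = M[:, 1:].sum(axis=1, keepdims=True)
            cols = ["theta"]
        if root_mode == "estimated":
            A = np.column_stack([M[:, 0], A])
            cols = ["root"] + cols
        else:
            ridx = design.reg_idx[design.root_regime]
            if _per_regime(model)["theta"]:
                A[:, ridx] += M[:, 0]
            else:
                A[:, 0] += M[:, 0]
    return A, cols


def _fit_given_cov(design, xv, Sigma, A):
    cf = cho_factor(Sigma, lower=True)
    Ai = cho_solve(cf, A)
    xi = cho_solve(cf, xv)
    G = A.T @ Ai
    coef = np.linalg.solve(G, A.T @ xi)
    r = xv - A @ coef
    quad = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    n = xv.size
    logL = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return coef, logL


def fit_hansen(
    smap: SimmapTree,
    x,
    model: str = "OUMV",
    root_mode: str = "stationary",
    n_starts: int = 5,
    seed: int = 0,
) -> HansenFit:
    """Multi-start ML fit of one Hansen model on one painting.

    alpha and sigma2 are searched on the log scale from ``n_starts`` seeded
    starting points; optima (and the root, when estimated) are profiled by
    GLS.  Standard errors come from the numerical Hessian of the full
    parameter vector; a singular Hessian leaves SEs absent and raises a
    diagnostic flag.  AICc uses n = number of tips.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    design = HansenDesign(smap)
    regimes = design.regimes
    K = len(regimes)
    per = _per_regime(model)
    xv = np.array([x[t] for t in design.taxa], dtype=float)
    if model in ("BM1", "BMS"):
        root_mode = "estimated"
    n_alpha = 0 if model in ("BM1", "BMS") else (K if per["alpha"] else 1)
    n_sig = K if per["sigma2"] else 1

    def unpack(v):
        a = np.exp(v[:n_alpha])
        s = np.exp(v[n_alpha:n_alpha + n_sig])
        alpha = (a if per["alpha"] else np.full(K, a[0] if n_alpha else 0.0))
        if n_alpha == 0:
            alpha = np.zeros(K)
        sigma2 = s if per["sigma2"] else np.full(K, s[0])
        return alpha, sigma2

    def nll(v):
        alpha, sigma2 = unpack(v)
        try:
            Sigma, M = design.cov_mean(alpha, sigma2, root_mode)
            A, _ = _profile_mean(design, Sigma, M, model, root_mode)
            _, logL = _fit_given_cov(design, xv, Sigma, A)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        return -logL

    rng = np.random.default_rng(seed)
    ndim = n_alpha + n_sig
    lo, hi = np.log(1e-9), np.log(50.0)
    bounds = [(lo, hi)] * ndim
    depth = max(np.diag(HansenDesign(smap).cov_mean(
        np.zeros(K), np.ones(K), "estimated")[0]))
    base_alpha = np.log(np.log(2.0) / max(depth, 1e-6))  # half-life ~ tree depth
    var_scale = np.log(max(np.var(xv), 1e-4) / max(depth, 1e-6))
    best = None
    for i in range(n_starts):
        x0 = np.concatenate([
            np.full(n_alpha, base_alpha) + rng.normal(0, 1.0, n_alpha),
            np.full(n_sig, var_scale) + rng.normal(0, 1.0, n_sig),
        ])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    alpha, sigma2 = unpack(best.x)
    Sigma, M = design.cov_mean(alpha, sigma2, root_mode)
    A, cols = _profile_mean(design, Sigma, M, model, root_mode)
    coef, logL = _fit_given_cov(design, xv, Sigma, A)

    # assemble parameter records
    theta = None
    root_value = None
    named = dict(zip(cols, coef))
    if model in ("BM1", "BMS"):
        root_value = float(named["root"])
    else:
        if per["theta"]:
            theta = {r: float(named[f"theta_{r}"]) for r in regimes}
        else:
            theta = {r: float(named["theta"]) for r in regimes}
        if root_mode == "estimated":
            root_value = float(named["root"])
        else:
            root_value = theta[design.root_regime]
    alpha_out = None if model in ("BM1", "BMS") else (
        {r: float(a) for r, a in zip(regimes, alpha)} if per["alpha"]
        else float(alpha[0])
    )
    sigma_out = ({r: float(s) for r, s in zip(regimes, sigma2)} if per["sigma2"]
                 else float(sigma2[0]))

    # numerical Hessian over (log alpha, log sigma2, mean coefs)
    full0 = np.concatenate([best.x, coef])
    nmean = len(coef)

    def nll_full(v):
        alpha_, sigma2_ = unpack(v[:ndim])
        try:
            S_, M_ = design.cov_mean(alpha_, sigma2_, root_mode)
            A_, _ = _profile_mean(design, S_, M_, model, root_mode)
            cf = cho_factor(S_, lower=True)
            r = xv - A_ @ v[ndim:]
            quad = float(r @ cho_solve(cf, r))
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return 0.5 * (xv.size * np.log(2 * np.pi) + logdet + quad)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10

    se: dict = {}
    flags: list[str] = []
    try:
        H = _num_hessian(nll_full, full0)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if (d <= 0).any():
            raise np.linalg.LinAlgError("negative variance")
        sevec = np.sqrt(d)
        # delta method back to natural scale for log-parameterized entries
        k = 0
        if n_alpha:
            vals = alpha if per["alpha"] else alpha[:1]
            for r, vv in zip(regimes if per["alpha"] else ["alpha"], vals):
                se[f"alpha_{r}" if per["alpha"] else "alpha"] = float(sevec[k] * vv)
                k += 1
        vals = sigma2 if per["sigma2"] else sigma2[:1]
        for r, vv in zip(regimes if per["sigma2"] else ["sigma2"], vals):
            se[f"sigma2_{r}" if per["sigma2"] else "sigma2"] = float(sevec[k] * vv)
            k += 1
        for c, s_ in zip(cols, sevec[ndim:]):
            se[c] = float(s_)
    except np.linalg.LinAlgError:
        se = {}
        flags.append("hessian_singular")
        log.warning("Hansen %s: Hessian not invertible; SEs unavailable", model)

    Kparams = ndim + nmean
    (score,) = information_scores([(model, logL, Kparams)], n=xv.size, corrected=True)
    fit = HansenFit(
        model=model, root_mode=root_mode, alpha=alpha_out, sigma2=sigma_out,
        theta=theta, root_value=root_value, se=se, logL=logL, score=score,
        flags=flags, regimes=list(regimes),
    )
    fit.flags = flags + sanity_flags(fit, xv)
    return fit


def _num_hessian(f, x0, eps=1e-4):
    n = len(x0)
    H = np.zeros((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def sanity_flags(fit: HansenFit, x) -> list[str]:
    """Degenerate-fit diagnostics mirroring the whole-tree pathologies.

    Flags: ``alpha_degenerate`` (alpha < 1e-6/Ma: effectively BM, optima
    meaningless), ``theta_outside`` (an optimum far outside the data range),
    ``theta_unreliable`` (SE exceeding the estimate).
    """
    xv = np.asarray([x[k] for k in x] if isinstance(x, dict) else x, dtype=float)
    flags = []
    alphas = []
    if fit.alpha is not None:
        alphas = list(fit.alpha.values()) if isinstance(fit.alpha, dict) else [fit.alpha]
    if any(a < ALPHA_DEGENERATE for a in alphas):
        flags.append("alpha_degenerate")
    if fit.theta is not None:
        lo, hi = xv.min(), xv.max()
        rng_ = hi - lo
        for r, th in fit.theta.items():
            if th < lo - 2 * rng_ or th > hi + 2 * rng_:
                flags.append("theta_outside")
                break
        for r in fit.theta:
            s = fit.se.get(f"theta_{r}")
            if s is not None and s > abs(fit.theta[r]) and abs(fit.theta[r]) > 1e-12:
                flags.append("theta_unreliable")
                break
    return flags


@dataclass
class HansenModelAverage:
    table: pd.DataFrame          # one row per (map, model, root_mode)
    mean_weights: pd.Series      # mean AICc weight per (model, root_mode)
    theta_averaged: dict         # regime -> model-averaged optimum
    theta_dispersion: dict       # regime -> s.d. of the per-map averages
    excluded: pd.DataFrame       # flagged fits listed separately


def hansen_model_set(
    maps: list[SimmapTree],
    x,
    models=MODELS,
    root_modes=("estimated", "stationary"),
    seed: int = 0,
) -> HansenModelAverage:
    """Fit every (model, root_mode) on every map; average by AICc weight.

    Weights are computed within each map over the admissible (unflagged)
    fits; flagged fits are excluded from averages and listed separately.
    Optima are weight-averaged over models that estimate them, then averaged
    across maps.
    """
    if not maps:
        raise ValueError("need at least one map")
    rows = []
    for mi, smap in enumerate(maps):
        for model in models:
            modes = root_modes if model in OU_MODELS else ("estimated",)
            for rm in modes:
                try:
                    fit = fit_hansen(smap, x, model=model, root_mode=rm, seed=seed + mi)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    log.warning("fit %s/%s on map %d failed: %s", model, rm, mi, exc)
                    continue
                rows.append(dict(
                    map=mi, model=model, root_mode=rm, K=fit.score.K,
                    logL=fit.logL, aicc=fit.score.aicc,
                    flags=",".join(fit.flags), fit=fit,
                ))
    df = pd.DataFrame(rows)
    # bracket access: 'flags' shadows the DataFrame.flags attribute
    ok = df[df["flags"] == ""].copy()
    excluded = df[df["flags"] != ""].drop(columns=["fit"])
    if ok.empty:
        raise RuntimeError("no admissible model: every fit raised sanity flags")
    # AICc weights within each map over admissible fits
    parts = []
    for mi, sub in ok.groupby("map"):
        d = sub.aicc - sub.aicc.min()
        w = np.exp(-d / 2.0)
        sub = sub.assign(weight=w / w.sum())
        parts.append(sub)
    ok = pd.concat(parts)
    mean_weights = ok.groupby(["model", "root_mode"]).weight.mean().sort_values(
        ascending=False)
    # model-averaged optima per map, then across maps
    regimes = sorted({r for f in ok.fit for r in (f.theta or {})})
    per_map = {r: [] for r in regimes}
    for mi, sub in ok.groupby("map"):
        wsum = {r: 0.0 for r in regimes}
        wtot = {r: 0.0 for r in regimes}
        for _, row in sub.iterrows():
            if row.fit.theta is None:
                continue
            for r in regimes:
                wsum[r] += row.weight * row.fit.theta[r]
                wtot[r] += row.weight
        for r in regimes:
            if wtot[r] > 0:
                per_map[r].append(wsum[r] / wtot[r])
    theta_avg = {r: float(np.mean(v)) for r, v in per_map.items() if v}
    theta_disp = {r: float(np.std(v)) for r, v in per_map.items() if v}
    return HansenModelAverage(
        table=ok.drop(columns=["fit"]),
        mean_weights=mean_weights,
        theta_averaged=theta_avg,
        theta_dispersion=theta_disp,
        excluded=excluded,
    )


def half_life(alpha: float, tree_depth: float | None = None):
    """Phylogenetic half-life ln(2)/alpha (Ma); optionally the fraction of
    the tree depth it represents."""
    if alpha <= 0:
        raise ValueError("half-life needs alpha > 0")
    t = float(np.log(2.0) / alpha)
    if tree_depth is not None:
        return t, t / tree_depth
    return t
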