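"""Continuous-time Markov inference for binary characters on time trees.

Covers the Felsenstein pruning likelihood for Mk models, ML fits of the
equal-rates (ER), symmetric (SYM) and all-rates-different (ARD) binary
models, reversible-jump MCMC over rate-class partitions, a four-state
correlated-evolution (dependent) model for two binary traits, ancestral
"node fossilization" Bayes-factor tests, and stochastic character mapping
(SIMMAP-style regime paintings).

Rates are per Ma.  Root state frequencies default to the observed
(empirical) tip frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .model_eval import ModelScore, bayes_factor, BayesFactorResult, information_scores
from .trees import Node, SimmapTree, TimeTree

log = logging.getLogger(__name__)

__all__ = [
    "QMatrix",
    "MkFit",
    "RJPosterior",
    "mk_loglik",
    "fit_mk_ml",
    "compare_mk_models",
    "rjmcmc_binary",
    "fit_dependent_discrete",
    "fossilize_bf",
    "stochastic_maps",
    "node_state_frequencies",
]

RATE_LO, RATE_HI = 1e-9, 100.0

# dependent-model cell names; state index = 2*traitA + traitB
DEP_CELLS = {
    "gainA_B0": (0, 2), "gainA_B1": (1, 3),
    "lossA_B0": (2, 0), "lossA_B1": (3, 1),
    "gainB_A0": (0, 1), "gainB_A1": (2, 3),
    "lossB_A0": (1, 0), "lossB_A1": (3, 2),
}
INDEP_GROUPS = {
    "gainA": ("gainA_B0", "gainA_B1"),
    "lossA": ("lossA_B0", "lossA_B1"),
    "gainB": ("gainB_A0", "gainB_A1"),
    "lossB": ("lossB_A0", "lossB_A1"),
}


@dataclass
class QMatrix:
    """Instantaneous rate matrix; rows sum to zero, off-diagonals >= 0."""

    states: list
    matrix: np.ndarray

    def __post_init__(self):
        Q = np.asarray(self.matrix, dtype=float)
        k = len(self.states)
        if Q.shape != (k, k):
            raise ValueError("Q shape does not match state count")
        off = Q[~np.eye(k, dtype=bool)]
        if (off < -1e-12).any():
            raise ValueError("negative off-diagonal rate")
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        self.matrix = Q

    @classmethod
    def binary(cls, q01: float, q10: float) -> "QMatrix":
        return cls([0, 1], np.array([[-q01, q01], [q10, -q10]]))

    @classmethod
    def dependent(cls, rates: dict) -> "QMatrix":
        """Four combined states (A,B): 00, 01, 10, 11; no double transitions."""
        Q = np.zeros((4, 4))
        for name, (i, j) in DEP_CELLS.items():
            Q[i, j] = rates[name]
        return cls(["00", "01", "10", "11"], Q)

    @classmethod
    def independent(cls, gainA, lossA, gainB, lossB) -> "QMatrix":
        rates = {}
        for g, val in zip(INDEP_GROUPS, (gainA, lossA, gainB, lossB)):
            for cell in INDEP_GROUPS[g]:
                rates[cell] = val
        return cls.dependent(rates)

    def stationary(self) -> np.ndarray:
        k = len(self.states)
        A = np.vstack([self.matrix.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()


def _p_binary(q01: float, q10: float, t: np.ndarray) -> np.ndarray:
    """Closed-form 2x2 transition matrices for an array of durations."""
    t = np.asarray(t, dtype=float)
    s = q01 + q10
    P = np.empty(t.shape + (2, 2))
    if s <= 0:
        P[...] = np.eye(2)
        return P
    e = np.exp(-s * t)
    p0, p1 = q10 / s, q01 / s
    P[..., 0, 0] = p0 + p1 * e
    P[..., 0, 1] = p1 * (1 - e)
    P[..., 1, 0] = p0 * (1 - e)
    P[..., 1, 1] = p1 + p0 * e
    return P


def transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for every duration in ``ts`` (k x k, via eigendecomposition,
    falling back to scaling-and-squaring when Q is defective)."""
    k = Q.shape[0]
    if k == 2:
        return _p_binary(Q[0, 1], Q[1, 0], ts)
    try:
        w, V = np.linalg.eig(Q)
        Vi = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e8:
            E = np.exp(np.multiply.outer(ts, w))  # (m, k)
            P = np.einsum("ij,mj,jk->mik", V, E, Vi).real
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=2, keepdims=True)
            return P
    except np.linalg.LinAlgError:
        pass
    P = np.array([expm(Q * t) for t in ts])
    if not np.isfinite(P).all():
        raise ValueError("non-finite transition matrix exp(Qt)")
    return P


class MkPruner:
    """Reusable pruning machinery for one (tree, tip-states) pair.

    Precomputes the postorder schedule so repeated likelihood evaluations
    (MCMC, optimizers) only pay for the transition matrices and the partial
    pass.
    """

    def __init__(self, tree: TimeTree, states, k: int = 2):
        if not tree.is_binary():
            raise ValueError("likelihood requires a fully resolved (binary) tree")
        self.tree = tree
        self.k = k
        nodes = list(tree.postorder())
        self.nodes = nodes
        self.index = {id(v): i for i, v in enumerate(nodes)}
        self.lengths = np.array(
            [v.length if v.parent is not None else 0.0 for v in nodes], dtype=float
        )
        self.tip_state = {}
        getter = states.get if hasattr(states, "get") else states.__getitem__
        missing = []
        for v in nodes:
            if v.is_tip:
                s = getter(v.label)
                if s is None or (isinstance(s, float) and math.isnan(s)):
                    missing.append(v.label)
                else:
                    self.tip_state[id(v)] = int(s)
        if missing:
            raise ValueError(f"unscored tips: {sorted(missing)}")
        vals = np.array(list(self.tip_state.values()))
        if vals.min() < 0 or vals.max() >= k:
            raise ValueError(f"tip states outside 0..{k-1}")
        counts = np.bincount(vals, minlength=k)
        self.empirical = counts / counts.sum()

    def root_freq(self, Q: QMatrix, root: str) -> np.ndarray:
        if isinstance(root, (list, tuple, np.ndarray)):
            f = np.asarray(root, dtype=float)
            return f / f.sum()
        if root == "empirical":
            return self.empirical
        if root == "flat":
            return np.full(self.k, 1.0 / self.k)
        if root == "stationary":
            return Q.stationary()
        raise ValueError(f"unknown root frequency rule {root!r}")

    def partials(self, Q: QMatrix, constraints=None):
        """Per-node scaled partial likelihoods plus log scaler; also returns
        the transition matrices used (postorder-aligned)."""
        P = transition_matrices(Q.matrix, self.lengths)
        con = {}
        if constraints:
            for node, s in constraints.items():
                con[self.index[id(node)]] = int(s)
        k = self.k
        L = np.zeros((len(self.nodes), k))
        logscale = 0.0
        for i, v in enumerate(self.nodes):
            if v.is_tip:
                L[i, self.tip_state[id(v)]] = 1.0
            else:
                part = np.ones(k)
                for c in v.children:
                    j = self.index[id(c)]
                    part = part * (P[j] @ L[j])
                if i in con:
                    keep = con[i]
                    mask = np.zeros(k)
                    mask[keep] = 1.0
                    part = part * mask
                m = part.max()
                if m <= 0:
                    return L, -np.inf, P
                L[i] = part / m
                logscale += np.log(m)
            if v.is_tip and i in con and self.tip_state[id(v)] != con[i]:
                return L, -np.inf, P
        return L, logscale, P

    def loglik(self, Q: QMatrix, root: str = "empirical", constraints=None) -> float:
        L, logscale, _ = self.partials(Q, constraints)
        if not np.isfinite(logscale):
            return -np.inf
        freq = self.root_freq(Q, root)
        tot = float(freq @ L[self.index[id(self.tree.root)]])
        if tot <= 0:
            return -np.inf
        return float(np.log(tot) + logscale)


def mk_loglik(tree: TimeTree, states, Q: QMatrix, root: str = "empirical",
              constraints=None) -> float:
    """Felsenstein pruning log-likelihood of tip states under ``Q``.

    ``root`` weights the root partials: 'empirical' (observed tip
    frequencies; the default), 'flat', 'stationary', or an explicit vector.
    ``constraints`` maps internal nodes to forced states ("fossilization").
    """
    k = Q.matrix.shape[0]
    return MkPruner(tree, states, k=k).loglik(Q, root=root, constraints=constraints)


@dataclass
class MkFit:
    model: str
    q01: float
    q10: float
    logL: float
    score: ModelScore | None = None
    boundary_flag: bool = False

    @property
    def Q(self) -> QMatrix:
        return QMatrix.binary(self.q01, self.q10)


def fit_mk_ml(tree: TimeTree, states, model: str = "ER", root: str = "empirical") -> MkFit:
    """Bounded ML fit of a binary Mk model.

    For two states SYM is structurally identical to ER (one free rate).  A
    rate estimate pinned at a search bound raises ``boundary_flag``.
    """
    from scipy import optimize

    pruner = MkPruner(tree, states, k=2)
    model = model.upper()
    if model in ("ER", "SYM"):
        nfree = 1

        def unpack(v):
            return float(np.exp(v[0])), float(np.exp(v[0]))
    elif model == "ARD":
        nfree = 2

        def unpack(v):
            return float(np.exp(v[0])), float(np.exp(v[1]))
    else:
        raise ValueError("model must be ER, SYM or ARD")

    def nll(v):
        q01, q10 = unpack(v)
        ll = pruner.loglik(QMatrix.binary(q01, q10), root=root)
        return -ll if np.isfinite(ll) else 1e10

    bounds = [(np.log(RATE_LO), np.log(RATE_HI))] * nfree
    best = None
    for start in (-3.0, -1.0, -5.0):
        res = optimize.minimize(nll, np.full(nfree, start), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    q01, q10 = unpack(best.x)
    # the surface is flat near a pinned rate, so flag by proximity band
    flag = any(q <= 100 * RATE_LO or q >= RATE_HI / 2 for q in (q01, q10))
    if flag:
        log.warning("Mk %s fit: rate pinned at search bound (flat or invariant data?)", model)
    fit = MkFit(model=model, q01=q01, q10=q10, logL=-best.fun, boundary_flag=flag)
    (fit.score,) = information_scores(
        [(model, fit.logL, nfree)], n=tree.n_tips, corrected=True
    )
    return fit


def compare_mk_models(tree: TimeTree, states, models=("ER", "SYM", "ARD"),
                      root: str = "empirical"):
    """Fit several Mk models and score them jointly with AICc weights."""
    fits = {m: fit_mk_ml(tree, states, m, root=root) for m in models}
    scores = information_scores(
        [(m, fits[m].logL, 1 if m in ("ER", "SYM") else 2) for m in models],
        n=tree.n_tips, corrected=True,
    )
    for s in scores:
        fits[s.name].score = s
    return fits, scores


# ---------------------------------------------------------------------------
# Reversible-jump MCMC over binary rate models
# ---------------------------------------------------------------------------

# model id -> (class of q01, class of q10); 0 means structural zero
RJ_MODELS = {
    "one_rate": (1, 1),
    "two_rate": (1, 2),
    "q01_zero": (0, 1),
    "q10_zero": (1, 0),
}


@dataclass
class RJPosterior:
    draws: pd.DataFrame
    settings: dict

    @property
    def logL_trace(self) -> np.ndarray:
        return self.draws["logL"].to_numpy()

    def model_frequencies(self) -> pd.Series:
        if "model" not in self.draws.columns:
            raise ValueError("fixed-parametrization posterior has no model column")
        return self.draws["model"].value_counts(normalize=True)


def _rates_of(model: str, values: dict) -> tuple[float, float]:
    c01, c10 = RJ_MODELS[model]
    return (values.get(c01, 0.0) if c01 else 0.0, values.get(c10, 0.0) if c10 else 0.0)


def rjmcmc_binary(
    trees,
    states,
    iterations: int = 2_010_000,
    thin: int = 1_000,
    burnin: int = 100_000,
    seed: int = 0,
    fixed_model: str | None = None,
    root: str = "empirical",
    constraints=None,
    hyper_max: float = 10.0,
) -> RJPosterior:
    """Reversible-jump MCMC over binary transition-rate models.

    Rate classes may be merged (one rate), split (two rates) or zeroed; jump
    proposals redraw the affected rates from the exponential hyperprior,
    whose mean is itself sampled uniformly on (0, ``hyper_max``).  Defaults
    follow the published chain settings (2,010,000 iterations, thin 1,000,
    burn-in 100,000).  ``fixed_model`` ('ER' or 'ARD') disables jumps and
    runs plain Metropolis in that parametrization, e.g. for Bayes-factor
    comparisons or fossilization tests.
    """
    if isinstance(trees, TimeTree):
        trees = [trees]
    rng = np.random.default_rng(seed)
    pruners = [MkPruner(t, states, k=2) for t in trees]
    tree_idx = 0

    model = "one_rate" if fixed_model in (None, "ER", "SYM") else "two_rate"
    if fixed_model in ("ARD",):
        model = "two_rate"
    m_hyper = 1.0
    values = {1: 0.05} if model == "one_rate" else {1: 0.05, 2: 0.05}

    def loglik(model, values, ti):
        q01, q10 = _rates_of(model, values)
        return pruners[ti].loglik(QMatrix.binary(q01, q10), root=root,
                                  constraints=constraints)

    cur = loglik(model, values, tree_idx)
    step = 0.8
    jump_acc = 0
    records = []
    model_names = list(RJ_MODELS)
    for it in range(iterations):
        if len(trees) > 1:
            ti = int(rng.integers(len(trees)))
            new = loglik(model, values, ti)
            if np.log(rng.uniform()) < new - cur:
                tree_idx, cur = ti, new
        # within-model rate updates (multiplicative random walk, Exp(m) prior)
        for cls in list(values):
            prop = values[cls] * float(np.exp(rng.normal(0, step)))
            if not (RATE_LO <= prop <= RATE_HI):
                continue
            vals2 = dict(values)
            vals2[cls] = prop
            new = loglik(model, vals2, tree_idx)
            ratio = (new - cur) + (-(prop - values[cls]) / m_hyper) + np.log(prop / values[cls])
            if np.log(rng.uniform()) < ratio:
                values, cur = vals2, new
        # hyperprior mean update
        mp = m_hyper + rng.normal(0, 1.0)
        if 1e-3 < mp < hyper_max:
            k = len(values)
            tot = sum(values.values())
            ratio = (-tot / mp - k * np.log(mp)) - (-tot / m_hyper - k * np.log(m_hyper))
            if np.log(rng.uniform()) < ratio:
                m_hyper = mp
        # reversible jump: uniform proposal over the other models, affected
        # rates redrawn from the hyperprior (proposal = prior, so the
        # acceptance ratio reduces to the likelihood ratio)
        if fixed_model is None:
            others = [m for m in model_names if m != model]
            mprop = others[int(rng.integers(len(others)))]
            classes = {c for c in RJ_MODELS[mprop] if c != 0}
            vals2 = {c: float(rng.exponential(m_hyper)) for c in classes}
            new = loglik(mprop, vals2, tree_idx)
            if np.log(rng.uniform()) < new - cur:
                model, values, cur = mprop, vals2, new
                if it >= burnin:
                    jump_acc += 1
        if it >= burnin and (it - burnin) % thin == 0:
            q01, q10 = _rates_of(model, values)
            records.append(
                dict(model=model, q01=q01, q10=q10, hyper_mean=m_hyper,
                     tree_index=tree_idx, logL=cur)
            )
    if fixed_model is None and jump_acc == 0 and iterations > burnin:
        log.warning("RJMCMC: no model jumps accepted after burn-in (chain may be stuck)")
    return RJPosterior(
        draws=pd.DataFrame(records),
        settings=dict(iterations=iterations, thin=thin, burnin=burnin, seed=seed,
                      fixed_model=fixed_model, root=root),
    )


# ---------------------------------------------------------------------------
# Correlated (dependent) two-trait model
# ---------------------------------------------------------------------------

def fit_dependent_discrete(
    trees,
    traitA,
    traitB,
    mode: str = "dependent",
    iterations: int = 200_000,
    thin: int = 100,
    burnin: int = 20_000,
    seed: int = 0,
    root: str = "empirical",
    hyper_max: float = 10.0,
) -> RJPosterior:
    """MCMC over the four-state model of two interacting binary traits.

    States combine (traitA, traitB); double transitions are structurally
    zero.  ``mode='independent'`` shares each trait's gain/loss rate across
    the other trait's background (4 free rates); ``mode='dependent'`` frees
    all 8.  The posterior records the giantism contrast
    ``rate(B 0->1 | A=1) / rate(B 0->1 | A=0)``.
    """
    if isinstance(trees, TimeTree):
        trees = [trees]
    rng = np.random.default_rng(seed)
    ga = traitA.get if hasattr(traitA, "get") else traitA.__getitem__
    gb = traitB.get if hasattr(traitB, "get") else traitB.__getitem__
    combo = {lab: 2 * int(ga(lab)) + int(gb(lab)) for lab in trees[0].tip_labels}
    va = [int(ga(l)) for l in trees[0].tip_labels]
    vb = [int(gb(l)) for l in trees[0].tip_labels]
    if va == vb or all(a == 1 - b for a, b in zip(va, vb)):
        log.warning("traits perfectly confounded; dependent-rate contrast unidentifiable")
    pruners = [MkPruner(t, combo, k=4) for t in trees]
    tree_idx = 0

    if mode == "dependent":
        names = list(DEP_CELLS)
    elif mode == "independent":
        names = list(INDEP_GROUPS)
    else:
        raise ValueError("mode must be 'independent' or 'dependent'")

    def qmat(vals):
        if mode == "dependent":
            return QMatrix.dependent(vals)
        return QMatrix.independent(vals["gainA"], vals["lossA"], vals["gainB"], vals["lossB"])

    values = {nm: 0.05 for nm in names}
    m_hyper = 1.0

    def loglik(vals, ti):
        return pruners[ti].loglik(qmat(vals), root=root)

    cur = loglik(values, tree_idx)
    step = 0.8
    records = []
    for it in range(iterations):
        if len(trees) > 1:
            ti = int(rng.integers(len(trees)))
            new = loglik(values, ti)
            if np.log(rng.uniform()) < new - cur:
                tree_idx, cur = ti, new
        for nm in names:
            prop = values[nm] * float(np.exp(rng.normal(0, step)))
            if not (RATE_LO <= prop <= RATE_HI):
                continue
            vals2 = dict(values)
            vals2[nm] = prop
            new = loglik(vals2, tree_idx)
            ratio = (new - cur) + (-(prop - values[nm]) / m_hyper) + np.log(prop / values[nm])
            if np.log(rng.uniform()) < ratio:
                values, cur = vals2, new
        mp = m_hyper + rng.normal(0, 1.0)
        if 1e-3 < mp < hyper_max:
            k = len(values)
            tot = sum(values.values())
            ratio = (-tot / mp - k * np.log(mp)) - (-tot / m_hyper - k * np.log(m_hyper))
            if np.log(rng.uniform()) < ratio:
                m_hyper = mp
        if it >= burnin and (it - burnin) % thin == 0:
            rec = dict(values)
            if mode == "dependent":
                rec["contrast"] = values["gainB_A1"] / max(values["gainB_A0"], 1e-300)
            else:
                rec["contrast"] = 1.0
            rec["hyper_mean"] = m_hyper
            rec["tree_index"] = tree_idx
            rec["logL"] = cur
            records.append(rec)
    return RJPosterior(
        draws=pd.DataFrame(records),
        settings=dict(mode=mode, iterations=iterations, thin=thin, burnin=burnin, seed=seed),
    )


# ---------------------------------------------------------------------------
# Node fossilization
# ---------------------------------------------------------------------------

def fossilize_bf(
    trees,
    states,
    node,
    forced_state: int = 0,
    iterations: int = 100_000,
    thin: int = 100,
    burnin: int = 10_000,
    seed: int = 0,
    root: str = "empirical",
) -> BayesFactorResult:
    """Bayes-factor test of an ancestral state by constraining a node.

    Two fixed-model (equal-rates) chains are run with the node forced to
    ``forced_state`` and to its opposite; the BF (2 x log harmonic-mean
    difference) is positive when the forced state is favoured.  ``node`` is
    a Node of the (first) tree or a pair of tip labels whose MRCA is used.
    """
    if isinstance(trees, TimeTree):
        trees = [trees]
    tree = trees[0]
    if isinstance(node, tuple):
        node = tree.mrca(*node)
    if node.is_tip:
        raise ValueError("fossilization applies to internal nodes")
    post_a = rjmcmc_binary(
        trees, states, iterations=iterations, thin=thin, burnin=burnin, seed=seed,
        fixed_model="ER", root=root, constraints={node: forced_state},
    )
    post_b = rjmcmc_binary(
        trees, states, iterations=iterations, thin=thin, burnin=burnin, seed=seed + 1,
        fixed_model="ER", root=root, constraints={node: 1 - forced_state},
    )
    return bayes_factor(post_a.logL_trace, post_b.logL_trace)


# ---------------------------------------------------------------------------
# Stochastic character mapping
# ---------------------------------------------------------------------------

def _simulate_path(rng, Q, a, t):
    """Unconditional Gillespie path from state ``a`` over duration ``t``."""
    k = Q.shape[0]
    s, now, hist = a, 0.0, []
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            hist.append((s, t - now))
            return hist
        wait = rng.exponential(1.0 / rate)
        if now + wait >= t:
            hist.append((s, t - now))
            return hist
        hist.append((s, wait))
        now += wait
        probs = np.clip(Q[s].copy(), 0, None)
        probs[s] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(k, p=probs))


def _bridge_path(rng, Q, a, b, t, max_n=1000):
    """Endpoint-conditioned path by uniformization (exact)."""
    k = Q.shape[0]
    omega = float(max(-Q.diagonal().min(), 1e-12))
    R = np.eye(k) + Q / omega
    Pt = transition_matrices(Q, np.array([t]))[0]
    pab = Pt[a, b]
    if pab <= 0:
        raise ValueError("endpoint pair has zero probability")
    # sample the number of uniformized jumps
    u = rng.uniform()
    cum = 0.0
    Rp = np.eye(k)  # R^n
    log_pois = -omega * t
    n = 0
    while n < max_n:
        term = math.exp(log_pois) * Rp[a, b] / pab
        cum += term
        if u <= cum:
            break
        n += 1
        Rp = Rp @ R
        log_pois += math.log(omega * t) - math.log(n)
    # sample the state sequence through R^n
    Rpows = [np.eye(k)]
    for _ in range(n):
        Rpows.append(Rpows[-1] @ R)
    seq = [a]
    for i in range(1, n):
        prev = seq[-1]
        w = R[prev, :] * Rpows[n - i][:, b]
        w = np.clip(w, 0, None)
        w /= w.sum()
        seq.append(int(rng.choice(k, p=w)))
    if n > 0:
        seq.append(b)
    times = np.sort(rng.uniform(0, t, size=n))
    # collapse virtual (self) transitions into segments
    hist = []
    cur_state, last = seq[0], 0.0
    for i in range(n):
        if seq[i + 1] != cur_state:
            hist.append((cur_state, times[i] - last))
            last = times[i]
            cur_state = seq[i + 1]
    hist.append((cur_state, t - last))
    return hist


def _conditional_path(rng, Q, a, b, t, attempts=50):
    if t <= 0:
        return [(a, 0.0)] if a == b else None
    for _ in range(attempts):
        hist = _simulate_path(rng, Q, a, t)
        if hist[-1][0] == b:
            return hist
    return _bridge_path(rng, Q, a, b, t)


def stochastic_maps(
    tree: TimeTree,
    states,
    model="ER",
    Q: QMatrix | None = None,
    nmaps: int = 25,
    seed: int = 0,
    root: str = "empirical",
) -> list[SimmapTree]:
    """Sample SIMMAP-style regime paintings conditional on tip states.

    Node states are drawn from their conditional (pruning) distributions,
    branch histories by rejection sampling with an exact uniformization
    bridge as fallback.  Tip states are honoured exactly on every map.
    """
    rng = np.random.default_rng(seed)
    if Q is None:
        fit = fit_mk_ml(tree, states, model if isinstance(model, str) else "ER", root=root)
        Q = fit.Q
    k = Q.matrix.shape[0]
    pruner = MkPruner(tree, states, k=k)
    L, logscale, P = pruner.partials(Q)
    if not np.isfinite(logscale):
        raise ValueError("tip data impossible under supplied Q")
    freq = pruner.root_freq(Q, root)
    idx = pruner.index
    maps = []
    for _ in range(nmaps):
        node_state: dict[int, int] = {}
        # root
        w = freq * L[idx[id(tree.root)]]
        w /= w.sum()
        node_state[id(tree.root)] = int(rng.choice(k, p=w))
        for v in tree.preorder():
            for c in v.children:
                j = idx[id(c)]
                w = P[j][node_state[id(v)], :] * L[j]
                w = np.clip(w, 0, None)
                w /= w.sum()
                node_state[id(c)] = int(rng.choice(k, p=w))
        out = tree.copy()
        for v_old, v_new in zip(tree.preorder(), out.preorder()):
            if v_old.parent is None:
                continue
            a = node_state[id(v_old.parent)]
            b = node_state[id(v_old)]
            hist = _conditional_path(rng, Q.matrix, a, b, v_old.length)
            if hist is None:
                raise RuntimeError("failed to sample a branch history")
            v_new.segments = [(s, d) for s, d in hist]
        smap = SimmapTree.__new__(SimmapTree)
        SimmapTree.__init__(smap, out.root, out.root_age)
        maps.append(smap)
    return maps


def node_state_frequencies(maps: list[SimmapTree]) -> pd.DataFrame:
    """Per-node posterior state frequencies aggregated over maps.

    Nodes are identified by the sorted tuple of descendant tip labels.
    """
    counts: dict[tuple, dict] = {}
    for m in maps:
        clades: dict[int, tuple] = {}
        for v in m.postorder():
            if v.is_tip:
                clades[id(v)] = (v.label,)
            else:
                clades[id(v)] = tuple(sorted(
                    lab for c in v.children for lab in clades[id(c)]
                ))
            key = clades[id(v)]
            st = m.node_state(v)
            counts.setdefault(key, {}).setdefault(st, 0)
            counts[key][st] += 1
    rows = []
    n = len(maps)
    for key, cnt in counts.items():
        row = {"clade": ";".join(key), "size": len(key)}
        for st, c in cnt.items():
            row[f"freq_{st}"] = c / n
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)
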