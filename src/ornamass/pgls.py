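"""Phylogenetic generalized least squares: ML and Bayesian regression.

The response (log_e body mass, kg) is modelled as multivariate normal with
mean ``X @ beta`` and covariance ``sigma2 * C``, where ``C`` is the
phylogenetic variance-covariance matrix after Pagel lambda/kappa/delta
transforms.  A binary ornamentation predictor turns the regression into a
phylogenetic t-test; adding a clade dummy and its interaction gives the
phylogenetic ANOVA.  The Bayesian sampler integrates over a set of
time-scaled trees by redrawing a tree index each iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .model_eval import ModelScore, information_scores
from .trees import PhyloCov, TimeTree, TransformParams, apply_transforms, phylo_vcv

log = logging.getLogger(__name__)

__all__ = [
    "TraitTable",
    "GLSFit",
    "PosteriorSample",
    "design_matrix",
    "gls_fit",
    "pgls_ml",
    "pgls_mcmc",
    "ornament_mass_threshold",
    "bm_ancestral_estimate",
]

GIANT_LOG_MASS = float(np.log(1000.0))  # 1,000 kg giantism threshold, log_e kg

TERMS = ("intercept", "Orna", "Phylo", "Orna:Phylo")


@dataclass
class TraitTable:
    """Per-taxon ornament state, log_e body mass (kg) and clade flag.

    The ``giant`` column (mass >= 1,000 kg) is derived from ``log_mass``.
    """

    table: pd.DataFrame  # columns: taxon, ornamented, log_mass, maniraptoriform

    def __post_init__(self):
        t = self.table
        need = {"taxon", "ornamented", "log_mass"}
        if not need.issubset(t.columns):
            raise ValueError(f"trait table needs columns {sorted(need)}")
        if "maniraptoriform" not in t.columns:
            t = t.assign(maniraptoriform=0)
        if t[["ornamented", "log_mass"]].isna().any().any():
            raise ValueError("missing values in ornamented/log_mass")
        if not set(np.unique(t.ornamented)) <= {0, 1}:
            raise ValueError("ornamented must be coded 0/1")
        t = t.assign(giant=(t.log_mass >= GIANT_LOG_MASS).astype(int))
        self.table = t.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    def aligned_to(self, tree: TimeTree) -> "TraitTable":
        """Reorder rows to the tree's tip order; taxa must match exactly."""
        labels = tree.tip_labels
        have = set(self.table.taxon)
        want = set(labels)
        if have != want:
            raise ValueError(
                "taxa mismatch between tree and trait table; "
                f"tree-only={sorted(want - have)[:5]}, table-only={sorted(have - want)[:5]}"
            )
        t = self.table.set_index("taxon").loc[labels].reset_index()
        return TraitTable(t)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    def __len__(self):
        return len(self.table)


def design_matrix(table: TraitTable, terms) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix from term names.

    Terms: ``intercept``, ``Orna`` (ornamented), ``Phylo`` (clade dummy),
    ``Orna:Phylo`` (interaction).
    """
    cols, names = [], []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(table)))
        elif term == "Orna":
            cols.append(table.column("ornamented"))
        elif term == "Phylo":
            cols.append(table.column("maniraptoriform"))
        elif term == "Orna:Phylo":
            cols.append(table.column("ornamented") * table.column("maniraptoriform"))
        else:
            raise ValueError(f"unknown design term {term!r}; choose from {TERMS}")
        names.append(term)
    return np.column_stack(cols), names


@dataclass
class GLSFit:
    coefficients: dict[str, float]
    sigma2: float
    logL: float
    r2: float
    transforms: TransformParams = field(default_factory=TransformParams)
    resid_sd_whitened: float = np.nan
    score: ModelScore | None = None

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))


def _gls_core(y, X, C):
    """Cholesky-whitened GLS; returns beta, sigma2(ML), logL, r2, resid sd."""
    n, p = X.shape
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix not positive definite") from exc
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise ValueError("design matrix is rank-deficient (collinear columns)")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0:
        # perfect fit: density degenerates; report +inf-free sentinel
        logL = np.inf
    else:
        logL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetC + n)
    # generalized R^2 in the whitened space, against the GLS intercept-only fit
    ones_w = solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float(np.sum((yw - mu * ones_w) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    resid_sd = np.sqrt(rss / max(n - p, 1))
    return beta, sigma2, logL, r2, resid_sd


def gls_fit(y, X, C, names=None, transforms: TransformParams | None = None) -> GLSFit:
    """Generalized least squares under residual covariance ``sigma2 * C``.

    ``sigma2`` is profiled at its ML value; the log-likelihood is the
    multivariate-normal density at the optimum (Cholesky-based, no explicit
    inverse).  R^2 is 1 - RSS/TSS in the whitened space, TSS taken about the
    GLS grand mean.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    C = C.matrix if isinstance(C, PhyloCov) else np.asarray(C, dtype=float)
    beta, sigma2, logL, r2, resid_sd = _gls_core(y, X, C)
    if names is None:
        names = [f"b{i}" for i in range(X.shape[1])]
    return GLSFit(
        coefficients=dict(zip(names, beta)),
        sigma2=sigma2,
        logL=logL,
        r2=r2,
        transforms=transforms or TransformParams(),
        resid_sd_whitened=resid_sd,
    )


class CovBuilder:
    """Fast lambda/kappa/delta covariance construction for one tree.

    Precomputes the tip-by-edge membership matrix so the kappa transform is
    a matrix product instead of a tree traversal; used in MCMC/optimizer
    inner loops.  Equivalent to :func:`ornamass.trees.apply_transforms`.
    """

    def __init__(self, tree: TimeTree):
        tips = tree.tips()
        self.taxa = [t.label for t in tips]
        index = {id(t): i for i, t in enumerate(tips)}
        edges = [v for v in tree.preorder() if v.parent is not None]
        n, m = len(tips), len(edges)
        U = np.zeros((n, m))
        below: dict[int, list[int]] = {}
        for v in tree.postorder():
            if v.is_tip:
                below[id(v)] = [index[id(v)]]
            else:
                below[id(v)] = [i for c in v.children for i in below[id(c)]]
        for j, e in enumerate(edges):
            U[below[id(e)], j] = 1.0
        self.U = U
        self.b = np.array([e.length for e in edges], dtype=float)
        if (self.b < 0).any():
            raise ValueError("negative branch length")

    def cov(self, params: TransformParams) -> np.ndarray:
        bk = np.where(self.b > 0, self.b, 0.0) ** params.kappa if params.kappa != 1 else self.b
        C = (self.U * bk) @ self.U.T
        if params.delta != 1.0:
            C = C ** params.delta
        if params.lam != 1.0:
            d = np.diag(C).copy()
            C = C * params.lam
            np.fill_diagonal(C, d)
        return C


TRANSFORM_BOUNDS = {"lam": (0.0, 1.0), "kappa": (1e-6, 3.0), "delta": (1e-6, 3.0)}


def pgls_ml(
    table: TraitTable,
    tree: TimeTree,
    formula=("intercept", "Orna"),
    transforms: tuple = ("lam", "kappa"),
) -> tuple[GLSFit, ModelScore]:
    """ML PGLS, profiling the requested Pagel transform parameters.

    ``transforms`` is any subset of {'lam', 'kappa', 'delta'} (possibly
    empty).  Free-parameter count K = len(beta) + 1 (sigma2) + number of
    transforms; AICc uses n = number of tips.
    """
    table = table.aligned_to(tree)
    y = table.column("log_mass")
    X, names = design_matrix(table, formula)
    builder = CovBuilder(tree)
    free = list(transforms)
    for t in free:
        if t not in TRANSFORM_BOUNDS:
            raise ValueError(f"unknown transform {t!r}")

    def params_from(vec):
        kw = dict(zip(free, vec))
        return TransformParams(
            lam=kw.get("lam", 1.0), kappa=kw.get("kappa", 1.0), delta=kw.get("delta", 1.0)
        )

    def nll(vec):
        try:
            C = builder.cov(params_from(vec))
            _, _, logL, _, _ = _gls_core(y, X, C)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        return -logL

    if free:
        bounds = [TRANSFORM_BOUNDS[t] for t in free]
        starts = [
            [0.5 * (lo + hi) for lo, hi in bounds],
            [max(lo, min(hi, 1.0)) for lo, hi in bounds],
            [lo + 0.05 * (hi - lo) for lo, hi in bounds],
        ]
        best = None
        for x0 in starts:
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        if not best.success and not np.isfinite(best.fun):
            raise RuntimeError(f"transform optimization failed: {best.message}")
        params = params_from(best.x)
    else:
        params = TransformParams()
    C = builder.cov(params)
    fit = gls_fit(y, X, C, names=names, transforms=params)
    K = X.shape[1] + 1 + len(free)
    (score,) = information_scores(
        [("+".join(free) if free else "none", fit.logL, K)], n=len(table), corrected=True
    )
    fit.score = score
    return fit, score


@dataclass
class PosteriorSample:
    """Thinned post-burn-in draws from the Bayesian PGLS sampler."""

    draws: pd.DataFrame  # coefficients, sigma2, transforms, tree_index, logL
    coef_names: list[str]
    settings: dict

    @property
    def logL_trace(self) -> np.ndarray:
        return self.draws["logL"].to_numpy()

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.draws.columns:
            if c in ("tree_index", "logL"):
                continue
            x = self.draws[c].to_numpy()
            rows.append(
                {
                    "parameter": c,
                    "median": np.median(x),
                    "lo2.5": np.quantile(x, 0.025),
                    "hi97.5": np.quantile(x, 0.975),
                    "prop_gt0": float(np.mean(x > 0)),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


def pgls_mcmc(
    table: TraitTable,
    trees,
    formula=("intercept", "Orna"),
    transforms: tuple = ("lam", "kappa"),
    iterations: int = 1_010_000,
    thin: int = 1_000,
    burnin: int = 10_000,
    seed: int = 0,
    coef_bound: float = 100.0,
    fix_slope_zero: bool = False,
) -> PosteriorSample:
    """Metropolis-within-Gibbs PGLS over a set of time-scaled trees.

    Defaults follow the published chain settings (1,010,000 iterations,
    thin 1,000, burn-in 10,000; uniform(-100, 100) coefficient prior); pass
    smaller values for desk-scale runs.  Each iteration redraws a uniformly
    random tree index.  ``fix_slope_zero`` pins every non-intercept
    coefficient at 0, giving the null model for Bayes-factor tests.
    """
    if isinstance(trees, TimeTree):
        trees = [trees]
    rng = np.random.default_rng(seed)
    tabs = [table.aligned_to(t) for t in trees]
    y0 = tabs[0].column("log_mass")
    builders = [CovBuilder(t) for t in trees]
    X, names = design_matrix(tabs[0], formula)
    n, p = X.shape
    free = [t for t in transforms]

    state_beta = np.zeros(p)
    state_beta[0] = float(np.mean(y0))
    state_ls2 = float(np.log(np.var(y0) + 1e-6))
    state_tr = {"lam": 0.9, "kappa": 1.0, "delta": 1.0}
    tree_idx = 0

    active = np.ones(p, dtype=bool)
    if fix_slope_zero:
        active[1:] = False
        state_beta[1:] = 0.0

    def loglik(beta, ls2, tr, ti):
        params = TransformParams(
            lam=tr.get("lam", 1.0), kappa=tr.get("kappa", 1.0), delta=tr.get("delta", 1.0)
        )
        C = builders[ti].cov(params)
        try:
            cf = cho_factor(C, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        L = cf[0]
        r = y0 - X @ beta
        z = cho_solve(cf, r)
        quad = float(r @ z)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        s2 = np.exp(ls2)
        return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + quad / s2)

    cur = loglik(state_beta, state_ls2, state_tr, tree_idx)
    if not np.isfinite(cur):
        raise RuntimeError("non-finite likelihood at initial state")

    step_beta = np.full(p, 0.5)
    step_ls2 = 0.5
    step_tr = {k: 0.1 for k in free}
    acc = {"beta": 0, "ls2": 0, "tr": 0}
    tries = {"beta": 1e-12, "ls2": 1e-12, "tr": 1e-12}

    records = []
    for it in range(iterations):
        # tree resampling (marginalizes calibration uncertainty); independence
        # proposal from the uniform tree prior, MH-corrected
        if len(trees) > 1:
            ti = int(rng.integers(len(trees)))
            new = loglik(state_beta, state_ls2, state_tr, ti)
            if np.log(rng.uniform()) < new - cur:
                tree_idx, cur = ti, new
        # coefficients, one at a time
        for j in range(p):
            if not active[j]:
                continue
            prop = state_beta.copy()
            prop[j] += rng.normal(0, step_beta[j])
            tries["beta"] += 1
            if abs(prop[j]) > coef_bound:
                continue
            new = loglik(prop, state_ls2, state_tr, tree_idx)
            if np.log(rng.uniform()) < new - cur:
                state_beta, cur = prop, new
                acc["beta"] += 1
        # log sigma2 (uniform prior on log sigma2 over a wide bound)
        prop_ls2 = state_ls2 + rng.normal(0, step_ls2)
        tries["ls2"] += 1
        if -20.0 < prop_ls2 < 20.0:
            new = loglik(state_beta, prop_ls2, state_tr, tree_idx)
            if np.log(rng.uniform()) < new - cur:
                state_ls2, cur = prop_ls2, new
                acc["ls2"] += 1
        # transform parameters
        for k in free:
            lo, hi = TRANSFORM_BOUNDS[k]
            prop_tr = dict(state_tr)
            prop_tr[k] = state_tr[k] + rng.normal(0, step_tr[k])
            tries["tr"] += 1
            if not (lo <= prop_tr[k] <= hi):
                continue
            new = loglik(state_beta, state_ls2, prop_tr, tree_idx)
            if np.log(rng.uniform()) < new - cur:
                state_tr, cur = prop_tr, new
                acc["tr"] += 1
        # adapt proposals during burn-in only (keeps detailed balance after)
        if it < burnin and it % 200 == 199:
            for key, steps in (("beta", step_beta), ("ls2", None), ("tr", None)):
                rate = acc[key] / tries[key]
                factor = np.exp(np.clip(rate - 0.3, -0.5, 0.5))
                if key == "beta":
                    step_beta *= factor
                elif key == "ls2":
                    step_ls2 *= factor
                else:
                    for k in free:
                        step_tr[k] *= factor
            acc = {k: 0 for k in acc}
            tries = {k: 1e-12 for k in tries}
        if it >= burnin and (it - burnin) % thin == 0:
            rec = dict(zip(names, state_beta))
            rec["sigma2"] = float(np.exp(state_ls2))
            for k in free:
                rec[k] = state_tr[k]
            rec["tree_index"] = tree_idx
            rec["logL"] = cur
            records.append(rec)

    overall = {k: acc[k] / tries[k] for k in acc}
    for k, r in overall.items():
        if tries[k] > 1 and not (0.05 <= r <= 0.7):
            log.warning("PGLS MCMC acceptance rate for %s block is %.3f", k, r)
    return PosteriorSample(
        draws=pd.DataFrame(records),
        coef_names=names,
        settings=dict(
            iterations=iterations, thin=thin, burnin=burnin, seed=seed,
            transforms=list(free), n_trees=len(trees),
        ),
    )


def ornament_mass_threshold(fit) -> dict:
    """Predicted body mass (kg) of an ornamented taxon: exp(b0 + b_Orna).

    Interpreted as the minimum mass at which ornaments are expected; PGLS
    prediction is a coarse extrapolation, so a warning is logged alongside.
    """
    log.warning(
        "PGLS-based mass prediction is a generalization of the fitted model; "
        "treat the threshold as indicative, not exact."
    )
    if isinstance(fit, GLSFit):
        if "Orna" not in fit.coefficients or "intercept" not in fit.coefficients:
            raise ValueError("model must contain intercept and Orna terms")
        kg = float(np.exp(fit.coefficients["intercept"] + fit.coefficients["Orna"]))
        return {"kg": kg}
    if isinstance(fit, PosteriorSample):
        if "Orna" not in fit.draws.columns:
            raise ValueError("posterior lacks an Orna coefficient")
        vals = np.exp(fit.draws["intercept"] + fit.draws["Orna"])
        return {
            "kg": float(np.median(vals)),
            "lo2.5": float(np.quantile(vals, 0.025)),
            "hi97.5": float(np.quantile(vals, 0.975)),
        }
    raise TypeError("fit must be a GLSFit or PosteriorSample")


def bm_ancestral_estimate(tree: TimeTree, x, node) -> tuple[float, float]:
    """Brownian-motion ancestral estimate at an internal node.

    Equivalent to the re-rooted GLS estimate: the tree metric is re-rooted
    at the target node, and the node value is the GLS grand mean with
    variance ``sigma2_hat / (1' C_r^{-1} 1)``.  ``x`` maps taxa to trait
    values (dict or pandas Series).
    """
    if node.is_tip:
        raise ValueError("ancestral estimates are for internal nodes only")
    tips = tree.tips()
    labels = [t.label for t in tips]
    xv = np.array([x[lab] for lab in labels], dtype=float)
    depths = tree.depths()
    # path distance from `node` to each tip via unrooted metric
    C0 = phylo_vcv(tree).matrix
    d_tip = np.diag(C0)
    # distance(i,j) = d_i + d_j - 2 * C0[i,j]; distance(node, i) analogous
    # using depth(node) and depth(mrca(node, tip)).
    anc = []
    v = node
    while v is not None:
        anc.append(v)
        v = v.parent
    anc_ids = {id(a): a for a in anc}

    def mrca_depth_with_node(tip):
        v = tip
        while id(v) not in anc_ids:
            v = v.parent
        return depths[v]

    d_node = np.array([depths[node] + d_tip[i] - 2 * mrca_depth_with_node(t)
                       for i, t in enumerate(tips)])
    # re-rooted covariance: C_r[i,j] = (d(node,i) + d(node,j) - d(i,j)) / 2
    Dij = d_tip[:, None] + d_tip[None, :] - 2 * C0
    Cr = 0.5 * (d_node[:, None] + d_node[None, :] - Dij)
    np.fill_diagonal(Cr, d_node)
    cf = cho_factor(Cr, lower=True)
    ones = np.ones(len(tips))
    Ci1 = cho_solve(cf, ones)
    denom = float(ones @ Ci1)
    mean = float(xv @ Ci1) / denom
    r = xv - mean
    sigma2 = float(r @ cho_solve(cf, r)) / len(tips)
    return mean, sigma2 / denom
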