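"""Felsenstein's threshold model: liability MCMC for a binary x continuous pair.

The binary character (ornamentation) is the sign of an unobserved
"liability" evolving by Brownian motion on the tree jointly with the
observed continuous trait (log_e mass).  The 2x2 Brownian rate matrix is

    R = [[1,          r*sqrt(s2)],
         [r*sqrt(s2), s2        ]]

with the liability rate fixed to 1 and the threshold fixed at 0 (the
standard identifiability constraints).  The sampler alternates Gibbs
updates of tip liabilities (conditional normals truncated to the side of 0
matching the observed state) with Metropolis updates of r, s2 and the two
root means.  The prior on r is uniform on [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .trees import TimeTree, phylo_vcv

log = logging.getLogger(__name__)

__all__ = ["ThresholdPosterior", "threshbayes"]


def _rtruncnorm(rng, mean, sd, positive: bool) -> float:
    """One draw from N(mean, sd^2) truncated to (0, inf) or (-inf, 0].

    Inverse-CDF in the body of the distribution; Robert's exponential
    rejection sampler in the far tail where the CDF saturates.
    """
    if not positive:
        return -_rtruncnorm(rng, -mean, sd, True)
    a = -mean / sd  # standardized lower bound
    if a < 6.0:
        lo = ndtr(a)
        u = rng.uniform(lo, 1.0)
        u = min(u, 1.0 - 1e-16)
        return mean + sd * ndtri(u)
    # deep tail: exponential proposal with optimal rate
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        e = rng.exponential(1.0 / lam)
        z = a + e
        if rng.uniform() <= np.exp(-0.5 * (z - lam) ** 2):
            return mean + sd * z


@dataclass
class ThresholdPosterior:
    draws: pd.DataFrame        # r, sigma2_cont, mu_liab, mu_cont, logL
    liabilities: np.ndarray    # (n_draws, n_tips)
    taxa: list[str]
    settings: dict

    @property
    def logL_trace(self) -> np.ndarray:
        return self.draws["logL"].to_numpy()

    @property
    def mean_r(self) -> float:
        return float(self.draws["r"].mean())

    @property
    def mean_r2(self) -> float:
        return float((self.draws["r"] ** 2).mean())

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in ("r", "sigma2_cont", "mu_liab", "mu_cont"):
            x = self.draws[c].to_numpy()
            rows.append({
                "parameter": c,
                "mean": float(x.mean()),
                "median": float(np.median(x)),
                "lo2.5": float(np.quantile(x, 0.025)),
                "hi97.5": float(np.quantile(x, 0.975)),
            })
        return pd.DataFrame(rows).set_index("parameter")


def threshbayes(
    tree: TimeTree,
    binary,
    continuous,
    ngen: int = 1_020_000,
    thin: int = 1_000,
    burnin: int = 20_000,
    seed: int = 0,
) -> ThresholdPosterior:
    """Liability MCMC for the correlation between a binary and a continuous trait.

    ``binary``/``continuous`` map taxa to 0/1 states and trait values.  The
    default generation count follows the published run (1,020,000); pass a
    smaller ``ngen`` for desk-scale work.  Returns draws of r (the BM
    correlation), the continuous-trait rate, root means, tip liabilities,
    and the log-likelihood trace.
    """
    rng = np.random.default_rng(seed)
    taxa = tree.tip_labels
    n = len(taxa)
    gb = binary.get if hasattr(binary, "get") else binary.__getitem__
    gc = continuous.get if hasattr(continuous, "get") else continuous.__getitem__
    y = np.array([int(gb(t)) for t in taxa])
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("binary states must be 0/1")
    xv = np.array([float(gc(t)) for t in taxa])
    C = phylo_vcv(tree).matrix
    Ci = np.linalg.inv(C)
    sign, logdetC = np.linalg.slogdet(C)
    if sign <= 0:
        raise ValueError("tree covariance not positive definite")

    # state
    liab = np.where(y == 1, 0.5, -0.5).astype(float)
    r = 0.0
    s2 = float(np.var(xv)) / max(np.mean(np.diag(C)), 1e-12) + 1e-6
    mu_l = 0.0
    mu_x = float(np.mean(xv))

    def R_of(r, s2):
        c = r * np.sqrt(s2)
        return np.array([[1.0, c], [c, s2]])

    def loglik(liab, r, s2, mu_l, mu_x):
        R = R_of(r, s2)
        detR = np.linalg.det(R)
        if detR <= 1e-12:
            return -np.inf, None
        Ri = np.linalg.inv(R)
        Z = np.column_stack([liab - mu_l, xv - mu_x])
        S = Z.T @ (Ci @ Z)
        quad = float(np.sum(Ri * S.T))  # tr(Ri @ S)
        ll = -0.5 * (2 * n * np.log(2 * np.pi) + n * np.log(detR)
                     + 2 * logdetC + quad)
        return ll, Ri

    cur, Ri = loglik(liab, r, s2, mu_l, mu_x)
    Ciu = Ci @ (liab - mu_l)   # maintained incrementally
    Ciw = Ci @ (xv - mu_x)

    step_r, step_s2, step_mu = 0.15, 0.4, 0.3
    records = []
    liab_store = []
    acc = tries = 0
    for it in range(ngen):
        # --- Gibbs: tip liabilities from truncated conditionals ---
        for i in range(n):
            prec = Ri[0, 0] * Ci[i, i]
            s_i = Ri[0, 0] * Ciu[i] + Ri[0, 1] * Ciw[i]
            m = mu_l + (liab[i] - mu_l) - s_i / prec
            sd = 1.0 / np.sqrt(prec)
            new = _rtruncnorm(rng, m, sd, positive=bool(y[i] == 1))
            delta = new - liab[i]
            if delta != 0.0:
                liab[i] = new
                Ciu += Ci[:, i] * delta
        cur, Ri = loglik(liab, r, s2, mu_l, mu_x)
        # --- Metropolis: r, s2, root means ---
        rp = r + rng.normal(0, step_r)
        tries += 1
        if -1.0 < rp < 1.0:
            new, Rin = loglik(liab, rp, s2, mu_l, mu_x)
            if np.log(rng.uniform()) < new - cur:
                r, cur, Ri = rp, new, Rin
                acc += 1
        sp = s2 * float(np.exp(rng.normal(0, step_s2)))
        if 1e-8 < sp < 1e8:
            new, Rin = loglik(liab, r, sp, mu_l, mu_x)
            if np.log(rng.uniform()) < (new - cur) + np.log(sp / s2):
                s2, cur, Ri = sp, new, Rin
        mp = mu_l + rng.normal(0, step_mu)
        new, Rin = loglik(liab, r, s2, mp, mu_x)
        if np.log(rng.uniform()) < new - cur:
            mu_l, cur, Ri = mp, new, Rin
            Ciu = Ci @ (liab - mu_l)
        mp = mu_x + rng.normal(0, step_mu)
        new, Rin = loglik(liab, r, s2, mu_l, mp)
        if np.log(rng.uniform()) < new - cur:
            mu_x, cur, Ri = mp, new, Rin
            Ciw = Ci @ (xv - mu_x)
        if it >= burnin and (it - burnin) % thin == 0:
            bad = np.where(np.sign(liab) != np.where(y == 1, 1, -1))[0]
            if bad.size and not np.all(liab[bad] == 0):
                raise AssertionError("liability sign inconsistent with observed state")
            records.append(dict(r=r, sigma2_cont=s2, mu_liab=mu_l, mu_cont=mu_x,
                                logL=cur))
            liab_store.append(liab.copy())
    if acc / max(tries, 1) == 0:
        log.warning("threshold model: correlation updates never accepted")
    return ThresholdPosterior(
        draws=pd.DataFrame(records),
        liabilities=np.array(liab_store),
        taxa=taxa,
        settings=dict(ngen=ngen, thin=thin, burnin=burnin, seed=seed),
    )
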