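"""Generators for every input the pipeline consumes.

The stated world mirrors the empirical study's structure: a theropod-like
tree of 111 tips with fossil (extinct) taxa, a binary ornament character
evolving under a symmetric 2-state Markov process, and log_e body mass (kg)
evolving under regime-dependent OU with optima near 2.394 (unornamented)
and 7.241 (ornamented) log_e kg, a shared attraction of 0.131/Ma, and a
large unornamented rate (1.358) against a small ornamented one (0.313).
A PGLS-style generative mode draws regression residuals from a
lambda/kappa-transformed Brownian covariance around intercept 1.98 and
ornament slope 2.09.  Every generator is deterministic under its seed and
returns the generating truth for parameter-recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .discrete import QMatrix
from .pgls import CovBuilder, TraitTable, design_matrix
from .trees import Node, SimmapTree, TimeTree, TransformParams, write_newick

__all__ = [
    "SimConfig",
    "sim_bd_tree",
    "sim_mk",
    "sim_hansen",
    "sim_regression",
    "make_fixture",
    "femur_length_mass",
]


@dataclass
class SimConfig:
    """Generator truth; defaults are the study's printed estimates."""

    n_tips: int = 111
    birth: float = 0.1           # 1/Ma
    death: float = 0.05          # 1/Ma
    min_fossil_fraction: float = 0.2
    q_ornament: float = 0.012    # symmetric ornament gain/loss rate, 1/Ma
    alpha: float = 0.131         # 1/Ma
    sigma2_unorn: float = 1.358  # (log_e kg)^2/Ma
    sigma2_orn: float = 0.313
    theta_unorn: float = 2.394   # log_e kg
    theta_orn: float = 7.241
    intercept: float = 1.98      # regression mode
    slope: float = 2.09
    lam: float = 0.9
    kappa: float = 0.3
    resid_sigma2: float = 0.02   # BM residual rate, regression mode
    ornamented_range: tuple = (30, 46)
    seed: int = 0

    def __post_init__(self):
        if self.birth <= 0 or self.death < 0:
            raise ValueError("need birth > 0 and death >= 0")
        if not (0 <= self.min_fossil_fraction <= 1):
            raise ValueError("min_fossil_fraction must be in [0,1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def sim_bd_tree(
    n_tips: int = 111,
    birth: float = 0.1,
    death: float = 0.05,
    seed: int = 0,
    mode: str = "n_tips",
    max_time: float = 200.0,
    min_fossil_fraction: float = 0.0,
    max_retries: int = 1000,
) -> TimeTree:
    """Complete birth-death tree retaining extinct lineages as fossil tips.

    ``mode='n_tips'`` runs until the total tip count (extant + extinct)
    reaches ``n_tips`` and cuts the tree at that moment (extant lineages
    become age-0 tips); whole-clade extinction triggers a bounded retry.
    ``mode='fixed_time'`` runs to ``max_time`` unconditionally (used for
    checking the analytic expected tip count).
    """
    if birth <= 0:
        raise ValueError("birth rate must be > 0")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        root = Node()
        now = 0.0
        alive: list[tuple[Node, float]] = [(root, 0.0)]  # (node, birth time)
        dead: list[Node] = []
        total = 1
        label_n = 0
        failed = False
        while True:
            n_alive = len(alive)
            if n_alive == 0:
                failed = True
                break
            if mode == "n_tips" and total >= n_tips:
                break
            rate = n_alive * (birth + death)
            wait = rng.exponential(1.0 / rate)
            if mode == "fixed_time" and now + wait > max_time:
                now = max_time
                break
            now += wait
            if mode == "fixed_time" and now > max_time:  # pragma: no cover
                break
            i = int(rng.integers(n_alive))
            node, t0 = alive.pop(i)
            if rng.uniform() < birth / (birth + death):
                node.length = now - t0
                c1, c2 = Node(), Node()
                node.add_child(c1)
                node.add_child(c2)
                alive.append((c1, now))
                alive.append((c2, now))
                total += 1
            else:
                node.length = now - t0
                label_n += 1
                node.label = f"t{label_n}"
                dead.append(node)
        if failed and mode == "n_tips":
            continue
        if mode == "n_tips" and alive:
            # run the present a random way into the next inter-event gap so
            # freshly born lineages do not end as zero-length tips
            rate = len(alive) * (birth + death)
            now += rng.uniform() * rng.exponential(1.0 / rate)
        # close off extant lineages at `now`
        for node, t0 in alive:
            node.length = now - t0
            label_n += 1
            node.label = f"t{label_n}"
        if mode == "n_tips" and not alive:
            continue
        # the stem from the origin to the first split carries no tips; the
        # tree proper starts at the root bifurcation
        stem = root.length or 0.0
        root.length = None
        tree = TimeTree(root, root_age=now - stem)
        if tree.n_tips < 3:
            continue
        n_fossil = len(dead)
        if mode == "n_tips" and n_fossil / tree.n_tips < min_fossil_fraction:
            continue
        # root must be a bifurcation; if its only event was terminal, retry
        if len(tree.root.children) != 2 and mode == "n_tips":
            continue
        return tree
    raise RuntimeError(f"birth-death simulation failed after {max_retries} retries")


def sim_mk(tree: TimeTree, Q: QMatrix, root_state: int = 0, seed: int = 0):
    """Exact Gillespie simulation of a discrete character along the tree.

    Returns ``(tip_states, true_map)`` where the map records the full
    history for map-accuracy tests.
    """
    rng = np.random.default_rng(seed)
    Qm = Q.matrix
    k = Qm.shape[0]
    out = tree.copy()
    state_at: dict[int, int] = {id(out.root): int(root_state)}
    tip_states: dict[str, int] = {}
    for v in out.preorder():
        if v.parent is None:
            continue
        s = state_at[id(v.parent)]
        t, segs = v.length, []
        now = 0.0
        while True:
            rate = -Qm[s, s]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if now + wait >= t:
                segs.append((s, t - now))
                break
            segs.append((s, wait))
            now += wait
            p = np.clip(Qm[s].copy(), 0, None)
            p[s] = 0.0
            p /= p.sum()
            s = int(rng.choice(k, p=p))
        v.segments = segs
        state_at[id(v)] = s
        if v.is_tip:
            tip_states[v.label] = s
    smap = SimmapTree.__new__(SimmapTree)
    SimmapTree.__init__(smap, out.root, out.root_age)
    return tip_states, smap


def sim_hansen(
    smap: SimmapTree,
    alpha,
    sigma2,
    theta,
    root_value: float | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Exact per-segment OU sampling of tip values on a painted tree.

    ``alpha``/``sigma2``/``theta`` are dicts over regime states (scalars are
    broadcast).  ``alpha`` entries of 0 give the Brownian limit.  The root
    starts at ``root_value`` (default: the root regime's optimum).
    """
    rng = np.random.default_rng(seed)
    regimes = sorted({s for v in smap.postorder() if v.parent is not None
                      for s, _ in v.segments})

    def get(p, r):
        return float(p[r]) if isinstance(p, dict) else float(p)

    if root_value is None:
        root_value = get(theta, smap.root_state())
    vals: dict[int, float] = {id(smap.root): float(root_value)}
    tips: dict[str, float] = {}
    for v in smap.preorder():
        if v.parent is None:
            continue
        xcur = vals[id(v.parent)]
        for s, d in v.segments:
            a, s2, th = get(alpha, s), get(sigma2, s), get(theta, s)
            if a > 1e-12:
                e = np.exp(-a * d)
                mean = th + (xcur - th) * e
                var = s2 * (1.0 - e * e) / (2.0 * a)
            else:
                mean = xcur
                var = s2 * d
            xcur = mean + rng.normal() * np.sqrt(max(var, 0.0))
        vals[id(v)] = xcur
        if v.is_tip:
            tips[v.label] = xcur
    return tips


def sim_regression(
    tree: TimeTree,
    ornament: dict[str, int],
    intercept: float = 1.98,
    slope: float = 2.09,
    lam: float = 1.0,
    kappa: float = 1.0,
    resid_sigma2: float = 0.02,
    seed: int = 0,
) -> TraitTable:
    """PGLS-style generative mode: y = b0 + b1*Orna + MVN(0, s2 * C(lam, kappa)).

    ``resid_sigma2`` is the Brownian residual rate; set it to 0 for
    noise-free regime means.
    """
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    C = CovBuilder(tree).cov(TransformParams(lam=lam, kappa=kappa))
    orna = np.array([ornament[t] for t in labels], dtype=float)
    mu = intercept + slope * orna
    if resid_sigma2 > 0:
        L = np.linalg.cholesky(resid_sigma2 * C + 1e-12 * np.eye(len(labels)))
        y = mu + L @ rng.normal(size=len(labels))
    else:
        y = mu
    return TraitTable(pd.DataFrame(dict(
        taxon=labels, ornamented=orna.astype(int), log_mass=y, maniraptoriform=0,
    )))


def _closest_clade(tree: TimeTree, target: int):
    """Internal node whose descendant tip count is closest to ``target``
    without engulfing the whole tree."""
    best, best_node = None, None
    sizes: dict[int, int] = {}
    for v in tree.postorder():
        sizes[id(v)] = 1 if v.is_tip else sum(sizes[id(c)] for c in v.children)
    for v in tree.preorder():
        if v.is_tip or v is tree.root:
            continue
        gap = abs(sizes[id(v)] - target)
        if best is None or gap < best:
            best, best_node = gap, v
    return best_node


def make_fixture(config: SimConfig, outdir=None):
    """Generate the packaged study-structure analogue.

    111 fossil-bearing tips; ornamentation simulated under the symmetric Mk
    truth until the ornamented count falls in the configured band (matching
    the 38/111 empirical split); log_e mass from the two-optimum OU truth on
    the true ornament painting; a clade of roughly half the tips flagged as
    the maniraptoriform analogue.  Returns (tree, TraitTable, truth dict,
    true painting) and, when ``outdir`` is given, writes
    newick/traits.tsv/truth.tsv.
    """
    tree = sim_bd_tree(
        n_tips=config.n_tips, birth=config.birth, death=config.death,
        seed=config.seed, min_fossil_fraction=config.min_fossil_fraction,
    )
    Q = QMatrix.binary(config.q_ornament, config.q_ornament)
    lo, hi = config.ornamented_range
    states = smap = None
    for k in range(200):
        states_k, smap_k = sim_mk(tree, Q, root_state=0, seed=config.seed * 1009 + k)
        cnt = sum(states_k.values())
        if lo <= cnt <= hi:
            states, smap = states_k, smap_k
            break
    if states is None:
        raise RuntimeError("could not hit the ornamented-count band; adjust q_ornament")
    mass = sim_hansen(
        smap,
        alpha=config.alpha,
        sigma2={0: config.sigma2_unorn, 1: config.sigma2_orn},
        theta={0: config.theta_unorn, 1: config.theta_orn},
        root_value=config.theta_unorn,
        seed=config.seed + 7,
    )
    clade_node = _closest_clade(tree, target=config.n_tips // 2)
    clade_tips = {v.label for v in tree.preorder()
                  if v.is_tip and _is_descendant(v, clade_node)}
    labels = tree.tip_labels
    table = TraitTable(pd.DataFrame(dict(
        taxon=labels,
        ornamented=[states[t] for t in labels],
        log_mass=[mass[t] for t in labels],
        maniraptoriform=[int(t in clade_tips) for t in labels],
    )))
    clade_pair = sorted(clade_tips)[:2] if len(clade_tips) >= 2 else None
    truth = dict(
        **asdict(config),
        n_ornamented=int(sum(states.values())),
        n_fossil_tips=int(sum(1 for a in tree.tip_ages().values() if a > 1e-9)),
        maniraptoriform_size=len(clade_tips),
        maniraptoriform_pair=clade_pair,
        mean_log_mass=float(np.mean([mass[t] for t in labels])),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(write_newick(tree) + "\n")
        table.write_tsv(outdir / "traits.tsv")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in truth.items():
                fh.write(f"{k}\t{json.dumps(v)}\n")
    return tree, table, truth, smap


def _is_descendant(v: Node, anc: Node) -> bool:
    while v is not None:
        if v is anc:
            return True
        v = v.parent
    return False


def femur_length_mass(femur_length_mm, a: float, b: float) -> float:
    """Power-law femoral allometry: mass_kg = a * length^b.

    The coefficients are deliberately user-supplied configuration — the
    source allometry's constants are not published alongside this pipeline's
    inputs, so none are hard-coded here.
    """
    return a * np.asarray(femur_length_mm, dtype=float) ** b
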