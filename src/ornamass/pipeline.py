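"""End-to-end orchestration: from config to a structured results report.

Runs the full comparative analysis in the order the science dictates:
time-scaled tree (given or simulated) -> PGLS transform-model selection and
Bayesian regression -> threshold-model correlation -> discrete transition
rates (RJMCMC + ML) -> ancestral fossilization test -> stochastic maps ->
multi-regime OU model set.  All chain lengths default to the published
settings divided by ``scale_divisor`` so a desk run finishes in minutes;
every stage is seeded from the one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discrete, hansen, model_eval, pgls, simulate, threshold, trees

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "Report", "run_analysis"]

PAPER_CHAINS = {
    "pgls": dict(iterations=1_010_000, thin=1_000, burnin=10_000),
    "rj": dict(iterations=2_010_000, thin=1_000, burnin=100_000),
    "threshold": dict(ngen=1_020_000, thin=1_000, burnin=20_000),
    "dependent": dict(iterations=200_000, thin=100, burnin=20_000),
    "fossilize": dict(iterations=100_000, thin=100, burnin=10_000),
}


@dataclass
class RunConfig:
    tree_path: str | None = None
    traits_path: str | None = None
    synthetic: dict = field(default_factory=dict)  # SimConfig overrides
    scale_divisor: float = 1.0
    nmaps: int = 25
    hansen_models: tuple = hansen.MODELS
    seed: int = 1
    outdir: str | None = None

    def __post_init__(self):
        if self.scale_divisor < 1:
            raise ValueError("scale_divisor must be >= 1")
        for p in (self.tree_path, self.traits_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def chain(self, which: str) -> dict:
        base = PAPER_CHAINS[which]
        out = {}
        for k, v in base.items():
            if k in ("thin",):
                out[k] = max(1, int(v / self.scale_divisor))
            elif k in ("iterations", "ngen", "burnin"):
                out[k] = max(10, int(v / self.scale_divisor))
            else:
                out[k] = v
        if self.scale_divisor > 1:
            log.info("chain %s scaled by 1/%g: %s", which, self.scale_divisor, out)
        return out


@dataclass
class Report:
    sections: dict
    seed: int
    version: str

    def summary_text(self) -> str:
        out = [f"ornamass report (seed={self.seed}, version={self.version})", ""]
        for name, sec in self.sections.items():
            out.append(f"== {name} ==")
            if isinstance(sec, pd.DataFrame):
                out.append(sec.to_string())
            elif isinstance(sec, pd.Series):
                out.append(sec.to_string())
            else:
                out.append(json.dumps(sec, indent=2, default=_jsonable))
            out.append("")
        return "\n".join(out)

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.txt").write_text(self.summary_text())
        for name, sec in self.sections.items():
            if isinstance(sec, (pd.DataFrame, pd.Series)):
                sec.to_csv(outdir / f"{name}.tsv", sep="\t")
            else:
                (outdir / f"{name}.json").write_text(
                    json.dumps(sec, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (pd.Series, pd.DataFrame)):
        return x.to_dict()
    return str(x)


def run_analysis(config: RunConfig) -> Report:
    """Execute every stage and return the assembled report."""
    from . import __version__

    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31 - 1)) for k in
             ("sim", "pgls", "pglsnull", "thresh", "rj", "rjfixed", "dep",
              "foss", "maps", "hansen")}

    # ---- inputs -----------------------------------------------------------
    if config.tree_path and config.traits_path:
        tree = trees.parse_newick(Path(config.tree_path).read_text())
        table = pgls.TraitTable.read_tsv(config.traits_path)
        truth = None
    else:
        sim_cfg = simulate.SimConfig(**{"seed": seeds["sim"], **config.synthetic})
        tree, table, truth, _ = simulate.make_fixture(sim_cfg)
        log.info("simulated fixture: %d tips, %d ornamented",
                 tree.n_tips, truth["n_ornamented"])
    table = table.aligned_to(tree)
    states = dict(zip(table.table.taxon, table.table.ornamented.astype(int)))
    mass = dict(zip(table.table.taxon, table.table.log_mass))
    sections: dict = {}
    sections["data"] = dict(
        n_taxa=tree.n_tips,
        n_ornamented=int(table.table.ornamented.sum()),
        mean_log_mass=float(table.table.log_mass.mean()),
        n_giant=int(table.table.giant.sum()),
        root_age=tree.root_age,
    )
    if truth:
        sections["data"]["generator_truth"] = truth

    # ---- PGLS: ML transform-model selection -------------------------------
    subsets = [(), ("lam",), ("kappa",), ("delta",), ("lam", "kappa"),
               ("lam", "delta"), ("kappa", "delta"), ("lam", "kappa", "delta")]
    rows = []
    for sub in subsets:
        fit, score = pgls.pgls_ml(table, tree, formula=("intercept", "Orna"),
                                  transforms=sub)
        rows.append(dict(transforms="+".join(sub) or "none", K=score.K,
                         logL=fit.logL, aicc=score.aicc, r2=fit.r2,
                         **{f"b_{k}": v for k, v in fit.coefficients.items()}))
    ml_tab = pd.DataFrame(rows)
    scores = model_eval.information_scores(
        [(r["transforms"], r["logL"], r["K"]) for r in rows],
        n=tree.n_tips, corrected=True)
    ml_tab["weight"] = [s.weight for s in scores]
    sections["pgls_ml"] = ml_tab.sort_values("aicc").reset_index(drop=True)

    # ---- PGLS: Bayesian regression + Bayes factor vs zero slope -----------
    ch = config.chain("pgls")
    post = pgls.pgls_mcmc(table, tree, formula=("intercept", "Orna"),
                          transforms=("lam", "kappa"), seed=seeds["pgls"], **ch)
    null = pgls.pgls_mcmc(table, tree, formula=("intercept", "Orna"),
                          transforms=("lam", "kappa"), seed=seeds["pglsnull"],
                          fix_slope_zero=True, **ch)
    bf_slope = model_eval.bayes_factor(post.logL_trace, null.logL_trace)
    thr = pgls.ornament_mass_threshold(post)
    summ = post.summary()
    sections["pgls_bayes"] = summ
    sections["pgls_bayes_extras"] = dict(
        slope_median=float(summ.loc["Orna", "median"]),
        slope_prop_gt0=float(summ.loc["Orna", "prop_gt0"]),
        mass_threshold_kg=thr,
        bf_vs_zero_slope=bf_slope.bf,
        bf_verdict=bf_slope.verdict,
    )

    # ---- threshold model --------------------------------------------------
    ch = config.chain("threshold")
    tpost = threshold.threshbayes(tree, states, mass, seed=seeds["thresh"], **ch)
    sections["threshold"] = dict(mean_r=tpost.mean_r, mean_r2=tpost.mean_r2)

    # ---- discrete transition rates ---------------------------------------
    ch = config.chain("rj")
    rj = discrete.rjmcmc_binary(tree, states, seed=seeds["rj"], **ch)
    fixed = discrete.rjmcmc_binary(tree, states, seed=seeds["rjfixed"],
                                   fixed_model="ER", **ch)
    free = discrete.rjmcmc_binary(tree, states, seed=seeds["rjfixed"] + 1,
                                  fixed_model="ARD", **ch)
    bf_rates = model_eval.bayes_factor(free.logL_trace, fixed.logL_trace)
    fits, mk_scores = discrete.compare_mk_models(tree, states)
    sections["discrete_rates"] = dict(
        rj_model_frequencies=rj.model_frequencies().to_dict(),
        rj_q01_mean=float(rj.draws.q01.mean()),
        rj_q10_mean=float(rj.draws.q10.mean()),
        bf_ard_vs_er=bf_rates.bf,
        ml_table={s.name: dict(logL=s.logL, aicc=s.aicc, weight=s.weight)
                  for s in mk_scores},
    )

    # ---- dependent (giantism) model --------------------------------------
    giant = dict(zip(table.table.taxon, table.table.giant.astype(int)))
    ch = config.chain("dependent")
    dep = discrete.fit_dependent_discrete(tree, states, giant, mode="dependent",
                                          seed=seeds["dep"], **ch)
    sections["giantism_contrast"] = dict(
        gain_rate_ornamented=float(dep.draws.gainB_A1.mean()),
        gain_rate_unornamented=float(dep.draws.gainB_A0.mean()),
        contrast_mean=float(dep.draws.contrast.mean()),
        contrast_median=float(dep.draws.contrast.median()),
    )

    # ---- ancestral fossilization at the root ------------------------------
    ch = config.chain("fossilize")
    pair = (tree.tip_labels[0], tree.tip_labels[-1])
    bf_root = discrete.fossilize_bf(tree, states, pair, forced_state=0,
                                    seed=seeds["foss"], **ch)
    sections["ancestral_root"] = dict(
        bf_unornamented_root=bf_root.bf, verdict=bf_root.verdict)

    # ---- stochastic maps + Hansen models ----------------------------------
    maps = discrete.stochastic_maps(tree, states, model="ER",
                                    nmaps=config.nmaps, seed=seeds["maps"])
    sections["map_node_frequencies"] = discrete.node_state_frequencies(maps)
    avg = hansen.hansen_model_set(maps[: max(3, config.nmaps // 5)], mass,
                                  models=config.hansen_models,
                                  seed=seeds["hansen"])
    best_model = avg.mean_weights.index[0]
    sections["hansen"] = dict(
        mean_weights={f"{m}/{rm}": float(w) for (m, rm), w in avg.mean_weights.items()},
        theta_averaged=avg.theta_averaged,
        theta_dispersion=avg.theta_dispersion,
        theta_kg={str(r): float(np.exp(v)) for r, v in avg.theta_averaged.items()},
        n_excluded=int(len(avg.excluded)),
    )
    # half-life from a representative best-model fit
    best_fit = hansen.fit_hansen(maps[0], mass, model=best_model[0],
                                 root_mode=best_model[1], seed=seeds["hansen"])
    if best_fit.alpha is not None:
        a = (list(best_fit.alpha.values())[0] if isinstance(best_fit.alpha, dict)
             else best_fit.alpha)
        if a > 0:
            hl, frac = hansen.half_life(a, tree_depth=tree.root_age)
            sections["hansen"]["half_life_ma"] = float(hl)
            sections["hansen"]["half_life_fraction_of_tree"] = float(frac)

    report = Report(sections=sections, seed=config.seed, version=__version__)
    if config.outdir:
        report.write(config.outdir)
    return report
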