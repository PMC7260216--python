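"""End-to-end orchestration on synthetic data.

``run_pipeline`` reproduces the full analysis shape on simulated inputs:

1. simulate a tree set under a k-state birth-death process (states are
   trophic guilds),
2. estimate per-tip DR rates and pool medians across the set,
3. attach a synthetic trait table (guilds from the simulated tip states)
   and run the boosting protocol on the per-tree DR rates,
4. fit MuSSE per tree (ML then MCMC) and pool posterior summaries,
5. reconstruct ancestral states, draw stochastic maps, and average the
   directed transition counts into a chord table.

Each stage writes its outputs to disk, is independently re-runnable from
the previous stage's files, and draws its randomness from a child seed
derived from the master seed and the stage name, so a configuration and
seed fully determine every output byte.  Because the simulated trees are
independent (not alternative imputations of one backbone), the boosting
table stacks per-tree rows — each species row keeps the guild and DR rate
of its own tree — while the median-pooled DR table is emitted alongside
for the across-tree view.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boostrates, charmap, io, tipdr, treesim
from . import sse as sse_mod
from .states import SSEParams, ValidationError
from .treesim import GUILDS

__all__ = ["RunConfig", "TreeSimConfig", "SSEConfig", "CharmapConfig",
           "BoostConfig", "run_pipeline", "smoke_config"]

log = logging.getLogger(__name__)


@dataclass
class TreeSimConfig:
    k: int = 2
    lam: tuple = (0.1, 0.2)
    mu: tuple = (0.03, 0.03)
    q: float = 0.03
    root_state: int = 1
    n_trees: int = 10
    n_extant: int = 200
    start: str = "crown"
    state_labels: tuple = ("GC", "HD")

    def params(self) -> SSEParams:
        return SSEParams.from_rates(list(self.lam), list(self.mu), self.q)

    def __post_init__(self):
        if len(self.state_labels) != self.k:
            raise ValidationError("state_labels must have one label per state")
        bad = set(self.state_labels) - set(GUILDS)
        if bad:
            raise ValidationError(f"state labels must be guild codes: {bad}")


@dataclass
class SSEConfig:
    root_mode: str = "fitzjohn"
    condition_survival: bool = True
    prior_rate: float | None = None     # None: 1/(2 * tree-wide Yule rate)
    n_gen: int = 2000
    n_prelim: int = 100
    burnin_frac: float = 0.10
    run_mcmc: bool = True

    def options(self) -> sse_mod.LikelihoodOptions:
        return sse_mod.LikelihoodOptions(root_mode=self.root_mode,
                                         condition_survival=self.condition_survival)


@dataclass
class CharmapConfig:
    n_maps: int = 10
    method: str = "marginal"


@dataclass
class BoostConfig:
    grid: dict = field(default_factory=lambda: {
        "learning_rate": [0.05, 0.1],
        "max_depth": [3, 5],
        "gamma": [0.0, 1.0],
        "subsample": [0.8],
    })
    stage2_draws: int = 20
    n_boot: int = 100
    cv_reps: int = 100
    num_boost_round: int = 60
    size_grid: int = 40

    def spec(self, seed: int) -> boostrates.BoostSpec:
        return boostrates.BoostSpec(grid=dict(self.grid),
                                    stage2_draws=self.stage2_draws,
                                    n_boot=self.n_boot, cv_reps=self.cv_reps,
                                    num_boost_round=self.num_boost_round,
                                    seed=seed)


@dataclass
class RunConfig:
    seed: int = 0
    treesim: TreeSimConfig = field(default_factory=TreeSimConfig)
    sse: SSEConfig = field(default_factory=SSEConfig)
    charmap: CharmapConfig = field(default_factory=CharmapConfig)
    boost: BoostConfig = field(default_factory=BoostConfig)
    noise_shape: float = 10.0           # trait-table rate noise (unused columns)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for key, sub in (("treesim", TreeSimConfig), ("sse", SSEConfig),
                         ("charmap", CharmapConfig), ("boost", BoostConfig)):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**kw[key])
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)


def smoke_config(seed: int = 0) -> RunConfig:
    """A minutes-scale configuration exercising every stage."""
    return RunConfig(
        seed=seed,
        treesim=TreeSimConfig(n_trees=2, n_extant=60),
        sse=SSEConfig(n_gen=60, n_prelim=20),
        charmap=CharmapConfig(n_maps=3),
        boost=BoostConfig(grid={"learning_rate": [0.1], "max_depth": [3],
                                "gamma": [0.5], "subsample": [0.8]},
                          stage2_draws=3, n_boot=15, cv_reps=10,
                          num_boost_round=30, size_grid=15),
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns the run manifest (also written to
    ``manifest.json``).  Identical config + seed reproduce every output
    file bit-for-bit (the manifest's timing section aside)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "hashes": {},
                      "warnings": []}
    cs = config.treesim
    params = cs.params()
    label_of = {i + 1: cs.state_labels[i] for i in range(cs.k)}

    def stage(name):
        t0 = time.time()

        def done(files):
            manifest["stages"][name] = round(time.time() - t0, 3)
            for f in files:
                manifest["hashes"][Path(f).name] = io.file_sha256(f)
        return done

    # ------------------------------------------------------------ simulate
    done = stage("simulate")
    outcomes = treesim.simulate_tree_set(
        params, cs.root_state, n_trees=cs.n_trees, n_extant=cs.n_extant,
        seed=io.derive_seed(config.seed, "treesim"), start=cs.start)
    files = []
    for i, o in enumerate(outcomes):
        io.write_newick(o.tree, out / f"tree_{i}.nwk")
        io.write_tip_states(o.states, out / f"states_{i}.tsv")
        files += [out / f"tree_{i}.nwk", out / f"states_{i}.tsv"]
        if o.history_tree is not None:
            io.write_history_newick(o.history_tree, o.true_history,
                                    out / f"history_{i}.nwk")
            files.append(out / f"history_{i}.nwk")
    io.write_params(params, out / "true_params.json")
    done(files + [out / "true_params.json"])

    # ------------------------------------------------------------------ DR
    done = stage("tipdr")
    rate_maps = [tipdr.dr_statistic(o.tree) for o in outcomes]
    rates = tipdr.pool_median(rate_maps)
    tipdr.write_rates(rates, out / "dr_rates.tsv")
    done([out / "dr_rates.tsv"])

    # --------------------------------------------------------------- boost
    done = stage("boost")
    tables = []
    for i, o in enumerate(outcomes):
        guilds = {f"t{i}_{lbl}": label_of[o.states.observed(lbl)]
                  for lbl in o.tree.tip_labels}
        gen = treesim.TraitGenSpec(
            n_species=len(guilds), noise_shape=config.noise_shape,
            seed=io.derive_seed(config.seed, "traits", i))
        tab, _ = treesim.simulate_trait_table(gen, guilds=guilds)
        tab["dr_rate"] = [rate_maps[i][lbl.split("_", 1)[1]] for lbl in tab.index]
        tables.append(tab)
    model_table = pd.concat(tables)
    io.write_trait_table(model_table, out / "model_table.tsv")
    response = model_table.pop("dr_rate")
    bspec = config.boost.spec(io.derive_seed(config.seed, "boost"))
    hp = boostrates.tune_two_step(model_table, response, bspec)
    cv = boostrates.fit_and_validate(model_table, response, hp, bspec)
    models = boostrates.bootstrap_models(
        model_table, response, hp, bspec.n_boot,
        seed=io.derive_seed(config.seed, "boost", "bootstrap"))
    imp = boostrates.bootstrap_importance(models)
    imp.to_csv(out / "importance.tsv", sep="\t")
    prof = boostrates.predict_profiles(models, model_table,
                                       size_grid=config.boost.size_grid)
    prof.summary().to_csv(out / "profiles.tsv", sep="\t", index=False)
    eff = boostrates.size_class_effects(prof)
    eff.to_csv(out / "effects.tsv", sep="\t", index=False)
    io.write_json({"hyperparameters": {k: v for k, v in hp.items() if k != "stage1"},
                   "accuracy_bias": cv["accuracy_bias"],
                   "accuracy_bias_pct": cv["accuracy_bias_pct"],
                   "precision_r2": cv["precision_r2"],
                   "n_reps": cv["n_reps"]}, out / "cv_report.json")
    done([out / "model_table.tsv", out / "importance.tsv", out / "profiles.tsv",
          out / "effects.tsv", out / "cv_report.json"])

    # ----------------------------------------------------------------- SSE
    done = stage("sse")
    opts = config.sse.options()
    fits = []
    draw_sets = []
    for i, o in enumerate(outcomes):
        fit = sse_mod.musse_ml(o.tree, o.states, options=opts,
                               seed=io.derive_seed(config.seed, "sse-ml", i))
        fits.append(fit)
        io.write_json(fit.to_dict(), out / f"fit_{i}.json")
        if config.sse.run_mcmc:
            draws = sse_mod.musse_mcmc(
                o.tree, o.states, fit, options=opts,
                prior_rate=config.sse.prior_rate,
                n_gen=config.sse.n_gen, n_prelim=config.sse.n_prelim,
                burnin_frac=config.sse.burnin_frac,
                seed=io.derive_seed(config.seed, "sse-mcmc", i),
                tree_id=f"tree_{i}")
            draw_sets.append(draws)
            draws.draws.assign(tree_id=f"tree_{i}").to_csv(
                out / f"draws_{i}.tsv", sep="\t")
    files = [out / f"fit_{i}.json" for i in range(len(outcomes))]
    if draw_sets:
        summary = sse_mod.pool_and_summarize(draw_sets)
        summary.to_csv(out / "sse_summary.tsv", sep="\t")
        files += [out / f"draws_{i}.tsv" for i in range(len(outcomes))]
        files.append(out / "sse_summary.tsv")
        ess_min = min(ds.ess().min() for ds in draw_sets)
        if ess_min < 200:
            manifest["warnings"].append(
                f"minimum posterior ESS {ess_min:.0f} < 200")
    done(files)

    # ------------------------------------------------------------- charmap
    done = stage("charmap")
    all_histories = []
    files = []
    for i, o in enumerate(outcomes):
        marg = charmap.marginal_asr(o.tree, o.states, fits[i].params, opts)
        marg.to_frame().to_csv(out / f"asr_{i}.tsv", sep="\t")
        files.append(out / f"asr_{i}.tsv")
        hists = charmap.sample_histories(
            o.tree, fits[i].params, marg, config.charmap.n_maps,
            seed=io.derive_seed(config.seed, "simmap", i),
            states=o.states, method=config.charmap.method)
        for j, h in enumerate(hists[:2]):       # keep a couple per tree
            io.write_history_newick(o.tree, h, out / f"map_{i}_{j}.nwk")
            files.append(out / f"map_{i}_{j}.nwk")
        all_histories.extend(hists)
    counts = charmap.count_transitions(all_histories, n_trees=len(outcomes))
    chord = charmap.chord_table(counts, list(cs.state_labels))
    chord.to_csv(out / "transitions.tsv", sep="\t", index=False)
    note = (f"mean transition counts averaged over {len(outcomes)} trees x "
            f"{config.charmap.n_maps} maps")
    io.write_json({"note": note, "n_trees": len(outcomes),
                   "n_maps": config.charmap.n_maps,
                   "matrix": counts.matrix}, out / "transitions_meta.json")
    done(files + [out / "transitions.tsv", out / "transitions_meta.json"])

    io.write_json(manifest, out / "manifest.json")
    return manifest
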