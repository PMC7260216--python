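"""Canonical simulation studies validating the inference machinery.

Each function runs a self-contained study at a declared desk-scale size
(documented defaults; see the methods note for why these sizes), returns
a plain dict of measured quantities, and takes every bit of randomness
from its ``seed`` argument.  The test suite asserts on these quantities
at the tolerances stated there; the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from . import boostrates, charmap, tipdr, treesim
from .io import derive_seed
from .pipeline import (BoostConfig, CharmapConfig, RunConfig, SSEConfig,
                       TreeSimConfig, run_pipeline)
from .states import SSEParams
from .sse import (LikelihoodOptions, SSEParamSpace, kde_mode, musse_mcmc,
                  musse_ml, pool_rate_draws)

__all__ = [
    "ml_rank_recovery", "mcmc_coverage", "branch_event_rate",
    "simmap_recovery", "planted_importance", "null_signal_r2",
    "noiseless_signal_r2", "discrimination_study",
]

# the two-state recovery regime: slow vs fast speciation, equal extinction,
# rare symmetric transitions
_RECOVERY = SSEParams.from_rates([0.1, 0.2], [0.03, 0.03], 0.01)


def ml_rank_recovery(n_reps: int = 20, n_tips: int = 500, seed: int = 0) -> dict:
    """Does ML recover lam2 > lam1 under the two-state recovery regime?"""
    correct = 0
    for r in range(n_reps):
        o = treesim.simulate_mbd_tree(_RECOVERY, 1, n_extant=n_tips,
                                      seed=derive_seed(seed, "mlrank", r))
        fit = musse_ml(o.tree, o.states)
        correct += int(fit.params.lam[1] > fit.params.lam[0])
    return {"prop_rank_correct": correct / n_reps, "n_reps": n_reps,
            "n_tips": n_tips}


def mcmc_coverage(n_reps: int = 20, n_tips: int = 100, n_gen: int = 400,
                  n_prelim: int = 50, seed: int = 0, level: float = 0.95) -> dict:
    """Credible-interval calibration: fraction of replicates whose
    ``level`` interval covers the true speciation rates."""
    a = (1.0 - level) / 2.0
    covered = 0
    total = 0
    for r in range(n_reps):
        o = treesim.simulate_mbd_tree(_RECOVERY, 1, n_extant=n_tips,
                                      seed=derive_seed(seed, "cover", r))
        fit = musse_ml(o.tree, o.states)
        draws = musse_mcmc(o.tree, o.states, fit, n_gen=n_gen,
                           n_prelim=n_prelim,
                           seed=derive_seed(seed, "cover-mcmc", r))
        rd = draws.rate_draws()
        for i, true in enumerate(_RECOVERY.lam, start=1):
            lo, hi = np.quantile(rd[f"lam{i}"], [a, 1.0 - a])
            covered += int(lo <= true <= hi)
            total += 1
    return {"coverage": covered / total, "n_intervals": total,
            "n_reps": n_reps, "n_tips": n_tips, "n_gen": n_gen}


def branch_event_rate(n_maps: int = 10_000, q: float = 0.5, t: float = 1.0,
                      seed: int = 0) -> dict:
    """Unconditional CTMC identity on a single branch: with endpoints drawn
    from the equilibrium joint, the mean 1->2 event count equals
    ``pi_1 * q12 * t``."""
    Q = np.array([[-q, q], [q, -q]])
    P = expm(Q * t)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_maps)
    for m in range(n_maps):
        a = int(rng.integers(2))                    # equilibrium pi = (.5, .5)
        b = int(rng.choice(2, p=P[a]))
        segs = charmap._sample_endpoint_path(a, b, t, Q, float(P[a, b]), rng)
        counts[m] = sum(1 for (s1, _), (s2, _) in zip(segs, segs[1:])
                        if s1 == 0 and s2 == 1)
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(n_maps))
    expected = 0.5 * q * t
    return {"mean_count": mean, "expected": expected, "se": se,
            "z": (mean - expected) / se, "n_maps": n_maps}


def simmap_recovery(n_trees: int = 20, n_tips: int = 500, n_maps: int = 10,
                    seed: int = 0) -> dict:
    """End-to-end mapping check: stochastic maps drawn under the TRUE
    generating parameters should recover the simulator's recorded
    transition counts.  Equal-rates two-state regime with moderate
    transitions so counts are well away from zero."""
    params = SSEParams.from_rates([0.15, 0.15], [0.03, 0.03], 0.03)
    true_total = np.zeros((2, 2))
    mapped_total = np.zeros((2, 2))
    for r in range(n_trees):
        o = treesim.simulate_mbd_tree(params, 1, n_extant=n_tips,
                                      seed=derive_seed(seed, "simmap", r))
        marg = charmap.marginal_asr(o.tree, o.states, params)
        hists = charmap.sample_histories(o.tree, params, marg, n_maps,
                                         seed=derive_seed(seed, "simmap-h", r))
        mapped_total += charmap.count_transitions(hists).matrix
        true_total += o.true_transitions
    rel = {}
    for i, j in ((0, 1), (1, 0)):
        rel[f"rel_err_{i + 1}to{j + 1}"] = float(
            (mapped_total[i, j] - true_total[i, j]) / true_total[i, j])
    return {**rel,
            "max_abs_rel_err": max(abs(v) for v in rel.values()),
            "true_counts": true_total.tolist(),
            "mapped_counts": mapped_total.tolist(),
            "n_trees": n_trees, "n_maps": n_maps}


# ---------------------------------------------------------------- boosting

def _boost_spec(seed, **kw) -> boostrates.BoostSpec:
    base = dict(grid={"learning_rate": [0.1], "max_depth": [4],
                      "gamma": [0.5], "subsample": [0.8]},
                stage2_draws=5, n_boot=200, cv_reps=50,
                num_boost_round=80, seed=seed)
    base.update(kw)
    return boostrates.BoostSpec(**base)


def planted_importance(n: int = 2000, n_boot: int = 200, seed: int = 0) -> dict:
    """One informative predictor (body size, via a power-law rate) among
    nine noise predictors: the informative one should rank first and beat
    the 100/p % chance line in essentially every bootstrap."""
    gen = treesim.TraitGenSpec(
        n_species=n, noise_shape=25.0,
        rate_fn=lambda guild, size: 0.05 * (size / 25.0) ** 0.7,
        seed=derive_seed(seed, "planted"))
    table, rates = treesim.simulate_trait_table(gen)
    hp = {"learning_rate": 0.1, "max_depth": 4, "gamma": 0.5,
          "subsample": 0.8, "num_boost_round": 80}
    models = boostrates.bootstrap_models(table, rates, hp, n_boot,
                                         seed=derive_seed(seed, "planted-boot"))
    imp = boostrates.bootstrap_importance(models)
    raw = imp.attrs["raw"]                  # (n_boot, p) frame, imp.index order
    p = raw.shape[1]
    first = (raw.to_numpy().argmax(axis=1) == list(raw.columns).index("size")).mean()
    above = (raw["size"] > 100.0 / p).mean()
    return {"prop_rank_first": float(first),
            "prop_above_chance": float(above),
            "mean_importance": float(imp.loc["size", "mean"]),
            "chance": 100.0 / p, "n_boot": n_boot, "n": n}


def null_signal_r2(n: int = 1500, cv_reps: int = 50, seed: int = 0) -> dict:
    """Pure gamma noise response: cross-validated R^2 should sit at zero."""
    gen = treesim.TraitGenSpec(n_species=n, noise_shape=5.0,
                               rate_fn=treesim.constant_rate(0.1),
                               seed=derive_seed(seed, "null"))
    table, rates = treesim.simulate_trait_table(gen)
    spec = _boost_spec(derive_seed(seed, "null-spec"), cv_reps=cv_reps)
    hp = {"learning_rate": 0.1, "max_depth": 4, "gamma": 0.5,
          "subsample": 0.8, "num_boost_round": 60}
    cv = boostrates.fit_and_validate(table, rates, hp, spec)
    return {"mean_r2": cv["precision_r2"], "mean_bias": cv["accuracy_bias"],
            "cv_reps": cv["n_reps"], "n": n}


def noiseless_signal_r2(n: int = 1500, cv_reps: int = 30, seed: int = 0) -> dict:
    """Response exactly a function of one feature: near-perfect recovery."""
    gen = treesim.TraitGenSpec(
        n_species=n, noise_shape=1e6,
        rate_fn=lambda guild, size: 0.05 * (size / 25.0) ** 0.7,
        seed=derive_seed(seed, "clean"))
    table, rates = treesim.simulate_trait_table(gen)
    spec = _boost_spec(derive_seed(seed, "clean-spec"), cv_reps=cv_reps)
    hp = {"learning_rate": 0.1, "max_depth": 4, "gamma": 0.0,
          "subsample": 1.0, "num_boost_round": 200}
    cv = boostrates.fit_and_validate(table, rates, hp, spec)
    return {"mean_r2": cv["precision_r2"], "mean_bias": cv["accuracy_bias"],
            "cv_reps": cv["n_reps"], "n": n}


# ----------------------------------------------------------- discrimination

def discrimination_study(seed: int = 0, n_trees: int = 10, n_tips: int = 200,
                         n_gen: int = 400, outdir=None) -> dict:
    """Qualitative reproduction of the headline structure on synthetic
    data: herbivore/detritivore-state lineages speciate twice as fast as
    generalized-carnivore-state lineages; the pooled posterior should
    separate the net diversification rates and the boosting stage should
    rank trophic identity above chance."""
    import tempfile

    cfg = RunConfig(
        seed=seed,
        treesim=TreeSimConfig(k=2, lam=(0.1, 0.2), mu=(0.03, 0.03), q=0.03,
                              n_trees=n_trees, n_extant=n_tips,
                              state_labels=("GC", "HD")),
        sse=SSEConfig(n_gen=n_gen, n_prelim=50),
        charmap=CharmapConfig(n_maps=10),
        boost=BoostConfig(grid={"learning_rate": [0.1], "max_depth": [4],
                                "gamma": [0.5], "subsample": [0.8]},
                          stage2_draws=5, n_boot=100, cv_reps=50,
                          num_boost_round=60),
    )
    if outdir is None:
        with tempfile.TemporaryDirectory() as td:
            run_pipeline(cfg, td)
            return _discrimination_metrics(td)
    run_pipeline(cfg, outdir)
    return _discrimination_metrics(outdir)


def _discrimination_metrics(outdir) -> dict:
    from pathlib import Path

    import pandas as pd

    out = Path(outdir)
    draws = []
    space = SSEParamSpace(2)
    for p in sorted(out.glob("draws_*.tsv")):
        df = pd.read_csv(p, sep="\t", index_col=0)
        from .sse import PosteriorDraws
        draws.append(PosteriorDraws(
            draws=df[space.free_names], space=space, burnin_frac=0.10,
            tree_id=p.stem))
    pooled = pool_rate_draws(draws)
    r_gc, r_hd = pooled["r1"].to_numpy(), pooled["r2"].to_numpy()
    gc_lo, gc_hi = np.quantile(r_gc, [0.25, 0.75])
    hd_lo, hd_hi = np.quantile(r_hd, [0.25, 0.75])
    imp = pd.read_csv(out / "importance.tsv", sep="\t", index_col=0)
    return {
        "r_gc_mode": kde_mode(r_gc), "r_hd_mode": kde_mode(r_hd),
        "r_gc_ci50": [float(gc_lo), float(gc_hi)],
        "r_hd_ci50": [float(hd_lo), float(hd_hi)],
        "ci50_disjoint": bool(hd_lo > gc_hi),
        "trophic_importance": float(imp.loc["trophic", "mean"]),
        "trophic_rank": int(list(imp.index).index("trophic")) + 1,
        "chance": float(imp["chance"].iloc[0]),
        "n_pooled_draws": int(len(pooled)),
    }
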