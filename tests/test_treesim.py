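"""Tests of the multi-state birth-death simulator and trait generator."""

import numpy as np
import pytest

from troposse.states import SSEParams, ValidationError
from troposse.treesim import (CladeExtinctError, TraitGenSpec, constant_rate,
                              guild_size_rate, simulate_mbd_tree,
                              simulate_trait_table, simulate_tree_set)


def pure_birth(lam=0.1):
    return SSEParams.from_rates([lam], 0.0, np.zeros((1, 1)))


class TestSimulateTree:
    def test_pure_birth_hits_requested_tips(self):
        o = simulate_mbd_tree(pure_birth(), 1, n_extant=50, seed=1)
        assert o.tree.n_tips == 50
        assert o.n_surviving == 50
        assert o.true_transitions.sum() == 0
        # no death: pruned and unpruned trees are identical
        assert o.tree.to_newick() == o.history_tree.to_newick()

    def test_mean_survivors_matches_linear_birth_death(self):
        # closed-form oracle: E[N(t)] = exp((lam - mu) t) from one lineage
        lam, mu, T = 0.2, 0.1, 10.0
        p = SSEParams.from_rates([lam], [mu], np.zeros((1, 1)))
        n = [simulate_mbd_tree(p, 1, max_time=T, seed=s, start="stem").n_surviving
             for s in range(1500)]
        target = np.exp((lam - mu) * T)
        se = np.std(n) / np.sqrt(len(n))
        assert abs(np.mean(n) - target) < 3 * se

    def test_state_frequencies_reach_equilibrium(self):
        # symmetric transitions, state-independent rates -> (0.5, 0.5)
        p = SSEParams.from_rates([0.1, 0.1], [0.1, 0.1], 0.05)
        freqs = []
        for s in range(250):
            o = simulate_mbd_tree(p, 1, max_time=50.0, seed=s)
            if o.states is not None and len(o.states) >= 2:
                c = o.states.counts()
                freqs.append(c / c.sum())
        f = np.mean(freqs, axis=0)
        se = np.std([x[0] for x in freqs]) / np.sqrt(len(freqs))
        assert abs(f[0] - 0.5) < 3 * se

    def test_history_invariants(self):
        p = SSEParams.from_rates([0.12, 0.2], [0.04, 0.04], 0.05)
        o = simulate_mbd_tree(p, 1, n_extant=120, seed=9)
        o.true_history.validate(o.history_tree)
        # total segment duration equals total unpruned tree length
        seg_total = sum(d for segs in o.true_history.segments for _, d in segs)
        assert seg_total == pytest.approx(
            o.history_tree.total_length(include_stem=True), abs=1e-6)
        # recorded counts equal a re-scan of the emitted history
        assert np.array_equal(o.true_transitions,
                              o.true_history.transition_counts())
        assert np.all(np.diag(o.true_transitions) == 0)
        assert o.tree.is_ultrametric(1e-6)

    def test_validation_errors(self):
        with pytest.raises(ValidationError):
            simulate_mbd_tree(pure_birth(), 1, seed=0)       # no stop rule
        with pytest.raises(ValidationError):
            simulate_mbd_tree(pure_birth(), 2, n_extant=10)  # bad root state
        with pytest.raises(ValidationError):
            SSEParams.from_rates([-0.1], 0.0, np.zeros((1, 1)))

    def test_certain_extinction_raises_with_retry_count(self):
        p = SSEParams.from_rates([0.01], [5.0], np.zeros((1, 1)))
        with pytest.raises(CladeExtinctError) as err:
            simulate_mbd_tree(p, 1, n_extant=50, seed=3, max_retries=5)
        assert err.value.retries == 5


class TestTreeSet:
    def test_counts_and_determinism(self):
        sets = [simulate_tree_set(pure_birth(), 1, n_trees=5, n_extant=20, seed=7)
                for _ in range(2)]
        for out in sets:
            assert len(out) == 5
            assert all(o.tree.n_tips == 20 for o in out)
        nwk = [[o.tree.to_newick() for o in s] for s in sets]
        assert nwk[0] == nwk[1]                   # same master seed: identical
        # derived seeds differ: topologies differ with overwhelming probability
        assert nwk[0][0] != nwk[0][1]


class TestTraitTable:
    def test_degenerate_noise_recovers_constant_rate(self):
        spec = TraitGenSpec(n_species=300, rate_fn=constant_rate(0.1),
                            noise_shape=1e6, seed=0)
        _, rates = simulate_trait_table(spec)
        assert np.all(np.abs(rates / 0.1 - 1.0) < 0.01)

    def test_degenerate_guild_probs(self):
        spec = TraitGenSpec(n_species=50, guild_probs=(0, 0, 0, 0, 0, 1), seed=1)
        table, _ = simulate_trait_table(spec)
        assert (table["trophic"] == "HD").all()

    def test_guild_rate_ratio_recovered(self):
        base = {g: 0.05 for g in ("GC", "MI", "OM", "PK", "SI")}
        base["HD"] = 0.10
        spec = TraitGenSpec(n_species=5000, rate_fn=guild_size_rate(base),
                            noise_shape=10.0, seed=2)
        table, rates = simulate_trait_table(spec)
        ratio = (rates[table["trophic"] == "HD"].mean()
                 / rates[table["trophic"] == "GC"].mean())
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_schema_and_reproducibility(self):
        spec = TraitGenSpec(n_species=40, seed=5)
        t1, r1 = simulate_trait_table(spec)
        t2, r2 = simulate_trait_table(spec)
        assert t1.equals(t2) and r1.equals(r2)
        assert list(t1.columns) == ["trophic", "size", "activity", "position",
                                    "range", "basin", "abs_lat", "dist_iaa",
                                    "sst", "prprod"]
        assert (t1["size"] > 0).all() and (t1["range"] >= 1).all()

    def test_nonpositive_rate_fn_rejected(self):
        spec = TraitGenSpec(n_species=10, rate_fn=lambda g, s: 0.0, seed=0)
        with pytest.raises(ValidationError):
            simulate_trait_table(spec)

    def test_guild_override(self):
        spec = TraitGenSpec(n_species=3, seed=0)
        table, _ = simulate_trait_table(spec, guilds={"x": "HD", "y": "GC"})
        assert list(table.index) == ["x", "y"]
        assert list(table["trophic"]) == ["HD", "GC"]
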