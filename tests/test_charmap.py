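"""Ancestral states, stochastic maps and transition counting."""

import numpy as np
import pytest
from scipy.linalg import expm

from oracles import brute_clamped_marginals
from troposse.states import CharacterHistory, SSEParams, TipStateMap, ValidationError
from troposse.charmap import (NodeMarginals, chord_table, count_transitions,
                              marginal_asr, sample_histories)
from troposse.sse import LikelihoodOptions
from troposse.treesim import simulate_mbd_tree
from troposse.trees import PhyloTree


class TestMarginalASR:
    @pytest.mark.parametrize("root_mode,cond", [("fitzjohn", True),
                                                ("fitzjohn", False),
                                                ("flat", False)])
    def test_matches_brute_force_clamping(self, five_tip, states5, params2,
                                          root_mode, cond):
        opts = LikelihoodOptions(root_mode=root_mode, condition_survival=cond)
        marg = marginal_asr(five_tip, states5, params2, opts)
        brute = brute_clamped_marginals(five_tip, states5, params2, opts)
        assert np.abs(marg.probs - brute).max() < 1e-6

    def test_symmetric_case_gives_even_root(self, quartet):
        p = SSEParams.from_rates([0.1, 0.1], [0.05, 0.05], 0.1)
        st = TipStateMap({"A": 1, "B": 2, "C": 2, "D": 1}, 2)
        marg = marginal_asr(quartet, st, p)
        assert marg.probs[quartet.root] == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_no_transitions_pins_all_nodes(self, quartet):
        p = SSEParams.from_rates([0.1, 0.1], [0.0, 0.0], 1e-9)
        st = TipStateMap({t: 1 for t in "ABCD"}, 2)
        marg = marginal_asr(quartet, st, p)
        assert np.allclose(marg.probs[:, 0], 1.0, atol=1e-6)

    def test_observed_tips_are_point_masses(self, five_tip, states5, params2):
        marg = marginal_asr(five_tip, states5, params2)
        for label in five_tip.tip_labels:
            i = five_tip.tip_index(label)
            s = states5.observed(label)
            assert marg.probs[i, s - 1] == pytest.approx(1.0)


class TestSampleHistories:
    def test_zero_q_constant_maps(self, quartet):
        p = SSEParams.from_rates([0.1, 0.1], [0.0, 0.0], 0.0)
        probs = np.zeros((quartet.n_nodes, 2))
        probs[:, 0] = 1.0
        hists = sample_histories(quartet, p, NodeMarginals(probs, 2), 5, seed=0)
        for h in hists:
            assert h.transition_counts().sum() == 0
            h.validate(quartet)
            assert all(len(h.segments[v]) == 1 for v in range(quartet.n_nodes - 1))

    def test_histories_satisfy_invariants(self):
        p = SSEParams.from_rates([0.15, 0.15], [0.03, 0.03], 0.05)
        o = simulate_mbd_tree(p, 1, n_extant=80, seed=4)
        marg = marginal_asr(o.tree, o.states, p)
        hists = sample_histories(o.tree, p, marg, 10, seed=1)
        for h in hists:
            h.validate(o.tree)
            # tips keep their observed states
            for label in o.tree.tip_labels:
                assert h.node_states[o.tree.tip_index(label)] == \
                    o.states.observed(label)

    def test_seed_reproducible(self, quartet):
        p = SSEParams.from_rates([0.1, 0.1], [0.0, 0.0], 0.2)
        st = TipStateMap({"A": 1, "B": 2, "C": 2, "D": 1}, 2)
        marg = marginal_asr(quartet, st, p)
        h1 = sample_histories(quartet, p, marg, 3, seed=9)
        h2 = sample_histories(quartet, p, marg, 3, seed=9)
        for a, b in zip(h1, h2):
            assert np.array_equal(a.node_states, b.node_states)
            assert a.segments == b.segments

    def test_impossible_endpoints_error(self, cherry):
        p = SSEParams.from_rates([0.1, 0.1], [0.0, 0.0], 0.0)  # q = 0
        probs = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])  # A=1, B=2
        with pytest.raises(ValidationError):
            sample_histories(cherry, p, NodeMarginals(probs, 2), 1, seed=0)

    def test_more_maps_shrink_monte_carlo_error(self):
        """The SE of mean counts falls as maps increase (variance ratio)."""
        p = SSEParams.from_rates([0.15, 0.15], [0.0, 0.0], 0.08)
        o = simulate_mbd_tree(p, 1, n_extant=60, seed=6)
        marg = marginal_asr(o.tree, o.states, p)

        def mean12(n_maps, seed):
            hs = sample_histories(o.tree, p, marg, n_maps, seed=seed)
            return count_transitions(hs).matrix[0, 1]

        small = [mean12(5, 100 + i) for i in range(12)]
        large = [mean12(50, 200 + i) for i in range(12)]
        assert np.var(large) < np.var(small)


class TestCounting:
    def _hist(self, segs_by_node, node_states, k=2):
        return CharacterHistory(k=k, node_states=np.array(node_states),
                                segments=segs_by_node)

    def test_constant_history_zero_matrix(self, cherry):
        h = self._hist([[(1, 1.0)], [(1, 1.0)], []], [1, 1, 1])
        tc = count_transitions([h], tree=cherry)
        assert np.all(tc.matrix == 0)

    def test_hand_built_counts(self, cherry):
        h = self._hist([[(1, 0.4), (2, 0.6)], [(1, 1.0)], []], [2, 1, 1])
        h2 = self._hist([[(1, 0.4), (2, 0.3), (1, 0.3)], [(1, 1.0)], []],
                        [1, 1, 1])
        tc = count_transitions([h, h2], tree=cherry)
        # map 1: one 1->2; map 2: one 1->2 and one 2->1 -> means (1.0, 0.5)
        assert tc.matrix[0, 1] == pytest.approx(1.0)
        assert tc.matrix[1, 0] == pytest.approx(0.5)

    def test_malformed_history_rejected(self, cherry):
        h = self._hist([[(1, 0.7)], [(1, 1.0)], []], [1, 1, 1])
        with pytest.raises(ValidationError, match="sum"):
            count_transitions([h], tree=cherry)

    def test_flow_consistency_on_fixture(self):
        """Entries/exits of a state balance up to boundary slack: the net
        flow |in - out| for each state cannot exceed the number of edges
        whose endpoint states differ."""
        p = SSEParams.from_rates([0.15, 0.15], [0.02, 0.02], 0.06)
        o = simulate_mbd_tree(p, 1, n_extant=100, seed=12)
        marg = marginal_asr(o.tree, o.states, p)
        hists = sample_histories(o.tree, p, marg, 5, seed=3)
        for h in hists:
            C = h.transition_counts()
            boundary = sum(
                1 for v in range(o.tree.n_nodes - 1)
                if h.node_states[v] != h.node_states[o.tree.parent[v]])
            for i in range(2):
                net = abs(C[i, :].sum() - C[:, i].sum())
                assert net <= boundary


class TestChordTable:
    def test_zero_matrix(self):
        from troposse.charmap import TransitionCounts
        tc = TransitionCounts(np.zeros((2, 2)), n_maps=1)
        tab = chord_table(tc, ["A", "B"])
        assert len(tab) == 2 and (tab["mean_lineages"] == 0).all()

    def test_values_and_roundtrip(self):
        from troposse.charmap import TransitionCounts
        tc = TransitionCounts(np.array([[0.0, 3.0], [1.0, 0.0]]), n_maps=1)
        tab = chord_table(tc, ["A", "B"])
        assert tab.set_index(["from", "to"]).loc[("A", "B"), "mean_lineages"] == 3
        back = np.zeros((2, 2))
        idx = {"A": 0, "B": 1}
        for _, row in tab.iterrows():
            back[idx[row["from"]], idx[row["to"]]] = row["mean_lineages"]
        assert np.array_equal(back, tc.matrix)

    def test_label_mismatch(self):
        from troposse.charmap import TransitionCounts
        tc = TransitionCounts(np.zeros((2, 2)), n_maps=1)
        with pytest.raises(ValidationError):
            chord_table(tc, ["only-one"])
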