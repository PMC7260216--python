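"""ML fitting, parameter tying, hidden-regime expansion, posterior
sampling, and pooled summaries."""

import numpy as np
import pandas as pd
import pytest

from troposse.states import SSEParams, TipStateMap, ValidationError
from troposse.sse import (HiddenSpec, LikelihoodOptions, PosteriorDraws,
                          SSEParamSpace, aic, expand_hidden, kde_mode,
                          musse_loglik, musse_mcmc, musse_ml,
                          pool_and_summarize, yule_rate)
from troposse.treesim import simulate_mbd_tree


@pytest.fixture(scope="module")
def two_state_sim():
    p = SSEParams.from_rates([0.1, 0.2], [0.03, 0.03], 0.02)
    return p, simulate_mbd_tree(p, 1, n_extant=200, seed=21)


class TestParamSpace:
    def test_roundtrip(self, params2):
        space = SSEParamSpace(2)
        assert space.n_free == 6
        x = space.to_vector(params2)
        back = space.to_params(x)
        assert np.allclose(back.lam, params2.lam)
        assert np.allclose(back.Q, params2.Q)

    def test_tie_and_fix(self):
        space = SSEParamSpace(2, tie={"mu2": "mu1"}, fix={"q21": 0.0})
        assert "mu2" not in space.free_names
        assert "q21" not in space.free_names
        p = space.to_params(space.to_vector(
            SSEParams.from_rates([0.1, 0.2], [0.05, 0.05],
                                 np.array([[0, 0.01], [0.0, 0]]))))
        assert p.mu[1] == p.mu[0]
        assert p.Q[1, 0] == 0.0

    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            SSEParamSpace(2, tie={"mu1": "mu2", "mu2": "mu1"})

    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError):
            SSEParamSpace(2, fix={"lam9": 1.0})


class TestML:
    def test_pure_birth_matches_yule_closed_form(self):
        p = SSEParams.from_rates([0.2], 0.0, np.zeros((1, 1)))
        o = simulate_mbd_tree(p, 1, n_extant=200, seed=11)
        space = SSEParamSpace(1, fix={"mu1": 0.0})
        opts = LikelihoodOptions(root_mode="flat", condition_survival=False)
        fit = musse_ml(o.tree, o.states, space=space, options=opts)
        lam_hat = yule_rate(o.tree)              # closed-form ML
        se = lam_hat / np.sqrt(o.tree.n_nodes - o.tree.n_tips)
        assert fit.converged
        assert abs(fit.params.lam[0] - lam_hat) < 1e-4   # same optimum
        assert abs(fit.params.lam[0] - 0.2) < 1.96 * se  # truth in 95% CI

    def test_two_state_point_estimate(self, two_state_sim):
        p, o = two_state_sim
        fit = musse_ml(o.tree, o.states)
        assert fit.converged
        assert fit.params.lam[1] > fit.params.lam[0]
        # restarting from the optimum does not improve the likelihood
        refit = musse_ml(o.tree, o.states, init=fit.params)
        assert refit.loglik <= fit.loglik + 1e-3

    def test_single_observed_state_reduces_to_birth_death(self):
        """All tips in state 1 with transitions pinned to 0: the fit is a
        plain constant-rate birth-death estimate for that state."""
        p1 = SSEParams.from_rates([0.25], [0.05], np.zeros((1, 1)))
        o = simulate_mbd_tree(p1, 1, n_extant=150, seed=13)
        st2 = TipStateMap({l: 1 for l in o.tree.tip_labels}, 2)
        space = SSEParamSpace(2, fix={"q12": 0.0, "q21": 0.0,
                                      "lam2": 0.1, "mu2": 0.01})
        fit2 = musse_ml(o.tree, st2, space=space)
        fit1 = musse_ml(o.tree, o.states, space=SSEParamSpace(1))
        assert fit2.params.lam[0] == pytest.approx(fit1.params.lam[0], rel=1e-3)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-3)


class TestHidden:
    def test_identity_expansion(self, two_state_sim):
        p, o = two_state_sim
        spec = HiddenSpec(2, 1)
        space, st = expand_hidden(spec, o.states)
        assert space.n_free == 6
        assert musse_loglik(o.tree, st, p) == pytest.approx(
            musse_loglik(o.tree, o.states, p), abs=1e-12)

    def test_tip_ambiguity_over_hidden_regimes(self, two_state_sim):
        _, o = two_state_sim
        spec = HiddenSpec(2, 2)
        _, st = expand_hidden(spec, o.states)
        label = o.tree.tip_labels[0]
        s = o.states.observed(label)
        assert st[label] == {spec.state_id(s, 1), spec.state_id(s, 2)}

    def test_constrained_never_beats_unconstrained(self, two_state_sim):
        _, o = two_state_sim
        su, stu = expand_hidden(HiddenSpec(2, 2, "unconstrained"), o.states)
        sc, stc = expand_hidden(HiddenSpec(2, 2, "constrained"), o.states)
        assert sc.n_free < su.n_free
        fu = musse_ml(o.tree, stu, space=su)
        fc = musse_ml(o.tree, stc, space=sc)
        assert fc.loglik <= fu.loglik + 1e-4

    def test_observed_rate_split_recovered_by_aic(self):
        """Data generated with rates split by the OBSERVED state: the
        unconstrained hidden model should win on AIC in the majority of
        replicates."""
        p = SSEParams.from_rates([0.06, 0.3], [0.03, 0.03], 0.05)
        wins = 0
        n_reps = 5
        for r in range(n_reps):
            o = simulate_mbd_tree(p, 1, n_extant=250, seed=300 + r)
            su, stu = expand_hidden(HiddenSpec(2, 2, "unconstrained"), o.states)
            sc, stc = expand_hidden(HiddenSpec(2, 2, "constrained"), o.states)
            fu = musse_ml(o.tree, stu, space=su)
            fc = musse_ml(o.tree, stc, space=sc)
            wins += int(aic(fu) < aic(fc))
        assert wins > n_reps / 2


class TestMCMC:
    def test_prior_only_recovers_exponential_mean(self, two_state_sim):
        p, o = two_state_sim
        space = SSEParamSpace(1, fix={"mu1": 0.0})
        start = np.array([0.2])
        d = musse_mcmc(o.tree, o.states, start, space=space, prior_rate=4.0,
                       n_gen=1500, n_prelim=100, seed=2, prior_only=True)
        m = d.post_burnin().mean().iloc[0]
        assert m == pytest.approx(1 / 4.0, rel=0.1)

    def test_seed_reproducibility(self, two_state_sim):
        p, o = two_state_sim
        fit = musse_ml(o.tree, o.states)
        kw = dict(n_gen=30, n_prelim=10, seed=7)
        d1 = musse_mcmc(o.tree, o.states, fit, **kw)
        d2 = musse_mcmc(o.tree, o.states, fit, **kw)
        assert d1.draws.equals(d2.draws)
        assert d1.burnin_frac == 0.10

    def test_rate_draws_and_ess(self, two_state_sim):
        p, o = two_state_sim
        fit = musse_ml(o.tree, o.states)
        d = musse_mcmc(o.tree, o.states, fit, n_gen=100, n_prelim=20, seed=5)
        rd = d.rate_draws()
        assert np.allclose(rd["r1"], rd["lam1"] - rd["mu1"])
        assert (rd[[c for c in rd.columns if c != "tree_id"]] .ge(-1).all().all())
        ess = d.ess()
        assert set(ess.index) == set(d.space.free_names)
        assert (ess > 0).all()


class TestPooling:
    def _draws(self, values, tree_id):
        space = SSEParamSpace(1, fix={"mu1": 0.0})
        df = pd.DataFrame({"lam1": values})
        return PosteriorDraws(draws=df, space=space, burnin_frac=0.0,
                              tree_id=tree_id)

    def test_single_set_identity(self):
        d = self._draws(np.linspace(0.1, 0.3, 100), "t0")
        s = pool_and_summarize([d])
        assert s.loc["lam1", "n_draws"] == 100
        assert s.loc["lam1", "lo"] == pytest.approx(0.105, abs=0.01)

    def test_net_diversification_arithmetic(self):
        # draws of lam = 0.2 +/- eps, mu = 0.1 +/- eps -> r mode near 0.1
        rng = np.random.default_rng(0)
        space = SSEParamSpace(1)          # free names: lam1, mu1 (no q at k=1)
        df = pd.DataFrame({"lam1": 0.2 + 0.001 * rng.standard_normal(500),
                           "mu1": 0.1 + 0.001 * rng.standard_normal(500)})
        d = PosteriorDraws(draws=df, space=space, burnin_frac=0.0)
        s = pool_and_summarize([d])
        assert s.loc["r1", "mode"] == pytest.approx(0.1, abs=0.005)

    def test_disjoint_supports_preserved(self):
        a = self._draws(np.full(200, 0.1) + np.linspace(0, 0.01, 200), "a")
        b = self._draws(np.full(200, 0.5) + np.linspace(0, 0.01, 200), "b")
        s = pool_and_summarize([a, b], level=0.95)
        assert s.loc["lam1", "lo"] < 0.12
        assert s.loc["lam1", "hi"] > 0.49

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pool_and_summarize([])
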