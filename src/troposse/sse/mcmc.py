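"""Bayesian sampling of SSE parameters.

The default kernel is univariate slice sampling (stepping-out and
shrinkage), which is tuning-light: per-parameter slice widths are set
from a short preliminary run, after which the main chain is drawn.  A
random-walk Metropolis kernel is available as an option.  Priors are
independent exponentials on every free rate; the default prior rate is
``1 / (2 * r_hat)`` with ``r_hat`` the tree-wide pure-birth rate estimate
(the upstream tool's documented heuristic).

One *generation* is one full sweep over the free parameters.  The
standard protocol mirrors the analysis this package reproduces: a
preliminary run of 100 generations, a main chain of 2000, 10% burn-in,
and convergence screening by effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..states import SSEParams, TipStateMap, ValidationError
from ..trees import PhyloTree
from .fit import SSEFit, yule_rate
from .likelihood import LikelihoodOptions, SSEComputeError, musse_loglik
from .paramspace import SSEParamSpace

__all__ = ["PosteriorDraws", "musse_mcmc", "default_prior_rate", "ChainStuckError"]

ESS_WARN_THRESHOLD = 200.0


class ChainStuckError(RuntimeError):
    """Raised when the sampler cannot move (advises a step-size change)."""


def default_prior_rate(tree: PhyloTree) -> float:
    """Exponential prior rate 1/(2*r_hat); prior mean twice the tree-wide
    pure-birth rate estimate."""
    return 1.0 / (2.0 * yule_rate(tree))


@dataclass
class PosteriorDraws:
    """Post-preliminary parameter draws for one tree.

    ``draws`` has one column per free parameter; ``burnin_frac`` is the
    fraction dropped by :meth:`post_burnin` (and by pooled summaries).
    """

    draws: pd.DataFrame
    space: SSEParamSpace
    burnin_frac: float
    tree_id: str = "tree_0"
    prior_rate: np.ndarray | None = None
    slice_w: np.ndarray | None = None

    def post_burnin(self) -> pd.DataFrame:
        n = len(self.draws)
        return self.draws.iloc[int(np.floor(self.burnin_frac * n)):]

    def ess(self) -> pd.Series:
        """Per-parameter effective sample size of the post-burn-in chain."""
        import arviz as az
        pb = self.post_burnin()
        ds = az.convert_to_dataset({c: pb[c].to_numpy()[None, :] for c in pb})
        e = az.ess(ds)
        return pd.Series({c: float(e[c].values) for c in pb.columns})

    def rate_draws(self) -> pd.DataFrame:
        """Per-draw full rates: lam_i, mu_i and net diversification r_i."""
        pb = self.post_burnin()
        k = self.space.k
        X = pb.to_numpy()
        cols = {f"lam{i}": np.empty(len(pb)) for i in range(1, k + 1)}
        cols.update({f"mu{i}": np.empty(len(pb)) for i in range(1, k + 1)})
        for row, x in enumerate(X):
            p = self.space.to_params(x)
            for i in range(k):
                cols[f"lam{i + 1}"][row] = p.lam[i]
                cols[f"mu{i + 1}"][row] = p.mu[i]
        out = pd.DataFrame(cols, index=pb.index)
        for i in range(1, k + 1):
            out[f"r{i}"] = out[f"lam{i}"] - out[f"mu{i}"]
        out["tree_id"] = self.tree_id
        return out


def _slice_update_1d(logpost, x, j, w, rng, f0=None, max_steps=50):
    """One stepping-out/shrinkage slice move for coordinate j (domain > 0).

    ``f0`` is the cached log-posterior at ``x``; returns ``(x_new, f_new)``.
    """
    if f0 is None:
        f0 = logpost(x)
    z = f0 - rng.exponential(1.0)
    u = rng.random()
    L = max(x[j] - u * w, 0.0)
    R = L + w
    xl = x.copy()
    xr = x.copy()
    for _ in range(max_steps):
        if L <= 0.0:
            L = 0.0
            break
        xl[j] = L
        if logpost(xl) <= z:
            break
        L = max(L - w, 0.0)
    for _ in range(max_steps):
        xr[j] = R
        if logpost(xr) <= z:
            break
        R += w
    xn = x.copy()
    for _ in range(200):
        xn[j] = rng.uniform(L, R)
        fn = logpost(xn)
        if fn > z:
            return xn, fn
        if xn[j] < x[j]:
            L = xn[j]
        else:
            R = xn[j]
    raise ChainStuckError(
        f"slice shrinkage failed on parameter index {j}; "
        "the slice width is likely far too large or the posterior is degenerate")


def _metropolis_update(logpost, x, step, rng):
    prop = x * np.exp(rng.normal(0.0, step, size=x.size))
    # log-normal proposal: Jacobian term sum(log prop) - sum(log x)
    lp_cur = logpost(x)
    lp_new = logpost(prop)
    log_acc = (lp_new + np.log(prop).sum()) - (lp_cur + np.log(x).sum())
    if np.log(rng.random()) < log_acc:
        return prop, lp_new, True
    return x, lp_cur, False


def musse_mcmc(tree: PhyloTree, states: TipStateMap,
               start: SSEFit | SSEParams | np.ndarray, *,
               space: SSEParamSpace | None = None,
               prior_rate: float | np.ndarray | None = None,
               n_gen: int = 2000, n_prelim: int = 100,
               burnin_frac: float = 0.10,
               seed: int | None = None,
               options: LikelihoodOptions | None = None,
               kernel: str = "slice",
               slice_w: np.ndarray | None = None,
               prior_only: bool = False,
               tree_id: str = "tree_0") -> PosteriorDraws:
    """Sample the posterior of the free SSE parameters for one tree.

    ``start`` is usually a converged :class:`SSEFit` (its space is reused
    unless ``space`` overrides it).  The preliminary run of ``n_prelim``
    generations tunes per-parameter slice widths; the returned draws are
    the ``n_gen`` post-preliminary generations, with the burn-in fraction
    recorded (removal happens at summary time).  Seed-reproducible.

    ``prior_only=True`` switches the likelihood off (posterior = prior),
    used for sampler validation.
    """
    options = options or LikelihoodOptions()
    if isinstance(start, SSEFit):
        space = space or start.space
        x0 = start.x.copy()
    elif isinstance(start, SSEParams):
        space = space or SSEParamSpace(start.k)
        x0 = space.to_vector(start)
    else:
        if space is None:
            raise ValidationError("raw start vector requires an explicit space")
        x0 = np.asarray(start, dtype=float).copy()
    if np.any(x0 <= 0):
        x0 = np.maximum(x0, 1e-6)

    rho = prior_rate if prior_rate is not None else default_prior_rate(tree)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (space.n_free,)).copy()
    if np.any(rho <= 0):
        raise ValidationError("prior rates must be positive")
    rng = np.random.default_rng(seed)

    def logpost(x):
        if np.any(x <= 0):
            return -np.inf
        lp = float(-(rho * x).sum())        # exponential log-prior (no const)
        if prior_only:
            return lp
        try:
            return lp + musse_loglik(tree, states, space.to_params(x), options)
        except SSEComputeError:
            return -np.inf

    if kernel not in ("slice", "metropolis"):
        raise ValidationError("kernel must be 'slice' or 'metropolis'")

    w = np.asarray(slice_w, float) if slice_w is not None else np.maximum(x0, 0.05)
    x = x0.copy()

    def sweep_slice(x, w, lp):
        for j in range(x.size):
            x, lp = _slice_update_1d(logpost, x, j, w[j], rng, lp)
        return x, lp

    if kernel == "slice":
        lp = logpost(x)
        prelim = np.empty((n_prelim, x.size))
        for g in range(n_prelim):
            x, lp = sweep_slice(x, w, lp)
            prelim[g] = x
        # tune: slice width from the preliminary spread (floor keeps it live)
        if n_prelim > 1:
            spread = prelim.max(axis=0) - prelim.min(axis=0)
            w = np.where(spread > 0, 2.0 * spread, w)
        draws = np.empty((n_gen, x.size))
        for g in range(n_gen):
            x, lp = sweep_slice(x, w, lp)
            draws[g] = x
    else:
        step = 0.2
        acc = 0
        for g in range(n_prelim):
            x, _, a = _metropolis_update(logpost, x, step, rng)
            acc += a
        rate = acc / max(n_prelim, 1)
        if rate < 0.05:
            step *= 0.3
        elif rate > 0.6:
            step *= 2.0
        draws = np.empty((n_gen, x.size))
        acc = 0
        for g in range(n_gen):
            x, _, a = _metropolis_update(logpost, x, step, rng)
            acc += a
            draws[g] = x
        if acc == 0:
            raise ChainStuckError(
                "Metropolis chain accepted no proposals; reduce the step size")

    df = pd.DataFrame(draws, columns=space.free_names)
    df.index.name = "generation"
    return PosteriorDraws(draws=df, space=space, burnin_frac=burnin_frac,
                          tree_id=tree_id, prior_rate=rho, slice_w=w)
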