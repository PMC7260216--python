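"""Maximum-likelihood fitting of SSE models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ..states import SSEParams, TipStateMap
from ..trees import PhyloTree
from .likelihood import LikelihoodOptions, SSEComputeError, musse_loglik
from .paramspace import SSEParamSpace

__all__ = ["SSEFit", "musse_ml", "yule_rate", "aic", "starting_params"]


@dataclass
class SSEFit:
    """Point estimate from :func:`musse_ml`.

    ``converged`` is False (a flag, not an exception) when the optimizer
    stalled or a restart still improved the objective; ``diagnostics``
    carries the optimizer messages.
    """

    params: SSEParams
    loglik: float
    converged: bool
    options: LikelihoodOptions
    space: SSEParamSpace
    x: np.ndarray
    n_evals: int = 0
    diagnostics: str = ""

    @property
    def n_free(self) -> int:
        return self.space.n_free

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(), "loglik": self.loglik,
                "converged": self.converged,
                "free": dict(zip(self.space.free_names, self.x.tolist())),
                "options": {"root_mode": self.options.root_mode,
                            "condition_survival": self.options.condition_survival}}


def aic(fit: SSEFit) -> float:
    return 2.0 * fit.n_free - 2.0 * fit.loglik


def yule_rate(tree: PhyloTree) -> float:
    """Pure-birth ML speciation rate: (number of internal nodes) divided
    by total branch length — the convention that counts the root merge,
    matching the per-node ``lam`` factors in the SSE likelihood."""
    n_internal = tree.n_nodes - tree.n_tips
    return n_internal / tree.total_length()


def starting_params(tree: PhyloTree, states: TipStateMap,
                    space: SSEParamSpace) -> np.ndarray:
    """Heuristic initial free vector: state-independent birth-death guess
    around the tree-wide pure-birth rate, slow character transitions."""
    lam0 = yule_rate(tree)
    x = np.empty(space.n_free)
    for i, name in enumerate(space.free_names):
        if name.startswith("lam"):
            x[i] = lam0
        elif name.startswith("mu"):
            x[i] = 0.5 * lam0
        else:
            x[i] = 0.1 * lam0
    return x


def musse_ml(tree: PhyloTree, states: TipStateMap, *,
             space: SSEParamSpace | None = None,
             init: SSEParams | np.ndarray | None = None,
             bounds: tuple = (1e-6, 10.0),
             options: LikelihoodOptions | None = None,
             n_restarts: int = 1,
             improve_tol: float = 1e-4,
             seed: int | None = None) -> SSEFit:
    """Maximize the MuSSE likelihood over the free parameters of ``space``.

    Optimization runs in log-parameter space (rates are positive) with
    L-BFGS-B inside ``bounds``.  After the first solve the optimizer is
    restarted from its own optimum; if the restart still improves the
    objective by more than ``improve_tol`` the fit is returned flagged
    unconverged rather than raising.  ``n_restarts`` extra jittered starts
    guard against local optima.
    """
    options = options or LikelihoodOptions()
    space = space or SSEParamSpace(states.k)
    lo, hi = bounds
    if lo <= 0 or hi <= lo:
        raise ValueError("bounds must satisfy 0 < lo < hi")

    if init is None:
        x0 = starting_params(tree, states, space)
    elif isinstance(init, SSEParams):
        x0 = space.to_vector(init)
    else:
        x0 = np.asarray(init, dtype=float)
    x0 = np.clip(x0, lo, hi)

    n_evals = 0

    def nll(logx):
        nonlocal n_evals
        n_evals += 1
        try:
            p = space.to_params(np.exp(logx))
            return -musse_loglik(tree, states, p, options)
        except SSEComputeError:
            return 1e10

    log_bounds = [(np.log(lo), np.log(hi))] * space.n_free

    def solve(start):
        return minimize(nll, np.log(np.clip(start, lo, hi)), method="L-BFGS-B",
                        bounds=log_bounds)

    best = solve(x0)
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        jitter = x0 * np.exp(rng.normal(0.0, 0.5, size=x0.size))
        res = solve(jitter)
        if res.fun < best.fun:
            best = res
    # restart-from-optimum convergence check
    recheck = solve(np.exp(best.x))
    converged = bool(best.fun - recheck.fun <= improve_tol)
    if recheck.fun < best.fun:
        best = recheck
    x = np.exp(best.x)
    params = space.to_params(x)
    return SSEFit(params=params, loglik=-float(best.fun), converged=converged,
                  options=options, space=space, x=x, n_evals=n_evals,
                  diagnostics=str(best.message))
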