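"""MuSSE log-likelihood: multi-state speciation/extinction on a rooted
binary tree with per-state speciation (lam_i), extinction (mu_i) and
character transition rates (q_ij).

Tips contribute indicator initial conditions over their admissible states
(complete sampling: E = 0 at the present).  Branches are integrated
rootward; at each internal node the two daughter partials are merged as
``D_i <- lam_i * D_i(left) * D_i(right)``.  At the root the per-state
partials are combined under a configurable weighting (likelihood-
proportional "FitzJohn" weights by default, optionally flat or a user
distribution), with optional conditioning on survival of both crown
lineages (division by ``sum_i pi_i lam_i (1 - E_i)^2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..states import SSEParams, TipStateMap, ValidationError
from ..trees import PhyloTree
from . import _kernels

__all__ = ["LikelihoodOptions", "musse_loglik", "LikelihoodCache", "SSEComputeError"]


class SSEComputeError(ArithmeticError):
    """Numerical failure during likelihood propagation (carries node id)."""

    def __init__(self, status: int, node: int):
        self.status = status
        self.node = node
        what = {_kernels.STATUS_NEGATIVE_D: "non-positive partial likelihood",
                _kernels.STATUS_STEP_FAILURE: "integration step failure"}
        super().__init__(f"{what.get(status, 'numerical error')} at node {node}")


@dataclass(frozen=True)
class LikelihoodOptions:
    """Root treatment and integrator settings.

    root_mode
        ``"fitzjohn"`` — weight root states by their likelihood share
        (the cited framework's default); ``"flat"`` — uniform 1/k;
        ``"given"`` — use ``root_pi``.
    condition_survival
        Divide by ``sum_i pi_i lam_i (1 - E_root,i)^2`` (survival of both
        crown lineages).  On by default.
    """

    root_mode: str = "fitzjohn"
    root_pi: tuple | None = None
    condition_survival: bool = True
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.root_mode not in ("fitzjohn", "flat", "given"):
            raise ValidationError(f"unknown root_mode {self.root_mode!r}")
        if self.root_mode == "given" and self.root_pi is None:
            raise ValidationError("root_mode='given' requires root_pi")

    def with_(self, **kw) -> "LikelihoodOptions":
        return replace(self, **kw)


@dataclass
class LikelihoodCache:
    """Per-node quantities from one likelihood pass, reused by the
    ancestral-state machinery.  ``D`` columns are normalized per node; the
    dropped magnitudes are in ``logscale``."""

    tree: PhyloTree
    params: SSEParams
    options: LikelihoodOptions
    E_node: np.ndarray
    D_node: np.ndarray
    E_top: np.ndarray
    D_top: np.ndarray
    logscale: float
    loglik: float


def _root_loglik(d_root: np.ndarray, E_root: np.ndarray, lam: np.ndarray,
                 options: LikelihoodOptions) -> float:
    """Combine normalized root partials into a (relative) log-likelihood."""
    k = lam.size
    if options.root_mode == "fitzjohn":
        tot = d_root.sum()
        if tot <= 0:
            return -np.inf
        pi = d_root / tot
    elif options.root_mode == "flat":
        pi = np.full(k, 1.0 / k)
    else:
        pi = np.asarray(options.root_pi, dtype=float)
        if pi.shape != (k,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValidationError("root_pi must be a length-k distribution")
    d = d_root
    if options.condition_survival:
        denom = float((pi * lam * (1.0 - E_root) ** 2).sum())
        if denom <= 0:
            return -np.inf
        d = d / denom
    L = float((pi * d).sum())
    return np.log(L) if L > 0 else -np.inf


def _run_pass(tree: PhyloTree, states: TipStateMap, params: SSEParams,
              options: LikelihoodOptions):
    if params.k != states.k:
        raise ValidationError("params.k and states.k disagree")
    D0 = states.tip_matrix(tree)
    status, bad, E_node, D_node, E_top, D_top, logscale = _kernels._postorder_pass(
        tree.left, tree.right, tree.blen, D0,
        params.lam, params.mu, params.Q, options.rtol, options.atol)
    if status != _kernels.STATUS_OK:
        raise SSEComputeError(status, bad)
    return E_node, D_node, E_top, D_top, logscale


def musse_loglik(tree: PhyloTree, states: TipStateMap, params: SSEParams,
                 options: LikelihoodOptions | None = None,
                 return_cache: bool = False):
    """MuSSE log-likelihood of ``states`` on ``tree`` under ``params``.

    Deterministic at fixed integrator tolerances and invariant to child
    ordering.  Raises :class:`SSEComputeError` on numerical failure and
    :class:`~troposse.trees.TreeStructureError` upstream for non-binary
    input.
    """
    options = options or LikelihoodOptions()
    E_node, D_node, E_top, D_top, logscale = _run_pass(tree, states, params, options)
    root = tree.root
    ll = _root_loglik(D_node[root], E_node[root], params.lam, options) + logscale
    if return_cache:
        return ll, LikelihoodCache(tree, params, options, E_node, D_node,
                                   E_top, D_top, logscale, ll)
    return ll
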