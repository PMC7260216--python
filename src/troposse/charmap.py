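"""Ancestral states and stochastic character mapping under a fitted SSE
model.

Marginal ancestral-state reconstruction clamps each node to each state in
turn, re-propagates the clamped partial likelihood along the node's root
path (all off-path subtree partials are reused from one cached
likelihood pass), applies the same root treatment as the likelihood, and
normalizes — exactly the brute-force "fix the node, recompute, normalize"
definition, computed in O(depth) per node instead of O(n).

Stochastic maps are drawn "marginals-as-input": node states are sampled
top-down from the reconstructed marginals, each non-root node re-weighted
by the parent-state row of the branch transition-probability matrix
``expm(Q t)``; the path along each branch is then drawn conditioned on
its endpoints by uniformization.  Within branches only the character
process ``Q`` acts (state-dependent birth/death does not bend the path
law) — the behavior of the mapping tool this protocol derives from, and a
documented approximation.  A standard joint top-down sampler (pruning
partials instead of marginals) is available via ``method="joint"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .states import CharacterHistory, SSEParams, TipStateMap, ValidationError
from .trees import PhyloTree
from .sse._kernels import propagate_branch
from .sse.likelihood import LikelihoodOptions, _root_loglik, musse_loglik

__all__ = ["NodeMarginals", "TransitionCounts", "marginal_asr",
           "sample_histories", "count_transitions", "chord_table"]


@dataclass
class NodeMarginals:
    """Per-node posterior state probabilities (rows sum to 1)."""

    probs: np.ndarray            # n_nodes x k
    k: int

    def __post_init__(self):
        s = self.probs.sum(axis=1)
        if np.any(np.abs(s - 1.0) > 1e-9) or np.any(self.probs < -1e-12):
            raise ValidationError("marginals must be distributions")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs,
                          columns=[f"p_{i}" for i in range(1, self.k + 1)])
        df.index.name = "node"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NodeMarginals":
        return cls(df.to_numpy(dtype=float), df.shape[1])


def marginal_asr(tree: PhyloTree, states: TipStateMap, params: SSEParams,
                 options: LikelihoodOptions | None = None) -> NodeMarginals:
    """Marginal ancestral-state reconstruction under the SSE model.

    For every node (tips included — observed tips come out as point
    masses), the returned row is proportional to the full-tree likelihood
    with that node's state clamped, under the same root mode and survival
    conditioning as the likelihood itself.
    """
    options = options or LikelihoodOptions()
    _, cache = musse_loglik(tree, states, params, options, return_cache=True)
    k = params.k
    lam, mu, Q = params.lam, params.mu, params.Q
    root = tree.root
    probs = np.empty((tree.n_nodes, k))
    for v in range(tree.n_nodes):
        logL = np.full(k, -np.inf)
        for j in range(k):
            if cache.D_node[v, j] <= 0.0:
                continue            # state impossible given the subtree
            d = np.zeros(k)
            d[j] = cache.D_node[v, j]
            logs = 0.0
            cur = v
            ok = True
            while cur != root:
                E = cache.E_node[cur]
                if tree.blen[cur] > 0.0:
                    try:
                        E, d, ls = propagate_branch(E, d, tree.blen[cur], lam,
                                                    mu, Q, options.rtol,
                                                    options.atol)
                    except ArithmeticError:
                        ok = False
                        break
                    if not np.isfinite(ls):
                        ok = False
                        break
                    logs += ls
                p = int(tree.parent[cur])
                sib = int(tree.right[p]) if tree.left[p] == cur else int(tree.left[p])
                d = lam * d * cache.D_top[sib]
                s = d.sum()
                if s <= 0.0:
                    ok = False
                    break
                d /= s
                logs += np.log(s)
                cur = p
            if not ok:
                continue
            rl = _root_loglik(d, cache.E_node[root], lam, options)
            logL[j] = rl + logs
        m = logL.max()
        if not np.isfinite(m):
            raise ValidationError(f"all states impossible at node {v}")
        w = np.exp(logL - m)
        probs[v] = w / w.sum()
    return NodeMarginals(probs, k)


# ---------------------------------------------------------------- mapping

def _branch_P(tree: PhyloTree, Q: np.ndarray) -> list:
    return [expm(Q * tree.blen[v]) for v in range(tree.n_nodes)]


def _sample_endpoint_path(a: int, b: int, t: float, Q: np.ndarray,
                          P_ab: float, rng) -> list:
    """Endpoint-conditioned CTMC path by uniformization.

    Returns ``(state, duration)`` segments from parent state ``a`` (0-based)
    to child state ``b`` over duration ``t``; self-transitions of the
    dominating chain are thinned out.
    """
    k = Q.shape[0]
    omega = float(-Q.diagonal().min())
    if omega <= 0.0:              # Q == 0: only constant paths possible
        if a != b:
            raise ValidationError("zero transition rate but differing endpoints")
        return [(a, t)]
    omega *= 1.05
    R = np.eye(k) + Q / omega
    # number of dominating-chain jumps: p(n) ~ Pois(omega t) * R^n[a,b] / P_ab
    u = rng.random() * P_ab
    log_pois = -omega * t
    Rn = np.eye(k)
    acc = 0.0
    n = 0
    while True:
        acc += np.exp(log_pois) * Rn[a, b]
        if acc >= u or n > 100_000:
            break
        n += 1
        log_pois += np.log(omega * t) - np.log(n)
        Rn = Rn @ R
    # intermediate states by forward filtering against remaining-step powers
    Rpow = [np.eye(k)]
    for _ in range(n):
        Rpow.append(Rpow[-1] @ R)
    seq = [a]
    for step in range(1, n):
        prev = seq[-1]
        wgt = R[prev, :] * Rpow[n - step][:, b]
        wgt = np.clip(wgt, 0.0, None)
        tot = wgt.sum()
        if tot <= 0.0:
            raise ValidationError("degenerate uniformization weights")
        seq.append(int(rng.choice(k, p=wgt / tot)))
    if n > 0:
        seq.append(b)
    times = np.sort(rng.uniform(0.0, t, size=n))
    # merge virtual (self) jumps into segments
    segs = []
    cur_state = seq[0]
    t_prev = 0.0
    for i in range(n):
        if seq[i + 1] != cur_state:
            segs.append((cur_state, times[i] - t_prev))
            t_prev = times[i]
            cur_state = seq[i + 1]
    segs.append((cur_state, t - t_prev))
    return segs


def sample_histories(tree: PhyloTree, params: SSEParams,
                     marginals: NodeMarginals, n_maps: int,
                     seed: int | None = None, *,
                     states: TipStateMap | None = None,
                     method: str = "marginal",
                     max_retries: int = 20) -> list:
    """Draw ``n_maps`` stochastic character histories.

    ``method="marginal"`` (default) samples node states top-down from
    ``marginals``, re-weighting each non-root node by the parent-to-state
    row of ``expm(Q t)``; ``method="joint"`` uses plain Mk pruning
    partials of the tip data (requires ``states``) for exact joint
    sampling under the character process.  Branch paths are always drawn
    endpoint-conditioned by uniformization.  Seed-reproducible.
    """
    if method not in ("marginal", "joint"):
        raise ValidationError("method must be 'marginal' or 'joint'")
    if marginals.probs.shape != (tree.n_nodes, params.k):
        raise ValidationError("marginals do not cover this tree")
    rng = np.random.default_rng(seed)
    k = params.k
    Q = params.Q
    P = _branch_P(tree, Q)
    root = tree.root

    if method == "joint":
        if states is None:
            raise ValidationError("method='joint' requires tip states")
        L = np.zeros((tree.n_nodes, k))
        D0 = states.tip_matrix(tree)
        for v in range(tree.n_nodes):
            if tree.left[v] < 0:
                L[v] = D0[v]
            else:
                l, r = int(tree.left[v]), int(tree.right[v])
                L[v] = (P[l] @ L[l]) * (P[r] @ L[r])
                s = L[v].sum()
                if s <= 0:
                    raise ValidationError(f"impossible tip data below node {v}")
                L[v] /= s

    histories = []
    for _ in range(n_maps):
        for attempt in range(max_retries):
            node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
            ok = True
            for v in range(tree.n_nodes - 1, -1, -1):   # preorder
                if v == root:
                    w = marginals.probs[root] if method == "marginal" else \
                        marginals.probs[root] * L[root]
                else:
                    sp = node_states[int(tree.parent[v])] - 1
                    base = marginals.probs[v] if method == "marginal" else L[v]
                    w = base * P[v][sp, :]
                w = np.clip(w, 0.0, None)
                tot = w.sum()
                if tot <= 0.0:
                    ok = False
                    bad_edge = v
                    break
                node_states[v] = 1 + int(rng.choice(k, p=w / tot))
            if ok:
                break
        else:
            raise ValidationError(
                f"no feasible state assignment for the edge above node "
                f"{bad_edge} after {max_retries} retries")

        segments: list = [[] for _ in range(tree.n_nodes)]
        for v in range(tree.n_nodes):
            if v == root:
                if tree.blen[root] > 0:
                    segments[root] = [(int(node_states[root]), tree.blen[root])]
                continue
            a = node_states[int(tree.parent[v])] - 1
            b = node_states[v] - 1
            p_ab = float(P[v][a, b])
            if p_ab <= 0.0:
                raise ValidationError(
                    f"endpoint pair ({a + 1}->{b + 1}) has zero probability "
                    f"on the edge above node {v}")
            segs = _sample_endpoint_path(a, b, float(tree.blen[v]), Q, p_ab, rng)
            segments[v] = [(s + 1, d) for s, d in segs]
        histories.append(CharacterHistory(k=k, node_states=node_states,
                                          segments=segments))
    return histories


@dataclass
class TransitionCounts:
    """Mean directed transition counts (lineages) over maps and trees."""

    matrix: np.ndarray
    n_maps: int
    n_trees: int = 1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < 0) or np.any(np.diag(self.matrix) != 0):
            raise ValidationError("counts must be >= 0 with a zero diagonal")


def count_transitions(histories: list, tree: PhyloTree | None = None,
                      n_trees: int = 1) -> TransitionCounts:
    """Mean i->j transition counts across histories.

    When ``tree`` is given each history is validated against it (segment
    durations must sum to branch lengths).
    """
    if not histories:
        raise ValidationError("no histories given")
    k = histories[0].k
    total = np.zeros((k, k), dtype=float)
    for h in histories:
        if h.k != k:
            raise ValidationError("histories have differing state counts")
        if tree is not None:
            h.validate(tree)
        total += h.transition_counts()
    return TransitionCounts(matrix=total / len(histories),
                            n_maps=len(histories) // max(n_trees, 1),
                            n_trees=n_trees)


def chord_table(counts: TransitionCounts, labels: list) -> pd.DataFrame:
    """Long-format (from, to, mean_lineages) table, diagonal omitted."""
    k = counts.matrix.shape[0]
    if len(labels) != k:
        raise ValidationError(f"need {k} labels, got {len(labels)}")
    rows = [(labels[i], labels[j], counts.matrix[i, j])
            for i in range(k) for j in range(k) if i != j]
    return pd.DataFrame(rows, columns=["from", "to", "mean_lineages"])
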