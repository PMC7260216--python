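"""Core parameter and character-data containers shared across modules.

States are identified by the integers ``1..k`` in all public interfaces
(the convention of the SSE literature); internal arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SSEParams", "TipStateMap", "CharacterHistory", "ValidationError"]


class ValidationError(ValueError):
    pass


@dataclass
class SSEParams:
    """Per-state speciation/extinction rates plus a transition-rate matrix.

    ``lam[i]`` and ``mu[i]`` are the speciation and extinction rates
    (events per Myr) of state ``i+1``; ``Q[i, j]`` (i != j) is the
    instantaneous transition rate from state ``i+1`` to ``j+1``; diagonal
    entries hold minus the row sum so rows sum to zero.  Net diversification
    ``r_i = lam_i - mu_i`` is derived, never stored.
    """

    k: int
    lam: np.ndarray
    mu: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        k = self.k
        if k < 1:
            raise ValidationError("k must be >= 1")
        if self.lam.shape != (k,) or self.mu.shape != (k,):
            raise ValidationError("lam/mu length must equal k")
        if self.Q.shape != (k, k):
            raise ValidationError("Q must be k x k")
        if np.any(self.lam < 0) or np.any(self.mu < 0):
            raise ValidationError("negative speciation or extinction rate")
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValidationError("negative off-diagonal transition rate")
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-12):
            raise ValidationError("Q rows must sum to zero (within 1e-12)")

    @classmethod
    def from_rates(cls, lam, mu, q) -> "SSEParams":
        """Build from off-diagonal rates; the diagonal is filled in.

        ``q`` may be a scalar (all off-diagonal rates equal) or a k x k
        array whose diagonal is ignored.
        """
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        k = lam.size
        mu = np.broadcast_to(np.asarray(mu, dtype=float), (k,)).copy()
        if np.isscalar(q) or np.asarray(q).ndim == 0:
            Q = np.full((k, k), float(q))
        else:
            Q = np.asarray(q, dtype=float).copy()
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(k, lam, mu, Q)

    @property
    def net_div(self) -> np.ndarray:
        """Net diversification r_i = lam_i - mu_i."""
        return self.lam - self.mu

    def to_dict(self) -> dict:
        return {"k": self.k, "lam": self.lam.tolist(), "mu": self.mu.tolist(),
                "Q": self.Q.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SSEParams":
        return cls(int(d["k"]), np.array(d["lam"]), np.array(d["mu"]), np.array(d["Q"]))


class TipStateMap:
    """Mapping tip label -> set of admissible states (subset of 1..k).

    A singleton set is an observed state; the full set encodes a missing or
    ambiguous observation.
    """

    def __init__(self, states: dict, k: int):
        self.k = int(k)
        self._map: dict = {}
        for label, st in states.items():
            if isinstance(st, (int, np.integer)):
                st = {int(st)}
            st = frozenset(int(s) for s in st)
            if not st:
                raise ValidationError(f"empty admissible set for tip {label!r}")
            if not st <= set(range(1, self.k + 1)):
                raise ValidationError(f"state out of range 1..{k} for tip {label!r}")
            self._map[label] = st
        self.labels = list(self._map)

    def __getitem__(self, label: str):
        return self._map[label]

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self):
        return iter(self._map)

    def items(self):
        return self._map.items()

    def observed(self, label: str) -> int:
        """The single observed state of ``label`` (error if ambiguous)."""
        st = self._map[label]
        if len(st) != 1:
            raise ValidationError(f"tip {label!r} is ambiguous: {sorted(st)}")
        return next(iter(st))

    def check_tree(self, tree) -> None:
        missing = set(tree.tip_labels) - set(self._map)
        if missing:
            raise ValidationError(f"tips without state entries: {sorted(missing)[:5]}")

    def tip_matrix(self, tree) -> np.ndarray:
        """n_nodes x k indicator matrix of admissible states (tips only)."""
        self.check_tree(tree)
        D0 = np.zeros((tree.n_nodes, self.k))
        for label in tree.tip_labels:
            i = tree.tip_index(label)
            for s in self._map[label]:
                D0[i, s - 1] = 1.0
        return D0

    def counts(self) -> np.ndarray:
        """Number of tips whose admissible set contains each state."""
        c = np.zeros(self.k, dtype=int)
        for st in self._map.values():
            for s in st:
                c[s - 1] += 1
        return c


@dataclass
class CharacterHistory:
    """A full character history painted on a tree.

    ``segments[v]`` is the ordered list of ``(state, duration)`` pieces on
    the edge *above* node ``v``, running parent -> child; ``node_states[v]``
    is the state at node ``v`` itself.  Zero-length edges carry a single
    zero-duration segment.
    """

    k: int
    node_states: np.ndarray
    segments: list  # list over nodes; entry = list[(state, duration)]

    def validate(self, tree, atol: float = 1e-9) -> None:
        ns = np.asarray(self.node_states)
        if ns.size != tree.n_nodes or len(self.segments) != tree.n_nodes:
            raise ValidationError("history does not cover every node")
        for v in range(tree.n_nodes):
            segs = self.segments[v]
            if v == tree.root and not segs:
                continue
            total = sum(d for _, d in segs)
            if abs(total - tree.blen[v]) > atol:
                raise ValidationError(
                    f"segments on edge above node {v} sum to {total}, "
                    f"branch length is {tree.blen[v]}")
            if segs[-1][0] != ns[v]:
                raise ValidationError(f"last segment state mismatch at node {v}")
            p = tree.parent[v]
            if p >= 0 and segs[0][0] != ns[p]:
                raise ValidationError(f"first segment state mismatch at node {v}")
            for (a, _), (b, _) in zip(segs, segs[1:]):
                if a == b:
                    raise ValidationError(
                        f"consecutive segments share a state on edge above {v}")

    def transition_counts(self) -> np.ndarray:
        """k x k matrix of state-change events along all edges."""
        C = np.zeros((self.k, self.k), dtype=np.int64)
        for segs in self.segments:
            for (a, _), (b, _) in zip(segs, segs[1:]):
                C[a - 1, b - 1] += 1
        return C

    def annotation_strings(self) -> dict:
        """Per-node comment payloads for segment-annotated Newick output."""
        out = {}
        for v, segs in enumerate(self.segments):
            if segs:
                out[v] = "hist=" + ",".join(f"{s}:{d:.17g}" for s, d in segs)
        return out
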