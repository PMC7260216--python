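"""Free-parameter space for SSE models: naming, tying and fixing.

Canonical parameter names are ``lam1..lamk``, ``mu1..muk`` and the
off-diagonal transition rates ``q12, q13, ...`` (``q{i}_{j}`` when k > 9).
A :class:`SSEParamSpace` maps a free vector to an :class:`SSEParams`
bundle; *tying* makes several named parameters share one free value
(hidden-regime models are built this way), *fixing* pins a parameter to a
constant (e.g. forbidden transitions at 0).
"""

from __future__ import annotations

import numpy as np

from ..states import SSEParams, ValidationError

__all__ = ["SSEParamSpace", "qname"]


def qname(i: int, j: int, k: int) -> str:
    return f"q{i}{j}" if k <= 9 else f"q{i}_{j}"


class SSEParamSpace:
    """Mapping between a free parameter vector and full SSE rates.

    Parameters
    ----------
    k : number of states.
    tie : dict name -> name; each key takes the value of (the resolution
        of) its target.  Chains are allowed; cycles are an error.
    fix : dict name -> value; fixed parameters are excluded from the free
        vector.  A tied target must not itself be tied away or fixed
        differently than expected — every canonical parameter must resolve
        to exactly one free slot or one fixed constant (a partition).
    """

    def __init__(self, k: int, tie: dict | None = None, fix: dict | None = None):
        self.k = int(k)
        tie = dict(tie or {})
        fix = dict(fix or {})
        names = [f"lam{i}" for i in range(1, k + 1)]
        names += [f"mu{i}" for i in range(1, k + 1)]
        names += [qname(i, j, k) for i in range(1, k + 1)
                  for j in range(1, k + 1) if i != j]
        self.names = names
        known = set(names)
        for d in (tie, fix):
            unknown = set(d) - known
            if unknown:
                raise ValidationError(f"unknown parameter names: {sorted(unknown)}")
        if set(tie) & set(fix):
            raise ValidationError("a parameter cannot be both tied and fixed")

        def resolve(name, seen=()):
            if name in seen:
                raise ValidationError(f"tying cycle through {name!r}")
            if name in tie:
                return resolve(tie[name], seen + (name,))
            return name

        self._rep = {n: resolve(n) for n in names}
        for n, r in self._rep.items():
            if r in fix and n != r:
                # tied into a fixed parameter: treat as fixed
                pass
        self.fixed = {n: float(fix[self._rep[n]]) for n in names
                      if self._rep[n] in fix}
        self.free_names = [n for n in names
                           if self._rep[n] == n and n not in fix]
        self._free_index = {n: i for i, n in enumerate(self.free_names)}

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def value_of(self, name: str, x: np.ndarray) -> float:
        rep = self._rep[name]
        if rep in self.fixed:
            return self.fixed[rep]
        return float(x[self._free_index[rep]])

    def to_params(self, x) -> SSEParams:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise ValidationError(
                f"expected free vector of length {self.n_free}, got {x.shape}")
        k = self.k
        lam = np.array([self.value_of(f"lam{i}", x) for i in range(1, k + 1)])
        mu = np.array([self.value_of(f"mu{i}", x) for i in range(1, k + 1)])
        Q = np.zeros((k, k))
        for i in range(1, k + 1):
            for j in range(1, k + 1):
                if i != j:
                    Q[i - 1, j - 1] = self.value_of(qname(i, j, k), x)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return SSEParams(k, lam, mu, Q)

    def to_vector(self, params: SSEParams) -> np.ndarray:
        """Free vector matching ``params`` (tied slots take the
        representative's value; fixed slots are checked loosely)."""
        vals = {}
        k = self.k
        for i in range(1, k + 1):
            vals[f"lam{i}"] = params.lam[i - 1]
            vals[f"mu{i}"] = params.mu[i - 1]
            for j in range(1, k + 1):
                if i != j:
                    vals[qname(i, j, k)] = params.Q[i - 1, j - 1]
        return np.array([vals[n] for n in self.free_names])

    def describe(self) -> dict:
        return {"k": self.k, "free": list(self.free_names),
                "fixed": dict(self.fixed),
                "tied": {n: r for n, r in self._rep.items() if n != r}}

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SSEParamSpace k={self.k} free={self.n_free}>"
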