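"""Hidden-regime (HiSSE-style) expansion of an observed-state SSE model.

An observed k-state character is expanded to ``k * n_hidden`` states;
expanded state ``(s, h)`` gets id ``(s - 1) * n_hidden + h``.  Tips
observed in state ``s`` become ambiguous over ``{(s, 1), ..., (s, H)}``,
and the plain MuSSE machinery runs unchanged on the expanded state space
with parameters tied:

* observed-state transition rates are shared across hidden regimes
  (one free rate per ordered observed pair),
* hidden-regime switching is a single global rate (``alpha``),
* simultaneous observed+hidden changes are fixed at zero,
* diversification rates follow the requested model —
  ``"unconstrained"``: lam/mu free per (observed state, hidden regime);
  ``"constrained"``: lam/mu tied across observed states within a hidden
  regime (rates differ only between hidden regimes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..states import TipStateMap, ValidationError
from .paramspace import SSEParamSpace, qname

__all__ = ["HiddenSpec", "expand_hidden"]


@dataclass(frozen=True)
class HiddenSpec:
    n_observed: int
    n_hidden: int
    model: str = "unconstrained"   # or "constrained"

    def __post_init__(self):
        if self.n_observed < 1 or self.n_hidden < 1:
            raise ValidationError("state counts must be >= 1")
        if self.model not in ("unconstrained", "constrained"):
            raise ValidationError("model must be 'unconstrained' or 'constrained'")

    @property
    def k_expanded(self) -> int:
        return self.n_observed * self.n_hidden

    def state_id(self, s: int, h: int) -> int:
        """Expanded 1-based id of observed state s in hidden regime h."""
        return (s - 1) * self.n_hidden + h

    def observed_of(self, e: int) -> int:
        return (e - 1) // self.n_hidden + 1

    def hidden_of(self, e: int) -> int:
        return (e - 1) % self.n_hidden + 1


def expand_hidden(spec: HiddenSpec, base_states: TipStateMap):
    """Expand tip states and build the tied parameter space.

    Returns ``(space, expanded_states)``.  With ``n_hidden=1`` the
    expansion is the identity and the space reduces to plain MuSSE.
    """
    if base_states.k != spec.n_observed:
        raise ValidationError("base_states.k != spec.n_observed")
    K = spec.k_expanded
    H = spec.n_hidden

    expanded = {}
    for label, st in base_states.items():
        expanded[label] = {spec.state_id(s, h) for s in st for h in range(1, H + 1)}
    states = TipStateMap(expanded, K)

    tie: dict = {}
    fix: dict = {}
    # diversification-rate tying
    for s in range(1, spec.n_observed + 1):
        for h in range(1, H + 1):
            e = spec.state_id(s, h)
            if spec.model == "constrained" and s > 1:
                tie[f"lam{e}"] = f"lam{spec.state_id(1, h)}"
                tie[f"mu{e}"] = f"mu{spec.state_id(1, h)}"
    # transition-rate structure
    for ei in range(1, K + 1):
        for ej in range(1, K + 1):
            if ei == ej:
                continue
            si, hi = spec.observed_of(ei), spec.hidden_of(ei)
            sj, hj = spec.observed_of(ej), spec.hidden_of(ej)
            name = qname(ei, ej, K)
            if si != sj and hi != hj:
                fix[name] = 0.0                       # no dual transitions
            elif si == sj:
                # hidden switch: one global rate alpha = q[(1,1)->(1,2)]
                alpha = qname(spec.state_id(1, 1), spec.state_id(1, 2), K)
                if name != alpha:
                    tie[name] = alpha
            elif hi != 1:                             # observed move, same regime
                tie[name] = qname(spec.state_id(si, 1), spec.state_id(sj, 1), K)
    space = SSEParamSpace(K, tie=tie, fix=fix)
    return space, states
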