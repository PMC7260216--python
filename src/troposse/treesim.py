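"""Forward simulation of trees under a k-state birth-death process, and
synthetic trait tables with a known rate-generating function.

The tree simulator is a standard Gillespie-style event simulation: each
lineage in state ``s`` waits an exponential time with total rate
``lam_s + mu_s + sum_j q_sj`` and then speciates, dies, or changes state.
The full (unpruned) character history is recorded, so downstream stages —
the DR statistic, SSE fits, stochastic mapping — can be validated against
exact ground truth.  Extinct lineages are pruned from the returned tree;
the history stays on the unpruned tree.

Trait tables emulate the structure of a reef-fish predictor dataset: a
six-level trophic guild, lognormal maximum body length, categorical
activity/water-column/basin variables and independent draws for the
geographic columns, with a latent per-species diversification rate equal
to a declared function of guild and size times gamma-distributed
multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import CharacterHistory, SSEParams, TipStateMap, ValidationError
from .trees import PhyloTree

__all__ = [
    "GUILDS", "SimOutcome", "TraitGenSpec", "CladeExtinctError",
    "simulate_mbd_tree", "simulate_tree_set", "simulate_trait_table",
    "constant_rate", "guild_size_rate",
]

#: Trophic guild codes: generalized carnivores, mobile invertivores,
#: omnivores, planktivores, sessile invertivores, herbivores/detritivores.
GUILDS = ("GC", "MI", "OM", "PK", "SI", "HD")


class CladeExtinctError(RuntimeError):
    """The simulated clade died out in every one of ``retries`` attempts."""

    def __init__(self, retries: int):
        self.retries = retries
        super().__init__(f"clade died in all {retries} attempts")


@dataclass
class SimOutcome:
    """One simulated tree plus its exact generating history.

    ``tree``/``states`` describe the pruned (surviving) tree; ``history_tree``
    and ``true_history`` describe the unpruned process, and
    ``true_transitions`` counts every character-change event that occurred,
    including on extinct lineages.  ``tree`` is ``None`` when fewer than two
    lineages survived (possible under a ``max_time`` stop).
    """

    tree: PhyloTree | None
    states: TipStateMap | None
    history_tree: PhyloTree | None
    true_history: CharacterHistory | None
    true_transitions: np.ndarray
    seed: int
    n_surviving: int
    n_retries: int = 0


class _Lineage:
    __slots__ = ("t0", "s0", "events", "t1", "fate", "children")

    def __init__(self, t0: float, s0: int):
        self.t0 = t0
        self.s0 = s0
        self.events: list = []      # (time, new_state)
        self.t1 = np.nan
        self.fate = "live"          # live | spec | ext
        self.children: tuple = ()

    @property
    def state(self) -> int:
        return self.events[-1][1] if self.events else self.s0


def simulate_mbd_tree(params: SSEParams, root_state: int, *,
                      max_time: float | None = None,
                      n_extant: int | None = None,
                      seed: int | None = None,
                      start: str = "crown",
                      max_retries: int = 1000,
                      max_events: int = 2_000_000) -> SimOutcome:
    """Simulate one multi-state birth-death tree.

    Exactly one of ``max_time`` (run to a fixed time horizon) or
    ``n_extant`` (stop the first moment the extant lineage count hits n,
    retrying on total extinction) must be given.  ``start='crown'`` begins
    with two lineages in ``root_state`` (SSE likelihoods condition on the
    crown); ``start='stem'`` begins with one.
    """
    if (max_time is None) == (n_extant is None):
        raise ValidationError("give exactly one of max_time or n_extant")
    if max_time is not None and max_time <= 0:
        raise ValidationError("max_time must be positive")
    if n_extant is not None and n_extant < 2:
        raise ValidationError("n_extant must be >= 2")
    if not 1 <= root_state <= params.k:
        raise ValidationError(f"root_state must be in 1..{params.k}")
    if start not in ("crown", "stem"):
        raise ValidationError("start must be 'crown' or 'stem'")
    rng = np.random.default_rng(seed)

    attempts = 0
    while True:
        attempts += 1
        # total extinction before the horizon is a valid outcome under a
        # max_time stop; under n_extant it triggers a retry
        lineages = _gillespie(params, root_state, max_time, n_extant, rng,
                              start, max_events,
                              allow_extinct=max_time is not None)
        if lineages is not None:
            break
        if attempts >= max_retries:
            raise CladeExtinctError(attempts)

    return _assemble(params, lineages, seed, attempts - 1, start, root_state)


def _gillespie(params, root_state, max_time, n_extant, rng, start,
               max_events, allow_extinct=False):
    """Run one attempt; return the lineage list, or None on total
    extinction under an ``n_extant`` stop (or when retrying is wanted)."""
    k = params.k
    lam, mu = params.lam, params.mu
    qoff = params.Q.copy()
    np.fill_diagonal(qoff, 0.0)
    qtot = qoff.sum(axis=1)
    total = lam + mu + qtot                      # per-lineage rate by state

    lineages: list[_Lineage] = [_Lineage(0.0, root_state)]
    if start == "crown":
        lineages.append(_Lineage(0.0, root_state))
    # active lineage ids grouped by current 0-based state
    by_state: list[list[int]] = [[] for _ in range(k)]
    for i, ln in enumerate(lineages):
        by_state[ln.s0 - 1].append(i)
    n_active = len(lineages)
    if n_extant is not None and n_active >= n_extant:
        raise ValidationError("n_extant not larger than the starting lineage count")

    t = 0.0
    for _ in range(max_events):
        counts = np.array([len(b) for b in by_state], dtype=float)
        R = float(counts @ total)
        if R <= 0:
            if max_time is not None:
                t = max_time
                break
            raise ValidationError(
                "all event rates are zero before reaching n_extant")
        t_next = t + rng.exponential(1.0 / R)
        if max_time is not None and t_next >= max_time:
            t = max_time
            break
        t = t_next
        # choose state class, then a uniform lineage within it
        s = int(rng.choice(k, p=counts * total / R))
        bucket = by_state[s]
        pos = int(rng.integers(len(bucket)))
        lid = bucket[pos]
        u = rng.random() * total[s]
        if u < lam[s]:                                        # speciation
            bucket[pos] = bucket[-1]
            bucket.pop()
            ln = lineages[lid]
            ln.t1, ln.fate = t, "spec"
            c1, c2 = len(lineages), len(lineages) + 1
            lineages.append(_Lineage(t, s + 1))
            lineages.append(_Lineage(t, s + 1))
            ln.children = (c1, c2)
            by_state[s].extend([c1, c2])
            n_active += 1
            if n_extant is not None and n_active == n_extant:
                break
        elif u < lam[s] + mu[s]:                              # extinction
            bucket[pos] = bucket[-1]
            bucket.pop()
            ln = lineages[lid]
            ln.t1, ln.fate = t, "ext"
            n_active -= 1
            if n_active == 0:
                if allow_extinct:
                    return lineages
                return None
        else:                                                 # transition
            w = qoff[s].copy()
            j = int(rng.choice(k, p=w / w.sum()))
            bucket[pos] = bucket[-1]
            bucket.pop()
            by_state[j].append(lid)
            lineages[lid].events.append((t, j + 1))
    else:
        raise RuntimeError(f"event budget ({max_events}) exhausted")

    for b in by_state:                      # cut survivors at the stop time
        for lid in b:
            lineages[lid].t1 = t
    return lineages


def _assemble(params, lineages, seed, n_retries, start, root_state) -> SimOutcome:
    k = params.k
    # exact transition counts over the whole (unpruned) process
    trans = np.zeros((k, k), dtype=np.int64)
    for ln in lineages:
        prev = ln.s0
        for _, s in ln.events:
            trans[prev - 1, s - 1] += 1
            prev = s

    live = [i for i, ln in enumerate(lineages) if ln.fate == "live"]
    n_surv = len(live)
    tip_name: dict[int, str] = {}
    it_live = iter(range(1, n_surv + 1))
    it_ext = iter(range(1, len(lineages) + 1))
    for i, ln in enumerate(lineages):
        if ln.fate == "live":
            tip_name[i] = f"t{next(it_live)}"
        elif ln.fate == "ext":
            tip_name[i] = f"x{next(it_ext)}"

    history_tree, history = _build_history_tree(lineages, k, start, root_state,
                                                tip_name)
    tree, states = _build_pruned(lineages, k, start, tip_name)
    return SimOutcome(tree=tree, states=states, history_tree=history_tree,
                      true_history=history, true_transitions=trans,
                      seed=seed if seed is not None else -1,
                      n_surviving=n_surv, n_retries=n_retries)


def _segments(ln: _Lineage) -> list:
    segs = []
    t_prev, s_prev = ln.t0, ln.s0
    for te, se in ln.events:
        segs.append((s_prev, te - t_prev))
        t_prev, s_prev = te, se
    segs.append((s_prev, ln.t1 - t_prev))
    return segs


def _build_history_tree(lineages, k, start, root_state, tip_name):
    """PhyloTree + CharacterHistory for the full unpruned process.

    Returns (None, None) when the process never produced a binary tree
    (a stem start whose first lineage never speciated).
    """
    if start == "crown":
        root_children = (0, 1)
    else:
        if lineages[0].fate != "spec":
            return None, None
        root_children = lineages[0].children

    order: list = []           # postorder entries: lineage id or "ROOT"

    def walk(lid):
        ln = lineages[lid]
        if ln.fate == "spec":
            walk(ln.children[0])
            walk(ln.children[1])
        order.append(lid)

    if start == "crown":
        walk(0)
        walk(1)
        order.append("ROOT")
    else:
        walk(root_children[0])
        walk(root_children[1])
        order.append(0)        # lineage 0's end is the root node

    n = len(order)
    index = {key: i for i, key in enumerate(order)}
    parent = np.full(n, -1, dtype=np.int64)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    labels: list = [None] * n
    node_states = np.zeros(n, dtype=np.int64)
    segments: list = [[] for _ in range(n)]

    for i, key in enumerate(order):
        if key == "ROOT":
            left[i], right[i] = index[0], index[1]
            parent[index[0]] = parent[index[1]] = i
            node_states[i] = root_state
            continue
        ln = lineages[key]
        blen[i] = ln.t1 - ln.t0
        node_states[i] = ln.state
        segments[i] = _segments(ln)
        if ln.fate == "spec":
            c1, c2 = ln.children
            left[i], right[i] = index[c1], index[c2]
            parent[index[c1]] = parent[index[c2]] = i
        else:
            labels[i] = tip_name[key]

    tree = PhyloTree(parent, left, right, blen, labels)
    hist = CharacterHistory(k=k, node_states=node_states, segments=segments)
    return tree, hist


def _build_pruned(lineages, k, start, tip_name):
    """Reconstructed tree of surviving lineages (unifurcations suppressed,
    stem dropped), with a singleton TipStateMap.  None if < 2 survivors."""

    def reduce(lid):
        """-> (label_or_subtree, pendant_length, tip_states) or None."""
        ln = lineages[lid]
        span = ln.t1 - ln.t0
        if ln.fate == "live":
            return ("tip", lid, span)
        if ln.fate == "ext":
            return None
        l = reduce(ln.children[0])
        r = reduce(ln.children[1])
        if l is None and r is None:
            return None
        if l is None or r is None:
            kind, payload, plen = l if l is not None else r
            return (kind, payload, plen + span)
        return ("node", (l, r), span)

    roots = []
    if start == "crown":
        for lid in (0, 1):
            sub = reduce(lid)
            if sub is not None:
                roots.append(sub)
    else:
        sub = reduce(0)
        if sub is not None:
            roots.append(sub)

    if not roots:
        return None, None
    if len(roots) == 2:
        crown = ("node", (roots[0], roots[1]), 0.0)
    elif roots[0][0] == "node":
        crown = roots[0]               # one crown side died; its sibling's
                                       # first surviving split becomes the root
    else:
        return None, None              # a single surviving lineage: no tree

    parent_l: list = []
    left_l: list = []
    right_l: list = []
    blen_l: list = []
    labels_l: list = []

    def emit(node, pendant_override=None):
        kind, payload, plen = node
        if kind == "tip":
            idx = len(parent_l)
            parent_l.append(-1); left_l.append(-1); right_l.append(-1)
            blen_l.append(plen if pendant_override is None else pendant_override)
            labels_l.append(tip_name[payload])
            return idx
        li = emit(payload[0])
        ri = emit(payload[1])
        idx = len(parent_l)
        parent_l.append(-1); left_l.append(-1); right_l.append(-1)
        blen_l.append(plen if pendant_override is None else pendant_override)
        labels_l.append(None)
        left_l[idx], right_l[idx] = li, ri
        parent_l[li] = parent_l[ri] = idx
        return idx

    emit(crown, pendant_override=0.0)
    tree = PhyloTree(np.array(parent_l), np.array(left_l), np.array(right_l),
                     np.array(blen_l), labels_l)
    states = {tip_name[i]: lineages[i].state
              for i, ln in enumerate(lineages) if lineages[i].fate == "live"}
    states = {lbl: st for lbl, st in states.items() if lbl in set(tree.tip_labels)}
    return tree, TipStateMap(states, k)


def simulate_tree_set(params: SSEParams, root_state: int, *, n_trees: int,
                      seed: int | None = None, **stop) -> list:
    """Simulate ``n_trees`` independent trees; per-tree seeds are derived
    deterministically from the master seed."""
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_trees)
    out = []
    for i, cs in enumerate(child_seeds):
        try:
            out.append(simulate_mbd_tree(params, root_state, seed=int(cs), **stop))
        except CladeExtinctError as e:
            raise CladeExtinctError(e.retries) from RuntimeError(
                f"replicate {i} of {n_trees} failed")
    return out


# --------------------------------------------------------------------- traits

def constant_rate(c: float):
    """rate_fn giving every species the same expected rate ``c``."""
    return lambda guild, size: c


def guild_size_rate(base: dict, size_ref: float = 25.0, size_exp: float = 0.0):
    """rate_fn: ``base[guild] * (size / size_ref) ** size_exp``.

    ``base`` maps guild code -> rate at the reference size (Myr^-1).
    """
    def fn(guild, size):
        return base[guild] * (size / size_ref) ** size_exp
    return fn


@dataclass
class TraitGenSpec:
    """Configuration of the synthetic trait-table generator.

    The latent per-species rate is ``rate_fn(guild, size)`` times
    multiplicative gamma noise with unit mean and shape ``noise_shape``
    (larger shape = less noise).  Geographic columns are independent draws
    from fixed, documented distributions — controllable signal/noise for
    the boosting stage, not a spatially explicit range model.
    """

    n_species: int
    guild_probs: tuple = (0.25, 0.25, 0.12, 0.15, 0.08, 0.15)  # over GUILDS
    size_log_mean: float = float(np.log(15.0))   # lognormal body length, cm
    size_log_sd: float = 0.9
    rate_fn: object = field(default_factory=lambda: constant_rate(0.1))
    noise_shape: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        p = np.asarray(self.guild_probs, dtype=float)
        if p.shape != (6,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("guild_probs must be a 6-vector summing to 1")
        if self.noise_shape <= 0:
            raise ValidationError("noise_shape must be positive")


_ACTIVITY = (("diurnal", "nocturnal", "both"), (0.60, 0.25, 0.15))
_POSITION = (("benthic", "benthopelagic", "pelagic"), (0.55, 0.30, 0.15))
_BASIN = (("Atlantic", "Indo-Pacific", "both"), (0.25, 0.60, 0.15))


def simulate_trait_table(spec: TraitGenSpec, guilds: dict | None = None):
    """Generate a trait table and the latent true rates.

    Returns ``(table, true_rates)``: a DataFrame with the ten predictor
    columns (species id as index) and a Series of latent rates (Myr^-1).
    ``guilds`` optionally fixes the trophic column (species -> guild code),
    e.g. to match simulated tip states; its keys define the species set.
    """
    rng = np.random.default_rng(spec.seed)
    if guilds is not None:
        species = list(guilds)
        trophic = [guilds[s] for s in species]
        bad = set(trophic) - set(GUILDS)
        if bad:
            raise ValidationError(f"unknown guild codes: {sorted(bad)}")
        n = len(species)
    else:
        n = spec.n_species
        species = [f"s{i + 1:05d}" for i in range(n)]
        trophic = [GUILDS[i] for i in rng.choice(6, size=n, p=np.asarray(spec.guild_probs))]

    size = np.exp(rng.normal(spec.size_log_mean, spec.size_log_sd, size=n))
    activity = [ _ACTIVITY[0][i] for i in rng.choice(3, size=n, p=_ACTIVITY[1]) ]
    position = [ _POSITION[0][i] for i in rng.choice(3, size=n, p=_POSITION[1]) ]
    basin = [ _BASIN[0][i] for i in rng.choice(3, size=n, p=_BASIN[1]) ]
    rng_range = np.maximum(1, np.rint(np.exp(rng.normal(np.log(30.0), 1.0, size=n)))).astype(int)
    abs_lat = rng.uniform(0.0, 35.0, size=n)
    dist_iaa = rng.uniform(0.0, 14000.0, size=n)
    sst = 28.5 - 0.28 * abs_lat + rng.normal(0.0, 1.0, size=n)
    prprod = np.exp(rng.normal(np.log(500.0), 0.6, size=n))

    expected = np.array([spec.rate_fn(g, s) for g, s in zip(trophic, size)])
    if np.any(expected <= 0):
        raise ValidationError("rate_fn must return strictly positive rates")
    noise = rng.gamma(spec.noise_shape, 1.0 / spec.noise_shape, size=n)
    true_rates = pd.Series(expected * noise, index=species, name="true_rate")

    table = pd.DataFrame({
        "trophic": pd.Categorical(trophic, categories=list(GUILDS)),
        "size": size,
        "activity": pd.Categorical(activity, categories=list(_ACTIVITY[0])),
        "position": pd.Categorical(position, categories=list(_POSITION[0])),
        "range": rng_range,
        "basin": pd.Categorical(basin, categories=list(_BASIN[0])),
        "abs_lat": abs_lat,
        "dist_iaa": dist_iaa,
        "sst": sst,
        "prprod": prprod,
    }, index=pd.Index(species, name="species"))
    return table, true_rates
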