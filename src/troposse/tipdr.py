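"""Tip-level speciation-rate estimation via the DR (inverse equal-splits)
statistic, with median pooling across a tree set.

For tip *i* with root path edge lengths ``l_1 (pendant), l_2, ..., l_N``
the equal-splits measure is ``ES_i = sum_j l_j * 2**-(j-1)`` and the DR
statistic is ``1 / ES_i``.  DR estimates *speciation* rate (not net
diversification); columns are labeled accordingly.  Externally computed
per-tip rates (e.g. from a Bayesian rate-shift analysis) can be supplied
in the same table schema wherever a TipRateTable is consumed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trees import PhyloTree

__all__ = ["equal_splits", "dr_statistic", "pool_median", "read_rates", "write_rates"]


def equal_splits(tree: PhyloTree, tip: str) -> float:
    """Equal-splits measure (Myr) for one tip.

    Invariant to tree rotation; errors if the whole root path has zero
    length (DR undefined).
    """
    v = tree.tip_index(tip)
    es = 0.0
    w = 1.0
    node = v
    while tree.parent[node] >= 0:   # stem edge above the root is excluded
        es += tree.blen[node] * w
        w *= 0.5
        node = int(tree.parent[node])
    if es <= 0.0:
        raise ValueError(f"tip {tip!r} has an all-zero root path; ES undefined")
    return float(es)


def dr_statistic(tree: PhyloTree) -> dict:
    """DR = 1/ES for every tip; returns label -> rate (Myr^-1)."""
    return {label: 1.0 / equal_splits(tree, label) for label in tree.tip_labels}


def pool_median(maps: list) -> pd.DataFrame:
    """Pool per-tip rate maps over a tree set by the row-wise median.

    All maps must share one tip-label set.  Returns a TipRateTable: one row
    per tip, one ``tree_<i>`` column per input map plus a ``median``
    column (the standard midpoint median for even counts).
    """
    if not maps:
        raise ValueError("no rate maps given")
    ref = set(maps[0])
    for i, m in enumerate(maps[1:], start=1):
        diff = ref ^ set(m)
        if diff:
            raise ValueError(
                f"tip label sets differ between map 0 and map {i}: "
                f"{sorted(diff)[:10]}")
    labels = sorted(ref)
    data = {f"tree_{i}": [m[l] for l in labels] for i, m in enumerate(maps)}
    table = pd.DataFrame(data, index=pd.Index(labels, name="tip"))
    table["median"] = table.median(axis=1)
    return table


def write_rates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_rates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
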