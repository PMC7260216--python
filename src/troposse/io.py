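"""File formats shared by all stages: Newick trees, tab-separated state
and trait tables, JSON parameter/fit/manifest files, and segment-annotated
Newick for character histories.

Every table is TSV with a header row (UTF-8); every tree is Newick with
branch lengths in Myr.  Character histories are written as Newick comments
of the form ``[&hist=state:duration,...]`` after each branch length,
segments ordered parent -> child.
"""

from __future__ import annotations

import hashlib
import json

import dendropy
import numpy as np
import pandas as pd

from .states import CharacterHistory, SSEParams, TipStateMap, ValidationError
from .trees import PhyloTree

__all__ = [
    "read_newick", "write_newick", "read_tip_states", "write_tip_states",
    "read_trait_table", "write_trait_table", "read_params", "write_params",
    "write_history_newick", "read_history_newick", "write_json", "read_json",
    "file_sha256", "derive_seed",
]


def derive_seed(master: int, *parts) -> int:
    """Deterministic child seed (< 2^31) from a master seed and stage tags."""
    key = f"{master}|" + "|".join(str(p) for p in parts)
    h = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ------------------------------------------------------------------- trees

def read_newick(path) -> PhyloTree:
    return PhyloTree.read(path)


def write_newick(tree: PhyloTree, path) -> None:
    tree.write(path)


# ------------------------------------------------------------------ states

def write_tip_states(states: TipStateMap, path) -> None:
    """TSV ``tip<TAB>state``; ambiguous sets joined with ``|``."""
    with open(path, "w") as fh:
        fh.write("tip\tstate\n")
        for label, st in states.items():
            fh.write(f"{label}\t" + "|".join(str(s) for s in sorted(st)) + "\n")


def read_tip_states(path, k: int) -> TipStateMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["tip", "state"]:
        raise ValidationError(f"bad tip-state header in {path}")
    return TipStateMap(
        {row.tip: {int(s) for s in str(row.state).split("|")}
         for row in df.itertuples()}, k)


# ------------------------------------------------------------------ tables

def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_trait_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_params(params: SSEParams, path) -> None:
    write_json(params.to_dict(), path)


def read_params(path) -> SSEParams:
    return SSEParams.from_dict(read_json(path))


# -------------------------------------------------- annotated histories

def write_history_newick(tree: PhyloTree, history: CharacterHistory, path) -> None:
    # full float precision so segment durations re-sum to the branch
    # lengths within the validation tolerance after a round-trip
    with open(path, "w") as fh:
        fh.write(tree.to_newick(precision=17,
                                annotations=history.annotation_strings()) + "\n")


def read_history_newick(path, k: int):
    """Read a segment-annotated Newick back into (tree, history)."""
    with open(path) as fh:
        text = fh.read()
    dt = dendropy.Tree.get(data=text, schema="newick",
                           preserve_underscores=True,
                           suppress_internal_node_taxa=True,
                           extract_comment_metadata=False)
    tree = PhyloTree.from_dendropy(dt)
    nodes = list(dt.postorder_node_iter())
    segments: list = [[] for _ in range(tree.n_nodes)]
    node_states = np.zeros(tree.n_nodes, dtype=np.int64)
    for i, nd in enumerate(nodes):
        payload = None
        for c in nd.comments:
            if c.startswith("&hist="):
                payload = c[len("&hist="):]
        if payload is None:
            continue
        segs = []
        for part in payload.split(","):
            s, d = part.split(":")
            segs.append((int(s), float(d)))
        segments[i] = segs
        node_states[i] = segs[-1][0]
    # root state: first segment of either child when the root edge is bare
    root = tree.root
    if not segments[root]:
        child = int(tree.left[root])
        if segments[child]:
            node_states[root] = segments[child][0][0]
    else:
        node_states[root] = segments[root][-1][0]
    history = CharacterHistory(k=k, node_states=node_states, segments=segments)
    history.validate(tree)
    return tree, history
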