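"""Clonal ordering of lesions from an allele-fraction matrix.

Lesions with identical SNV presence patterns are merged into one node;
nodes are ordered by strict containment of their presence sets (Hasse
diagram).  Edges are annotated with SNVs newly present in the child
('+') and shared SNVs whose AF increased by at least ``increase_ratio``
fold ('up').
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AFMatrix",
    "CloneNode",
    "CloneEdge",
    "CloneTree",
    "binarize",
    "truncal_set",
    "order_lesions",
    "assign_sample",
]

DEFAULT_PRESENCE_THRESHOLD = 0.01   # the deep-seq detection cutoff
DEFAULT_INCREASE_RATIO = 1.5
DEFAULT_TRUNCAL_MAX_FOLD_SPREAD = 1.5


@dataclass(frozen=True)
class AFMatrix:
    """Lesions x variants allele-fraction table."""

    values: pd.DataFrame  # index: lesion ids, columns: variant ids

    def __post_init__(self):
        vals = self.values.to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError("empty AF matrix")
        if np.any((vals < 0) | (vals > 1)) or not np.all(np.isfinite(vals)):
            raise ValueError("AFs must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "AFMatrix":
        """Build from {lesion: {variant: af}} (missing entries are 0)."""
        return cls(pd.DataFrame(d).T.fillna(0.0))

    @property
    def lesions(self) -> list:
        return list(self.values.index)

    @property
    def variants(self) -> list:
        return list(self.values.columns)


def binarize(matrix: AFMatrix, threshold: float = DEFAULT_PRESENCE_THRESHOLD) -> pd.DataFrame:
    """Boolean presence matrix: AF >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return matrix.values >= threshold


def truncal_set(
    matrix: AFMatrix,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    max_fold_spread: float | None = DEFAULT_TRUNCAL_MAX_FOLD_SPREAD,
) -> frozenset:
    """Variants present in every lesion.

    With ``max_fold_spread`` set (default 1.5), a variant additionally
    must show approximately the same AF in all lesions, i.e. a max/min
    AF ratio at most that value; pass ``None`` for pure presence.
    """
    presence = binarize(matrix, threshold)
    everywhere = presence.all(axis=0)
    result = set()
    for variant in matrix.variants:
        if not everywhere[variant]:
            continue
        if max_fold_spread is not None:
            afs = matrix.values[variant]
            if afs.max() > max_fold_spread * afs.min():
                continue
        result.add(variant)
    return frozenset(result)


@dataclass(frozen=True)
class CloneNode:
    node_id: str
    lesions: tuple
    presence: frozenset
    afs: dict  # variant -> mean AF over member lesions


@dataclass(frozen=True)
class CloneEdge:
    parent: str
    child: str
    gained: tuple                  # newly present SNVs ('+')
    increased: tuple               # (variant, fold_change) pairs ('up')


@dataclass(frozen=True)
class CloneTree:
    nodes: dict                    # node_id -> CloneNode
    edges: tuple
    roots: tuple

    def children(self, node_id: str) -> list:
        return [e.child for e in self.edges if e.parent == node_id]

    def depth(self, node_id: str) -> int:
        parents = {e.child: e.parent for e in self.edges}
        d = 0
        while node_id in parents:
            node_id = parents[node_id]
            d += 1
        return d

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "nodes": [
                {
                    "id": n.node_id,
                    "lesions": list(n.lesions),
                    "snvs": sorted(n.presence),
                    "mean_afs": {v: round(a, 6) for v, a in sorted(n.afs.items())},
                }
                for n in (self.nodes[k] for k in sorted(self.nodes))
            ],
            "edges": [
                {
                    "parent": e.parent,
                    "child": e.child,
                    "gained": list(e.gained),
                    "increased": [{"variant": v, "fold": round(f, 4)} for v, f in e.increased],
                }
                for e in self.edges
            ],
            "roots": list(self.roots),
        }
        return json.dumps(payload, indent=indent)

    def to_dot(self) -> str:
        lines = ["digraph clones {"]
        for k in sorted(self.nodes):
            lines.append(f'  "{k}";')
        for e in self.edges:
            ann = [f"+{v}" for v in e.gained] + [f"^{v}" for v, _ in e.increased]
            lines.append(f'  "{e.parent}" -> "{e.child}" [label="{" ".join(ann)}"];')
        lines.append("}")
        return "\n".join(lines)


def order_lesions(
    matrix: AFMatrix,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    increase_ratio: float = DEFAULT_INCREASE_RATIO,
) -> CloneTree:
    """Build the containment (Hasse) diagram over grouped lesions.

    Deterministic: groups are labeled by their sorted member lesions and
    ties are resolved lexicographically.  Inputs whose presence sets do
    not form a chain yield a forest.
    """
    presence = binarize(matrix, threshold)

    groups: dict = {}
    for lesion in matrix.lesions:
        key = frozenset(v for v in matrix.variants if presence.loc[lesion, v])
        groups.setdefault(key, []).append(lesion)

    nodes = {}
    for key, lesions in groups.items():
        members = tuple(sorted(lesions))
        node_id = ",".join(members)
        afs = {v: float(matrix.values.loc[list(members), v].mean()) for v in matrix.variants}
        nodes[node_id] = CloneNode(node_id=node_id, lesions=members, presence=key, afs=afs)

    ids = sorted(nodes)
    edges = []
    for child in ids:
        cset = nodes[child].presence
        parents = [
            p for p in ids
            if p != child
            and nodes[p].presence < cset
            # Hasse condition: no intermediate node between parent and child
            and not any(
                nodes[p].presence < nodes[q].presence < cset
                for q in ids if q not in (p, child)
            )
        ]
        for parent in sorted(parents):
            pnode, cnode = nodes[parent], nodes[child]
            gained = tuple(sorted(cset - pnode.presence))
            increased = tuple(
                (v, cnode.afs[v] / pnode.afs[v])
                for v in sorted(cset & pnode.presence)
                if pnode.afs[v] > 0 and cnode.afs[v] >= increase_ratio * pnode.afs[v]
            )
            edges.append(CloneEdge(parent=parent, child=child, gained=gained, increased=increased))

    children = {e.child for e in edges}
    roots = tuple(sorted(i for i in ids if i not in children))
    return CloneTree(nodes=nodes, edges=tuple(edges), roots=roots)


def assign_sample(
    sample_afs: dict,
    tree: CloneTree,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> str | None:
    """Deepest node whose full SNV presence set the sample carries.

    A sample carrying none of any root's SNVs is unassigned (None); a
    sample carrying some root SNVs but no complete node set falls back
    to the best-overlapping root.
    """
    carried = frozenset(v for v, af in sample_afs.items() if af >= threshold)
    candidates = [k for k, n in tree.nodes.items() if n.presence <= carried]
    if candidates:
        return sorted(candidates, key=lambda k: (-tree.depth(k), k))[0]
    overlaps = {r: len(tree.nodes[r].presence & carried) for r in tree.roots}
    best = max(sorted(overlaps), key=lambda r: overlaps[r])
    if overlaps[best] == 0:
        return None
    return best
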