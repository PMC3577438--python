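"""Neighbor-joining topology estimation with outgroup rooting.

NJ supplies the fixed topology that the dating sampler conditions on; it is
exact on additive distance matrices. The unrooted NJ tree is rooted on the
branch leading to the outgroup's attachment point, with a warning when the
outgroup is not monophyletic in the unrooted tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceMatrix
from .timetree import TimeTree, TreeNode

__all__ = ["BLNode", "nj_tree", "to_timetree"]


@dataclass
class BLNode:
    """Tree node carrying the length of the branch above it (subs/site)."""

    label: Optional[str] = None
    length: float = 0.0
    children: list["BLNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> set[str]:
        if self.is_leaf:
            return {self.label}
        out: set[str] = set()
        for c in self.children:
            out |= c.leaf_labels()
        return out

    def to_newick(self) -> str:
        if self.is_leaf:
            return f"{self.label}:{self.length:.8f}"
        inner = ",".join(c.to_newick() for c in self.children)
        return f"({inner}):{self.length:.8f}"


def _neighbor_joining(D: np.ndarray, labels: list[str]) -> BLNode:
    """Classic NJ; returns an unrooted tree as a trifurcating root."""
    nodes = [BLNode(label=l) for l in labels]
    D = D.copy().astype(float)
    active = list(range(len(labels)))

    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        gi, gj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = BLNode()
        nodes[gi].length = li
        nodes[gj].length = lj
        parent.children = [nodes[gi], nodes[gj]]

        # distances from the new node
        dnew = 0.5 * (D[gi, :] + D[gj, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(parent)
        k = D.shape[0] - 1
        active = [a for a in active if a not in (gi, gj)] + [k]

    i, j, k = active
    # final trifurcation branch lengths
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = BLNode()
    for idx, l in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(l, 0.0)
        root.children.append(nodes[idx])
    return root


def _reroot_on_edge(root: BLNode, target: BLNode) -> BLNode:
    """Root the unrooted tree at the midpoint of the branch above ``target``.

    The BLNode structure is flattened into an undirected edge graph and a
    fresh rooted tree is rebuilt outward from the new root, which avoids any
    in-place pointer surgery.
    """
    adj: dict[int, list[tuple[int, float]]] = {}
    objects: dict[int, BLNode] = {}
    parent_of: dict[int, int] = {}

    def register(n: BLNode) -> None:
        objects[id(n)] = n
        adj.setdefault(id(n), [])
        for c in n.children:
            parent_of[id(c)] = id(n)
            register(c)
            adj[id(n)].append((id(c), c.length))
            adj[id(c)].append((id(n), c.length))

    register(root)
    half = target.length / 2.0
    rid = -1  # synthetic root id
    pid = parent_of[id(target)]
    # remove the split edge and insert the root in its middle
    adj[id(target)] = [(p, l) for p, l in adj[id(target)] if p != pid] + [(rid, half)]
    adj[pid] = [(p, l) for p, l in adj[pid] if p != id(target)] + [(rid, half)]
    adj[rid] = [(id(target), half), (pid, half)]

    def rebuild(nid: int, parent: int, length: float) -> BLNode:
        src = objects.get(nid)
        node = BLNode(label=src.label if src is not None else None, length=length)
        kids = [rebuild(c, nid, l) for c, l in adj[nid] if c != parent]
        if src is not None and src.is_leaf:
            return node
        node.children = kids
        # suppress unary nodes created by removing the old trifurcation
        if len(node.children) == 1:
            child = node.children[0]
            child.length += node.length
            return child
        return node

    new_root = rebuild(rid, parent=rid, length=0.0)
    new_root.length = 0.0
    return new_root


def nj_tree(
    D: DistanceMatrix, outgroup: Sequence[str]
) -> BLNode:
    """Neighbor-joining tree rooted on the outgroup attachment branch.

    With a single outgroup taxon the root bisects its terminal branch; with
    several, the branch above their MRCA in the unrooted tree is used, and a
    warning is issued when the outgroup is not monophyletic there.
    """
    if len(D.taxa) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    outgroup = list(outgroup)
    missing = set(outgroup) - set(D.taxa)
    if missing:
        raise ValueError(f"outgroup taxa not in matrix: {sorted(missing)}")
    unrooted = _neighbor_joining(D.values, list(D.taxa))

    og = set(outgroup)
    target = None
    stack = [unrooted]
    while stack:
        n = stack.pop()
        if n is not unrooted and n.leaf_labels() == og:
            target = n
            break
        stack.extend(n.children)
    if target is None:
        warnings.warn("outgroup not monophyletic; rooting at first outgroup tip")
        stack = [unrooted]
        while stack:
            n = stack.pop()
            if n.is_leaf and n.label == outgroup[0]:
                target = n
                break
            stack.extend(n.children)
    return _reroot_on_edge(unrooted, target)


def to_timetree(bltree: BLNode, rate: Optional[float] = None) -> TimeTree:
    """Convert a rooted branch-length tree into an ultrametric starting tree.

    Node ages are set to the mean root-to-tip residual below each node (in
    subs/site, divided by ``rate`` when given) — a crude clock projection
    used only to initialize the dating sampler.
    """
    scale = 1.0 if rate is None else 1.0 / rate

    def build(n: BLNode) -> tuple[TreeNode, float]:
        if n.is_leaf:
            return TreeNode(age=0.0, label=n.label), 0.0
        built = []
        for c in n.children:
            node, h = build(c)
            built.append((node, h + c.length * scale))
        age = float(np.mean([h for _, h in built]))
        out = TreeNode(age=max(age, max(h for _, h in built) * (1 + 1e-9) + 1e-12))
        for node, _ in built:
            out.add_child(node)
        return out, out.age

    root, _ = build(bltree)
    return TimeTree(root)
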