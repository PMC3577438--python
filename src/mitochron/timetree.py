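"""Dated species trees: a minimal ultrametric tree container and a Yule simulator.

A :class:`TimeTree` is a rooted binary tree whose internal nodes carry ages in
millions of years (mya) with all tips at age 0, the object both simulated as
ground truth and estimated by the dating sampler.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import dendropy

__all__ = ["TreeNode", "TimeTree", "simulate_time_tree"]


@dataclass
class TreeNode:
    """Node of a dated tree. Tips have ``age == 0`` and a taxon ``label``."""

    age: float = 0.0
    label: Optional[str] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class TimeTree:
    """Rooted binary ultrametric tree with node ages in mya (tips at 0).

    Parameters
    ----------
    root : TreeNode
        Root of the tree; every internal node must be older than its children.
    birth_rate : float, optional
        Yule per-lineage birth rate (per my) used to generate the tree, kept
        for provenance when the tree is simulated.
    """

    def __init__(self, root: TreeNode, birth_rate: Optional[float] = None):
        self.root = root
        self.birth_rate = birth_rate
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        """Parse a Newick string with branch lengths into a dated tree.

        Node ages are recovered from root-to-tip path lengths; the tree must
        be ultrametric for the result to validate.
        """
        dt = dendropy.Tree.get(data=newick, schema="newick")
        droot = dt.seed_node

        depths: dict = {droot: 0.0}
        for e in dt.preorder_edge_iter():
            if e.head_node is droot:
                continue
            depths[e.head_node] = depths[e.tail_node] + (e.length or 0.0)
        height = max(depths[l] for l in dt.leaf_node_iter())

        def build(dn) -> TreeNode:
            node = TreeNode(age=height - depths[dn])
            if dn.is_leaf():
                node.age = 0.0
                node.label = dn.taxon.label if dn.taxon else None
            for c in dn.child_nodes():
                node.add_child(build(c))
            return node

        return cls(build(droot))

    # -- iteration ---------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator[TreeNode]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return [l.label for l in self.leaves()]

    @property
    def n_taxa(self) -> int:
        return len(self.leaves())

    @property
    def root_age(self) -> float:
        return self.root.age

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        for n in self.preorder():
            if n.children and len(n.children) != 2:
                raise ValueError("tree must be strictly binary")
            for c in n.children:
                if c.age >= n.age and not (c.is_leaf and n.age > 0):
                    if c.age >= n.age:
                        raise ValueError(
                            f"child age {c.age} not younger than parent age {n.age}"
                        )
        if self.n_taxa < 2:
            raise ValueError("tree needs at least 2 taxa")

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        """All leaves sit at age 0 by construction; always true here, kept as
        an explicit check for trees built from Newick branch lengths."""
        return all(abs(l.age) <= rtol * max(self.root.age, 1.0) for l in self.leaves())

    # -- derived quantities ------------------------------------------------

    def tmrca(self, label_a: str, label_b: str) -> float:
        """Age of the MRCA of two labelled tips."""
        path = {}
        node = self._find_leaf(label_a)
        while node is not None:
            path[id(node)] = node
            node = node.parent
        node = self._find_leaf(label_b)
        while node is not None:
            if id(node) in path:
                return node.age
            node = node.parent
        raise ValueError("tips do not share a root")  # pragma: no cover

    def _find_leaf(self, label: str) -> TreeNode:
        for l in self.leaves():
            if l.label == label:
                return l
        raise KeyError(label)

    def branch_durations(self) -> dict[int, float]:
        """Map id(node) -> duration (my) of the branch above the node."""
        return {
            id(n): n.parent.age - n.age
            for n in self.preorder()
            if n.parent is not None
        }

    # -- output ------------------------------------------------------------

    def to_newick(self, precision: int = 8) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                core = n.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n.parent is not None:
                core += f":{n.parent.age - n.age:.{precision}f}"
            return core

        return fmt(self.root) + ";"

    def copy(self) -> "TimeTree":
        def clone(n: TreeNode) -> TreeNode:
            m = TreeNode(age=n.age, label=n.label)
            for c in n.children:
                m.add_child(clone(c))
            return m

        return TimeTree(clone(self.root), birth_rate=self.birth_rate)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree n_taxa={self.n_taxa} root_age={self.root_age:.3f}>"


def simulate_time_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    root_age: float = 1.0,
    seed: Optional[int] = None,
    label_prefix: str = "taxon",
) -> TimeTree:
    """Simulate a Yule (pure-birth) tree conditioned on tip count and root age.

    Exponential waiting times between birth events are drawn at per-lineage
    rate ``birth_rate``; a random lineage splits at each event. The resulting
    internal node depths are rescaled affinely so the first split sits exactly
    at ``root_age`` and tips at 0, i.e. the tree is conditioned on both
    ``n_taxa`` and the root age, preserving the Yule ranking of node ages.

    Parameters
    ----------
    n_taxa : int
        Number of tips, at least 2.
    birth_rate : float
        Per-lineage speciation rate (per my); shapes relative node depths.
    root_age : float
        Age of the root divergence in mya.
    seed : int, optional
        Seed for reproducibility.

    Returns
    -------
    TimeTree
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")

    rng = np.random.default_rng(seed)

    # forward simulation: event depths measured from the root split (time 0)
    root = TreeNode()
    left, right = TreeNode(), TreeNode()
    root.add_child(left)
    root.add_child(right)
    active = [left, right]
    depth = 0.0
    split_depth = {id(root): 0.0}
    while len(active) < n_taxa:
        depth += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        split_depth[id(node)] = depth
        a, b = TreeNode(), TreeNode()
        node.add_child(a)
        node.add_child(b)
        active.extend([a, b])
    # total depth at which tips are observed: one more waiting time
    total = depth + rng.exponential(1.0 / (birth_rate * n_taxa))

    # assign ages: internal node depth d -> age root_age * (1 - d/total)
    counter = iter(range(n_taxa))
    stack = [root]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            n.age = 0.0
            n.label = f"{label_prefix}{next(counter) + 1}"
        else:
            n.age = root_age * (1.0 - split_depth[id(n)] / total)
        stack.extend(n.children)
    return TimeTree(root, birth_rate=birth_rate)
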