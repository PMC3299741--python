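"""UPGMA guide tree and tree-derived sequence weights.

UPGMA merges the closest cluster pair; the distance from the merged cluster
Z = X u Y to any other cluster W is the leaf-count-weighted average

    d(W, Z) = (d(W, X) Num(X) + d(W, Y) Num(Y)) / (Num(X) + Num(Y)),

which keeps cluster distances equal to the mean over original leaf pairs.
Sequence weights follow the classic tree-partitioned scheme: each branch
length is divided equally among the leaves below it and summed per leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class TreeNode:
    """Node of a rooted binary guide tree.

    ``height`` is the merge height (half the merge distance, 0 for leaves);
    ``size`` the number of leaves below; ``length`` the branch length to the
    parent (filled during construction, root keeps 0).
    """

    leaf_id: Optional[str] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    height: float = 0.0
    size: int = 1
    length: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.leaf_id is not None

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            yield from self.left.leaves()
            yield from self.right.leaves()


@dataclass(frozen=True)
class GuideTree:
    root: TreeNode
    ids: tuple

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.leaf_id}:{node.length:.6g}"
            return f"({fmt(node.left)},{fmt(node.right)}):{node.length:.6g}"

        return fmt(self.root) + ";"


@dataclass(frozen=True)
class SequenceWeights:
    """Positive per-sequence weights and their cached sum."""

    weights: dict
    wN: float = field(default=0.0)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("sequence weights must be strictly positive")
        object.__setattr__(self, "wN", float(sum(self.weights.values())))


def upgma_update(d_wx: float, d_wy: float, num_x: int, num_y: int) -> float:
    """Leaf-count-weighted distance update for the merged cluster."""
    return (d_wx * num_x + d_wy * num_y) / (num_x + num_y)


def upgma(D: np.ndarray, ids) -> GuideTree:
    """Agglomerate a symmetric distance matrix into a rooted binary tree.

    The minimum-distance pair is merged each step; ties are broken by the
    smallest (row, col) index pair, indices referring to cluster creation
    order, so runs are platform-reproducible.
    """
    D = np.asarray(D, float)
    n = len(ids)
    if n < 2:
        raise ValueError("UPGMA needs at least two sequences")
    if D.shape != (n, n) or not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite and N x N")
    if np.abs(D - D.T).max() > 1e-12:
        raise ValueError("distance matrix must be symmetric")

    nodes = [TreeNode(leaf_id=i) for i in ids]
    dist = {}
    for a in range(n):
        for b in range(a + 1, n):
            dist[(a, b)] = D[a, b]
    active = list(range(n))
    next_idx = n
    store = {i: nodes[i] for i in range(n)}

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = dist[(min(a, b), max(a, b))]
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        na, nb = store[a], store[b]
        height = d / 2.0
        na.length = height - na.height
        nb.length = height - nb.height
        merged = TreeNode(left=na, right=nb, height=height,
                          size=na.size + nb.size)
        for c in active:
            if c in (a, b):
                continue
            dca = dist[(min(c, a), max(c, a))]
            dcb = dist[(min(c, b), max(c, b))]
            dist[(min(c, next_idx), max(c, next_idx))] = upgma_update(
                dca, dcb, na.size, nb.size)
        active = [c for c in active if c not in (a, b)] + [next_idx]
        store[next_idx] = merged
        next_idx += 1

    return GuideTree(root=store[active[0]], ids=tuple(ids))


def sequence_weights(tree: GuideTree) -> SequenceWeights:
    """Tree-partitioned weights: every branch length is shared equally by
    the leaves below it.

    A fully degenerate tree (all branch lengths 0, e.g. identical
    sequences) falls back to uniform weights 1/N; individual zero weights
    are floored at a small positive value to keep weights strictly
    positive.
    """
    raw = {i: 0.0 for i in tree.ids}

    def walk(node: TreeNode) -> None:
        below = [lf.leaf_id for lf in node.leaves()]
        share = node.length / len(below)
        for lid in below:
            raw[lid] += share
        if not node.is_leaf:
            walk(node.left)
            walk(node.right)

    walk(tree.root)
    total = sum(raw.values())
    n = len(tree.ids)
    if total <= 0:
        return SequenceWeights(weights={i: 1.0 / n for i in tree.ids})
    floor = max(total * 1e-8, 1e-300)
    return SequenceWeights(weights={i: max(w, floor) for i, w in raw.items()})
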