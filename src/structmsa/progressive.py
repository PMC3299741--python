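"""Progressive profile-profile alignment and randomized iterative refinement.

Profiles (groups of already-aligned sequences) are aligned by dynamic
programming over a column-pair score matrix averaged from the transformed
pairwise posteriors, weighted by the product of sequence weights.  The guide
tree fixes the merge order; refinement repeatedly splits the sequence set
into a random bipartition and realigns the two halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consistency import PosteriorStore
from .distance import dp_align
from .guidetree import GuideTree, SequenceWeights, TreeNode
from .seqio import GAP, MultipleAlignment, drop_all_gap_columns


@dataclass(frozen=True)
class Profile:
    """An ordered subset of sequences with their current gapped rows."""

    ids: tuple
    rows: tuple

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("profile rows must have equal length")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def residue_ordinals(self) -> np.ndarray:
        """Per-row array of residue ordinals per column (-1 for gaps)."""
        out = np.full((len(self.rows), self.width), -1, dtype=int)
        for r, row in enumerate(self.rows):
            k = 0
            for c, ch in enumerate(row):
                if ch != GAP:
                    out[r, c] = k
                    k += 1
        return out


def profile_posterior(A: Profile, B: Profile, posteriors: PosteriorStore,
                      w: SequenceWeights, seq_index: dict) -> np.ndarray:
    """Column-pair score matrix between two profiles.

    Entry (c, d) is the weighted mean over cross pairs (X in A, Y in B) of
    the posterior at the residues occupying columns c and d; gap occupants
    contribute 0.  Weights are w_X * w_Y, normalized by their sum.
    """
    if set(A.ids) & set(B.ids):
        raise ValueError("profiles must be disjoint")
    ordA = A.residue_ordinals()
    ordB = B.residue_ordinals()
    M = np.zeros((A.width, B.width))
    wsum = 0.0
    for a, xid in enumerate(A.ids):
        wa = w.weights[xid]
        maskA = ordA[a] >= 0
        for b, yid in enumerate(B.ids):
            wb = w.weights[yid]
            wsum += wa * wb
            P = posteriors.get(seq_index[xid], seq_index[yid])
            maskB = ordB[b] >= 0
            sub = P[np.ix_(ordA[a][maskA], ordB[b][maskB])]
            M[np.ix_(maskA, maskB)] += wa * wb * sub
    return M / wsum


def align_profiles(A: Profile, B: Profile, M: np.ndarray) -> Profile:
    """Merge two profiles along the optimal path through their column-pair
    score matrix (gap columns score 0; ties diagonal > up > left)."""
    _, ops = dp_align(M)
    rowsA = ["" for _ in A.ids]
    rowsB = ["" for _ in B.ids]
    ca = cb = 0
    for op in ops:
        if op == "d":
            for r in range(len(A.ids)):
                rowsA[r] += A.rows[r][ca]
            for r in range(len(B.ids)):
                rowsB[r] += B.rows[r][cb]
            ca += 1
            cb += 1
        elif op == "u":
            for r in range(len(A.ids)):
                rowsA[r] += A.rows[r][ca]
            for r in range(len(B.ids)):
                rowsB[r] += GAP
            ca += 1
        else:
            for r in range(len(A.ids)):
                rowsA[r] += GAP
            for r in range(len(B.ids)):
                rowsB[r] += B.rows[r][cb]
            cb += 1
    return Profile(ids=A.ids + B.ids, rows=tuple(rowsA + rowsB))


def progressive_align(tree: GuideTree, posteriors: PosteriorStore,
                      w: SequenceWeights, seqs) -> MultipleAlignment:
    """Post-order traversal of the guide tree, merging child profiles;
    final row order follows the input sequence order."""
    seq_index = {s.id: k for k, s in enumerate(seqs)}
    residues = {s.id: s.residues for s in seqs}

    def build(node: TreeNode) -> Profile:
        if node.is_leaf:
            return Profile(ids=(node.leaf_id,), rows=(residues[node.leaf_id],))
        left = build(node.left)
        right = build(node.right)
        M = profile_posterior(left, right, posteriors, w, seq_index)
        return align_profiles(left, right, M)

    prof = build(tree.root)
    order = {i: prof.ids.index(i) for i in (s.id for s in seqs)}
    ids = [s.id for s in seqs]
    rows = [prof.rows[order[i]] for i in ids]
    return MultipleAlignment(ids, drop_all_gap_columns(rows))


def iterative_refine(aln: MultipleAlignment, posteriors: PosteriorStore,
                     w: SequenceWeights, iters: int, seed: int,
                     seqs=None) -> MultipleAlignment:
    """Randomized refinement: per iteration, draw a uniform nonempty proper
    bipartition of the sequences, strip all-gap columns from each half, and
    realign the two halves (the realignment is accepted unconditionally).

    ``iters=0`` returns the input unchanged; a fixed seed makes the whole
    procedure bit-reproducible.
    """
    n = len(aln.ids)
    if iters == 0 or n < 2:
        return aln
    seq_index = {i: k for k, i in enumerate(aln.ids)} if seqs is None else \
        {s.id: k for k, s in enumerate(seqs)}
    rng = np.random.default_rng(seed)
    current = aln
    for _ in range(iters):
        while True:
            mask = rng.integers(0, 2, size=n).astype(bool)
            if 0 < mask.sum() < n:
                break
        groupA = [k for k in range(n) if mask[k]]
        groupB = [k for k in range(n) if not mask[k]]
        profs = []
        for group in (groupA, groupB):
            rows = drop_all_gap_columns([current.rows[k] for k in group])
            profs.append(Profile(ids=tuple(current.ids[k] for k in group),
                                 rows=tuple(rows)))
        M = profile_posterior(profs[0], profs[1], posteriors, w, seq_index)
        merged = align_profiles(profs[0], profs[1], M)
        order = {i: merged.ids.index(i) for i in current.ids}
        rows = [merged.rows[order[i]] for i in current.ids]
        current = MultipleAlignment(current.ids, drop_all_gap_columns(rows))
    return current
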