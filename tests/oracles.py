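"""Independent brute-force reference implementations used only by tests.

Everything here enumerates explicitly (paths, alignments, matchings,
agglomeration steps) so it shares no dynamic-programming code with the
package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def enumerate_partition(score: np.ndarray, bgo: float, bge: float):
    """Sum e^{alignment score} over all global alignments and, per residue
    pair, over the alignments containing that match.

    Alignment grammar: match columns score ``score[i, j]``; a gap run of
    length k scores ``bgo + (k-1) * bge``; a gap in one sequence may not be
    directly adjacent to a gap in the other.
    Returns (partition_value, posterior_matrix).
    """
    n1, n2 = score.shape
    total = 0.0
    per_pair = np.zeros((n1, n2))

    def rec(i, j, last, acc, pairs):
        nonlocal total
        if i == n1 and j == n2:
            w = math.exp(acc)
            total += w
            for p in pairs:
                per_pair[p] += w
            return
        if i < n1 and j < n2:
            rec(i + 1, j + 1, "M", acc + score[i, j], pairs + [(i, j)])
        if i < n1 and last != "Y":
            rec(i + 1, j, "X", acc + (bge if last == "X" else bgo), pairs)
        if j < n2 and last != "X":
            rec(i, j + 1, "Y", acc + (bge if last == "Y" else bgo), pairs)

    rec(0, 0, "S", 0.0, [])
    return total, per_pair / total


def enumerate_hmm(xi: np.ndarray, yi: np.ndarray, trans: np.ndarray,
                  match_emis: np.ndarray, insert_emis: np.ndarray):
    """Total path probability and per-pair match posteriors of the 3-state
    pair HMM by exhaustive path enumeration (start behaves like a match
    state; no end-state factor).

    Returns (total_probability, posterior_matrix).
    """
    n1, n2 = len(xi), len(yi)
    total = 0.0
    per_pair = np.zeros((n1, n2))

    def rec(i, j, state, p, pairs):
        nonlocal total
        if i == n1 and j == n2:
            total += p
            for q in pairs:
                per_pair[q] += p
            return
        if i < n1 and j < n2:
            pm = p * trans[state, 0] * match_emis[xi[i], yi[j]]
            if pm > 0:
                rec(i + 1, j + 1, 0, pm, pairs + [(i, j)])
        if i < n1:
            px = p * trans[state, 1] * insert_emis[xi[i]]
            if px > 0:
                rec(i + 1, j, 1, px, pairs)
        if j < n2:
            py = p * trans[state, 2] * insert_emis[yi[j]]
            if py > 0:
                rec(i, j + 1, 2, py, pairs)

    rec(0, 0, 0, 1.0, [])
    return total, per_pair / total


def brute_best_matching(M: np.ndarray) -> float:
    """Maximum total score over all monotone pair subsets of a matrix
    (every ascending row subset paired in order with an ascending column
    subset)."""
    n1, n2 = M.shape
    best = 0.0
    for k in range(1, min(n1, n2) + 1):
        for rs in combinations(range(n1), k):
            for cs in combinations(range(n2), k):
                s = sum(M[r, c] for r, c in zip(rs, cs))
                best = max(best, s)
    return best


def naive_upgma(D: np.ndarray, ids):
    """Agglomerate by always recomputing cluster distances as the mean over
    the original leaf pairs (no distance-update formula).  Returns a
    canonical nested representation with merge heights."""
    D = np.asarray(D, float)
    idx = {name: k for k, name in enumerate(ids)}
    clusters = [(frozenset([name]), name, 0.0) for name in ids]

    def cdist(a, b):
        return float(np.mean([[D[idx[x], idx[y]] for y in b] for x in a]))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i][0], clusters[j][0])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        sa, ra, _ = clusters[i]
        sb, rb, _ = clusters[j]
        kids = sorted([ra, rb], key=repr)
        merged = (sa | sb, (round(d / 2.0, 9), kids[0], kids[1]), d / 2.0)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters[0][1]


def canonical_tree(node):
    """Canonical nested representation of a package GuideTree node."""
    if node.is_leaf:
        return node.leaf_id
    kids = sorted([canonical_tree(node.left), canonical_tree(node.right)],
                  key=repr)
    return (round(node.height, 9), kids[0], kids[1])


def naive_consistency(store_get, n, w, k, l):
    """Direct dense evaluation of one transformed pairwise matrix."""
    w = np.asarray(w, float)
    acc = (w[k] + w[l]) * store_get(k, l)
    for z in range(n):
        if z in (k, l):
            continue
        acc = acc + w[z] * store_get(k, z) @ store_get(z, l)
    return acc / w.sum()
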