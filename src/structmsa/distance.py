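"""Pairwise distances from posterior alignments and contact-map similarity.

The distance between two sequences combines (a) the score of the optimal
posterior-weighted global alignment, normalized by the shorter length, and
(b) a contact-map similarity score computed on the gapless columns of that
alignment:

    d(X, Y) = 1 - W4 * Optscore / min(n1, n2) - W5 * CMscore,  W4 + W5 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .matrices import WeightConfig
from .seqio import ContactMap


@dataclass(frozen=True)
class PairAlignment:
    """Gapless matched positions of a pairwise alignment, strictly
    increasing in both coordinates."""

    pairs: tuple

    def __post_init__(self) -> None:
        prev = (-1, -1)
        for i, j in self.pairs:
            if not (i > prev[0] and j > prev[1]):
                raise ValueError("pair alignment must be strictly monotone")
            prev = (i, j)

    def __len__(self) -> int:
        return len(self.pairs)


def dp_align(M: np.ndarray):
    """Maximum-sum monotone matching over a score matrix (gaps score 0).

    Returns ``(score, ops)`` where ops is a list of 'd' (match), 'u'
    (consume a row) and 'l' (consume a column) steps from the origin.
    Ties are broken diagonal > up > left.
    """
    n1, n2 = M.shape
    AS = np.zeros((n1 + 1, n2 + 1))
    for i in range(1, n1 + 1):
        cand = np.maximum(AS[i - 1, :-1] + M[i - 1, :], AS[i - 1, 1:])
        # running max folds in the left-neighbour dependency AS[i, j-1]
        AS[i, 1:] = np.maximum.accumulate(
            np.concatenate(([AS[i, 0]], cand)))[1:]
    ops = []
    i, j = n1, n2
    while i > 0 or j > 0:
        if i > 0 and j > 0 and AS[i, j] == AS[i - 1, j - 1] + M[i - 1, j - 1]:
            ops.append("d")
            i, j = i - 1, j - 1
        elif i > 0 and AS[i, j] == AS[i - 1, j]:
            ops.append("u")
            i -= 1
        else:
            ops.append("l")
            j -= 1
    ops.reverse()
    return float(AS[n1, n2]), ops


def optimal_alignment(P: np.ndarray):
    """Optimal posterior-weighted global alignment of a sequence pair.

    Returns the matched pairs and the optimal score AS(n1, n2).
    """
    score, ops = dp_align(np.asarray(P, float))
    pairs = []
    i = j = 0
    for op in ops:
        if op == "d":
            pairs.append((i, j))
            i += 1
            j += 1
        elif op == "u":
            i += 1
        else:
            j += 1
    return PairAlignment(tuple(pairs)), score


def contact_map_score(pa: PairAlignment, cx: ContactMap, cy: ContactMap) -> float:
    """Contact-map similarity over the gapless columns of a pair alignment.

    Both maps are restricted to the matched positions, giving n x n
    matrices X' and Y'; the score is the mean diagonal of X'Y', i.e.
    (1/n^2) sum_ij X'_ij Y'_ji.  An empty alignment scores 0.
    """
    n = len(pa)
    if n == 0:
        return 0.0
    ix = np.fromiter((p[0] for p in pa.pairs), dtype=int, count=n)
    iy = np.fromiter((p[1] for p in pa.pairs), dtype=int, count=n)
    if ix.max() >= cx.n or iy.max() >= cy.n:
        raise ValueError("contact map smaller than aligned indices")
    rx = cx.probs[np.ix_(ix, ix)]
    ry = cy.probs[np.ix_(iy, iy)]
    # trace(rx @ ry) without forming the product
    return float(np.sum(rx * ry.T)) / (n * n)


def pairwise_distance(optscore: float, cmscore: Optional[float],
                      n1: int, n2: int, cfg: WeightConfig) -> float:
    """Distance per the weighted combination above, clamped to [0, 1].

    ``cmscore=None`` (a sequence lacks a contact map) disables the contact
    term: the posterior-alignment term then gets full weight.
    """
    w5 = cfg.wc if cmscore is not None else 0.0
    w4 = 1.0 - w5
    d = 1.0 - w4 * optscore / min(n1, n2) - w5 * (cmscore or 0.0)
    return min(max(d, 0.0), 1.0)


def distance_matrix(seqs, posteriors, cfg: WeightConfig) -> np.ndarray:
    """Assemble the symmetric N x N distance matrix (zero diagonal).

    ``posteriors`` is a PosteriorStore over the same sequence order.  The
    contact term is evaluated only when ``wc > 0`` and both sequences carry
    contact maps, so with wc = 0 the result is bitwise independent of any
    contact input.
    """
    n = len(seqs)
    D = np.zeros((n, n))
    for k in range(n):
        for l in range(k + 1, n):
            P = posteriors.get(k, l)
            pa, optscore = optimal_alignment(P)
            cmscore = None
            if cfg.wc > 0 and seqs[k].cmap is not None and seqs[l].cmap is not None:
                cmscore = contact_map_score(pa, seqs[k].cmap, seqs[l].cmap)
            d = pairwise_distance(optscore, cmscore, len(seqs[k]), len(seqs[l]), cfg)
            D[k, l] = D[l, k] = d
    return D
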