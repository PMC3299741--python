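"""Weighted consistency transformation of pairwise posterior matrices.

Each pairwise posterior P_XY is re-estimated through every third sequence Z
acting as an alignment relay:

    P'_XY = ((w_X + w_Y) P_XY + sum_Z w_Z P_XZ P_ZY) / w_N

with w_N the total sequence weight.  For two sequences the transform is the
identity.  Updates are synchronous (all new matrices are computed from the
previous round), so the result does not depend on pair iteration order.
"""

from __future__ import annotations

import numpy as np


class PosteriorStore:
    """All-pairs posterior matrices, stored once per unordered pair.

    ``get(k, l)`` returns the matrix with rows indexed by sequence k and
    columns by sequence l (a transpose view when k > l).
    """

    def __init__(self, n_seqs: int):
        self.n_seqs = n_seqs
        self._data = {}

    def set(self, k: int, l: int, P: np.ndarray) -> None:
        if k == l:
            raise KeyError("self-pairs are not stored")
        if k > l:
            k, l, P = l, k, P.T
        self._data[(k, l)] = np.asarray(P, float)

    def get(self, k: int, l: int) -> np.ndarray:
        if k < l:
            return self._data[(k, l)]
        return self._data[(l, k)].T

    def pairs(self):
        return sorted(self._data)

    def complete(self) -> bool:
        n = self.n_seqs
        return len(self._data) == n * (n - 1) // 2


def transform(posteriors: PosteriorStore, weights: np.ndarray,
              rounds: int = 1, sparsity_cutoff: float = 0.0) -> PosteriorStore:
    """Apply ``rounds`` synchronous consistency rounds.

    ``weights`` is indexed by sequence position (same order as the store).
    Entries below ``sparsity_cutoff`` are zeroed after each round (after,
    never before, the relay products); entries are clamped to [0, 1].
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    n = posteriors.n_seqs
    if len(weights) != n:
        raise ValueError("one weight per sequence required")
    if not posteriors.complete():
        raise ValueError("posterior store is missing pairs")
    w = np.asarray(weights, float)
    wN = float(w.sum())
    if n == 2:
        # wN = wX + wY and the relay sum is empty: the transform is the
        # identity, returned without arithmetic so the fixed point is exact.
        return posteriors
    cur = posteriors
    for _ in range(rounds):
        new = PosteriorStore(n)
        for (k, l) in cur.pairs():
            acc = (w[k] + w[l]) * cur.get(k, l)
            for z in range(n):
                if z == k or z == l:
                    continue
                acc = acc + w[z] * (cur.get(k, z) @ cur.get(z, l))
            P = acc / wN
            if P.max(initial=0.0) > 1.0 + 1e-6:
                raise FloatingPointError(
                    "consistency transform produced entries above 1 beyond "
                    "tolerance; input posteriors violate mass bounds")
            P = np.clip(P, 0.0, 1.0)
            if sparsity_cutoff > 0.0:
                P[P < sparsity_cutoff] = 0.0
            new.set(k, l, P)
        cur = new
    return cur
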