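"""Sequence-only alignment posteriors from a 3-state pair hidden Markov model.

The model has a match state M emitting residue pairs and two insert states
Ix/Iy emitting single residues against a gap; direct Ix<->Iy transitions are
disallowed.  Forward-backward in log space yields, for every residue pair
(i, j), the posterior probability that x_i aligns to y_j marginalized over
all global alignments.

Match emissions are joint residue-pair probabilities implied by the BLOSUM62
log-odds table at its canonical half-bit scale (solving for background
frequencies f with sum_b f_b 2^{S(a,b)/2} = 1, then p(a,b) = f_a f_b
2^{S(a,b)/2}); insert emissions are the marginal background frequencies.
Transition defaults follow the ProbCons-family single-affine parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .seqio import AA20, AnnotatedSequence

NEG = -np.inf

#: gap-open probability delta (M -> Ix and M -> Iy each) and gap-extension
#: probability epsilon (Ix -> Ix, Iy -> Iy).
DEFAULT_DELTA = 0.019931223
DEFAULT_EPSILON = 0.79433459


@dataclass(frozen=True)
class PairHMMParams:
    """Transition/emission tables of the 3-state pair HMM (all probabilities).

    ``trans`` is the 3x3 matrix over states (M, Ix, Iy); the initial
    distribution is the M row (a path behaves as if preceded by a virtual
    match).  ``match_emis`` is a 21x21 joint table over AA20+'X';
    ``insert_emis`` its marginal.
    """

    alphabet: str
    trans: np.ndarray
    match_emis: np.ndarray
    insert_emis: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.trans, float)
        if t.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if np.abs(t.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("transition rows must sum to 1")
        if t[1, 2] != 0.0 or t[2, 1] != 0.0:
            raise ValueError("direct Ix<->Iy transitions are not part of the model")
        m = np.asarray(self.match_emis, float)
        q = np.asarray(self.insert_emis, float)
        if abs(m.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("emission tables must be normalized")
        if np.abs(m - m.T).max() > 1e-12:
            raise ValueError("match emission table must be symmetric")
        object.__setattr__(self, "trans", t)
        object.__setattr__(self, "match_emis", m)
        object.__setattr__(self, "insert_emis", q)

    @property
    def log_trans(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.trans)

    def index(self, residues: str) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.alphabet)}
        return np.fromiter((lut[c] for c in residues), dtype=int, count=len(residues))


_DEFAULT_CACHE = None


def _blosum_joint():
    """Joint residue-pair probabilities implied by BLOSUM62 (see module doc)."""
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    S = np.array([[B[a, b] for b in AA20] for a in AA20], dtype=float)
    odds = 2.0 ** (S / 2.0)
    f = np.linalg.solve(odds, np.ones(20))
    if np.any(f <= 0):  # pragma: no cover - guards against a corrupt table
        raise RuntimeError("implied background frequencies are not positive")
    joint = np.outer(f, f) * odds
    joint = 0.5 * (joint + joint.T)
    return joint / joint.sum()


def default_params(delta: float = DEFAULT_DELTA,
                   epsilon: float = DEFAULT_EPSILON) -> PairHMMParams:
    """Default parameters; the 'X' residue emits like an average residue."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is not None and (delta, epsilon) == (DEFAULT_DELTA,
                                                           DEFAULT_EPSILON):
        return _DEFAULT_CACHE
    joint20 = _blosum_joint()
    q20 = joint20.sum(axis=1)
    qx = float(q20.mean())
    joint = np.zeros((21, 21))
    joint[:20, :20] = joint20
    joint[20, :20] = joint[: 20, 20] = q20 * qx
    joint[20, 20] = qx * qx
    joint /= joint.sum()
    q = joint.sum(axis=1)
    q /= q.sum()
    trans = np.array([
        [1.0 - 2.0 * delta, delta, delta],
        [1.0 - epsilon, epsilon, 0.0],
        [1.0 - epsilon, 0.0, epsilon],
    ])
    params = PairHMMParams(alphabet=AA20 + "X", trans=trans,
                           match_emis=joint, insert_emis=q)
    if (delta, epsilon) == (DEFAULT_DELTA, DEFAULT_EPSILON):
        _DEFAULT_CACHE = params
    return params


def params_from_yaml(path) -> PairHMMParams:
    """Load expert-override parameters from YAML (keys: alphabet, trans,
    match_emis, insert_emis)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PairHMMParams(
        alphabet=doc["alphabet"],
        trans=np.array(doc["trans"], float),
        match_emis=np.array(doc["match_emis"], float),
        insert_emis=np.array(doc["insert_emis"], float),
    )


def _log_emissions(X: AnnotatedSequence, Y: AnnotatedSequence,
                   params: PairHMMParams):
    xi = params.index(X.residues)
    yi = params.index(Y.residues)
    with np.errstate(divide="ignore"):
        em2 = np.log(params.match_emis)[np.ix_(xi, yi)]
        emx = np.log(params.insert_emis)[xi]
        emy = np.log(params.insert_emis)[yi]
    return em2, emx, emy


def _la2(a: float, b: float) -> float:
    """log(e^a + e^b) for scalars, tolerant of -inf."""
    if a == NEG:
        return b
    if b == NEG:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


def _la3(a: float, b: float, c: float) -> float:
    return _la2(_la2(a, b), c)


def _forward(em2, emx, emy, lt):
    """Fill the forward lattices fM/fX/fY of shape (n1+1, n2+1).

    The virtual start behaves like a match state at (0,0), so the initial
    distribution equals the M transition row.
    """
    n1, n2 = em2.shape
    fM = np.full((n1 + 1, n2 + 1), NEG)
    fX = np.full((n1 + 1, n2 + 1), NEG)
    fY = np.full((n1 + 1, n2 + 1), NEG)
    fromM = np.full((n1 + 1, n2 + 1), NEG)
    fromM[0, 0] = 0.0  # virtual start
    t00, t01, t02 = lt[0]
    t10, t11 = lt[1, 0], lt[1, 1]
    t20, t22 = lt[2, 0], lt[2, 2]
    for j in range(1, n2 + 1):
        fY[0, j] = emy[j - 1] + _la2(fromM[0, j - 1] + t02, fY[0, j - 1] + t22)
    for i in range(1, n1 + 1):
        ei = emx[i - 1]
        e2 = em2[i - 1]
        for j in range(n2 + 1):
            fX[i, j] = ei + _la2(fromM[i - 1, j] + t01, fX[i - 1, j] + t11)
            if j >= 1:
                fM[i, j] = e2[j - 1] + _la3(fromM[i - 1, j - 1] + t00,
                                            fX[i - 1, j - 1] + t10,
                                            fY[i - 1, j - 1] + t20)
                fromM[i, j] = fM[i, j]
                fY[i, j] = emy[j - 1] + _la2(fromM[i, j - 1] + t02,
                                             fY[i, j - 1] + t22)
    return fM, fX, fY


def _backward(em2, emx, emy, lt):
    """Backward lattices: b*[i, j] is the probability of emitting the
    remaining suffix given the current state (current emission excluded)."""
    n1, n2 = em2.shape
    bM = np.full((n1 + 1, n2 + 1), NEG)
    bX = np.full((n1 + 1, n2 + 1), NEG)
    bY = np.full((n1 + 1, n2 + 1), NEG)
    bM[n1, n2] = bX[n1, n2] = bY[n1, n2] = 0.0
    t00, t01, t02 = lt[0]
    t10, t11 = lt[1, 0], lt[1, 1]
    t20, t22 = lt[2, 0], lt[2, 2]
    for i in range(n1, -1, -1):
        for j in range(n2, -1, -1):
            if i == n1 and j == n2:
                continue
            diag = em2[i, j] + bM[i + 1, j + 1] if (i < n1 and j < n2) else NEG
            down = emx[i] + bX[i + 1, j] if i < n1 else NEG
            right = emy[j] + bY[i, j + 1] if j < n2 else NEG
            bM[i, j] = _la3(t00 + diag, t01 + down, t02 + right)
            bX[i, j] = _la2(t10 + diag, t11 + down)
            bY[i, j] = _la2(t20 + diag, t22 + right)
    return bM, bX, bY


def hmm_total_loglik(X: AnnotatedSequence, Y: AnnotatedSequence,
                     params: PairHMMParams = None,
                     algorithm: str = "forward") -> float:
    """Total log-likelihood of the sequence pair, by forward or backward
    recursion (the two must agree — a standard implementation check)."""
    if params is None:
        params = default_params()
    em2, emx, emy = _log_emissions(X, Y, params)
    lt = params.log_trans
    n1, n2 = em2.shape
    if algorithm == "forward":
        fM, fX, fY = _forward(em2, emx, emy, lt)
        total = logsumexp([fM[n1, n2], fX[n1, n2], fY[n1, n2]])
    elif algorithm == "backward":
        bM, bX, bY = _backward(em2, emx, emy, lt)
        # Initial distribution = M transition row (virtual start match).
        total = logsumexp([
            lt[0, 0] + em2[0, 0] + bM[1, 1],
            lt[0, 1] + emx[0] + bX[1, 0],
            lt[0, 2] + emy[0] + bY[0, 1],
        ])
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if not np.isfinite(total):
        raise FloatingPointError("non-finite pair-HMM log-likelihood")
    return float(total)


def hmm_posterior(X: AnnotatedSequence, Y: AnnotatedSequence,
                  params: PairHMMParams = None) -> np.ndarray:
    """Posterior match probabilities P(x_i ~ y_j | X, Y), an n1 x n2 matrix.

    Entries below 1e-12 are flushed to zero to keep downstream sparse
    operations stable.
    """
    if params is None:
        params = default_params()
    em2, emx, emy = _log_emissions(X, Y, params)
    lt = params.log_trans
    n1, n2 = em2.shape
    fM, fX, fY = _forward(em2, emx, emy, lt)
    bM, _, _ = _backward(em2, emx, emy, lt)
    total = logsumexp([fM[n1, n2], fX[n1, n2], fY[n1, n2]])
    if not np.isfinite(total):
        raise FloatingPointError("non-finite pair-HMM log-likelihood")
    post = np.exp(fM[1:, 1:] + bM[1:, 1:] - total)
    if post.max(initial=0.0) > 1.0 + 1e-6:
        raise FloatingPointError("pair-HMM posterior exceeds 1 beyond tolerance")
    post = np.clip(post, 0.0, 1.0)
    post[post < 1e-12] = 0.0
    return post
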