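"""Structure-aware alignment posteriors via the alignment partition function.

Every global alignment ``aln`` of X and Y receives weight e^{score(aln)},
where matched residue pairs contribute

    w1 * beta * s(x_i, y_j) + w2 * SS(ss_i, ss_j) + w3 * SA(sa_i, sa_j)

(s a substitution log-odds score, SS/SA identity scores on predicted
secondary structure and solvent accessibility) and gap runs contribute
beta * (gap_open + (len-1) * gap_ext).  Adjacent gap columns in opposite
sequences are disallowed, matching the recursion grammar: an X-gap may not
directly follow a Y-gap or vice versa.  Summing those weights with dynamic
programming in log space gives the partition function F; the posterior that
x_i aligns to y_j is the weight of all alignments containing that pair
divided by F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import SubstitutionMatrix, WeightConfig
from .seqio import AnnotatedSequence

NEG = -np.inf


class AnnotationError(ValueError):
    """Structural weights are active but an annotation is missing."""


@dataclass(frozen=True)
class PartitionLattice:
    """Log-domain forward lattices of shape (n1+1, n2+1).

    ``FM[i, j]`` sums alignments of the length-i/length-j prefixes ending
    with x_i matched to y_j; ``FX``/``FY`` those ending with x_i / y_j
    against a gap; ``F`` their cellwise sum.  ``F[0, 0] = 1`` seeds the
    recursion (empty prefix).
    """

    FM: np.ndarray
    FX: np.ndarray
    FY: np.ndarray
    F: np.ndarray


def pair_score_matrix(X: AnnotatedSequence, Y: AnnotatedSequence,
                      cfg: WeightConfig, S: SubstitutionMatrix) -> np.ndarray:
    """The n1 x n2 matrix of match-column exponents.

    By default beta scales only the amino-acid term; with
    ``beta_scales_structure`` it multiplies the whole weighted sum.
    """
    if cfg.w2 > 0 and (X.ss is None or Y.ss is None):
        raise AnnotationError(
            "w2 > 0 requires secondary-structure annotations on both sequences")
    if cfg.w3 > 0 and (X.sa is None or Y.sa is None):
        raise AnnotationError(
            "w3 > 0 requires solvent-accessibility annotations on both sequences")
    def _agree(a: str, b: str) -> np.ndarray:
        av = np.frombuffer(a.encode(), dtype=np.uint8)
        bv = np.frombuffer(b.encode(), dtype=np.uint8)
        return (av[:, None] == bv[None, :]).astype(float)

    sub = S.pair_scores(X.residues, Y.residues)
    score = cfg.w1 * sub if cfg.beta_scales_structure else cfg.w1 * cfg.beta * sub
    if cfg.w2 > 0:
        score = score + cfg.w2 * _agree(X.ss, Y.ss)
    if cfg.w3 > 0:
        score = score + cfg.w3 * _agree(X.sa, Y.sa)
    return cfg.beta * score if cfg.beta_scales_structure else score


def partition_forward(X: AnnotatedSequence, Y: AnnotatedSequence,
                      cfg: WeightConfig, S: SubstitutionMatrix,
                      score: np.ndarray = None) -> PartitionLattice:
    """Fill the forward partition-function lattice in log space."""
    if score is None:
        score = pair_score_matrix(X, Y, cfg, S)
    n1, n2 = score.shape
    bgo = cfg.beta * cfg.gap_open
    bge = cfg.beta * cfg.gap_ext
    FM = np.full((n1 + 1, n2 + 1), NEG)
    FX = np.full((n1 + 1, n2 + 1), NEG)
    FY = np.full((n1 + 1, n2 + 1), NEG)
    F = np.full((n1 + 1, n2 + 1), NEG)
    FM[0, 0] = 0.0  # empty-prefix seed
    F[0, 0] = 0.0
    js = np.arange(n2)
    for j in range(1, n2 + 1):
        FY[0, j] = np.logaddexp(FM[0, j - 1] + bgo, FY[0, j - 1] + bge)
    F[0, 1:] = FY[0, 1:]
    for i in range(1, n1 + 1):
        FX[i, :] = np.logaddexp(FM[i - 1, :] + bgo, FX[i - 1, :] + bge)
        FM[i, 1:] = F[i - 1, :-1] + score[i - 1, :]
        # FY[i, j] = sum_{k<=j-1} FM[i, k] e^{bgo} e^{bge (j-1-k)}: a
        # running log-sum along the row.
        g = np.logaddexp.accumulate(FM[i, :-1] - bge * js)
        FY[i, 1:] = bgo + bge * js + g
        F[i, :] = np.logaddexp(np.logaddexp(FM[i, :], FX[i, :]), FY[i, :])
    for arr in (FM, FX, FY, F):
        if np.isnan(arr).any() or np.isposinf(arr).any():
            raise FloatingPointError("non-finite cell in partition lattice")
    return PartitionLattice(FM=FM, FX=FX, FY=FY, F=F)


def _reversed_seq(s: AnnotatedSequence) -> AnnotatedSequence:
    return AnnotatedSequence(
        id=s.id, residues=s.residues[::-1],
        ss=None if s.ss is None else s.ss[::-1],
        sa=None if s.sa is None else s.sa[::-1],
        cmap=None)


def partition_posterior(X: AnnotatedSequence, Y: AnnotatedSequence,
                        cfg: WeightConfig, S: SubstitutionMatrix) -> np.ndarray:
    """Structure-aware posterior matrix: entry (i, j) is the summed weight of
    all global alignments matching x_i with y_j, divided by the partition
    function.

    The suffix partition function is obtained by running the identical
    forward recursion on the reversed sequences (the alignment grammar is
    reversal-symmetric), then index-mapping.
    """
    score = pair_score_matrix(X, Y, cfg, S)
    fwd = partition_forward(X, Y, cfg, S, score=score)
    rev = partition_forward(_reversed_seq(X), _reversed_seq(Y), cfg, S,
                            score=score[::-1, ::-1])
    n1, n2 = score.shape
    total = fwd.F[n1, n2]
    # prefix F[i, j] (residues before the match) * e^{score} * suffix
    suffix = rev.F[::-1, ::-1]  # suffix[i, j] = weight of aligning x_{i+1..}, y_{j+1..}
    logp = fwd.F[:-1, :-1] + score + suffix[1:, 1:] - total
    post = np.exp(logp)
    if post.max(initial=0.0) > 1.0 + 1e-6:
        raise FloatingPointError(
            "partition posterior exceeds 1 beyond clamp tolerance")
    return np.clip(post, 0.0, 1.0)


def combine_posteriors(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Fuse two posterior matrices entrywise by the root mean square."""
    if p1.shape != p2.shape:
        raise ValueError(f"posterior shape mismatch: {p1.shape} vs {p2.shape}")
    return np.clip(np.sqrt((p1 ** 2 + p2 ** 2) / 2.0), 0.0, 1.0)
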