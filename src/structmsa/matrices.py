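"""Similarity matrices and the alignment weight configuration.

The amino-acid term uses a Gonnet-family log-odds substitution table (tenth-bit
units).  Secondary structure (H/E/C) and relative solvent accessibility (e/b)
are scored with identity matrices: concordant states score 1, discordant 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .seqio import AA20, SA_ALPHABET, SS_ALPHABET


@dataclass(frozen=True)
class WeightConfig:
    """Tunable weights and penalties for the whole pipeline.

    ``w1``/``w2``/``w3`` weight amino-acid, secondary-structure and
    solvent-accessibility similarity inside the partition-function exponent
    (they must sum to 1); ``wc`` weights the contact-map score in the
    pairwise distance (the posterior-alignment term gets 1 - wc).  ``beta``
    is the inverse-temperature controlling how strongly suboptimal
    alignments are down-weighted; ``gap_open``/``gap_ext`` are non-positive
    affine gap penalties on the substitution-score scale.
    """

    w1: float = 0.4
    w2: float = 0.5
    w3: float = 0.1
    wc: float = 0.9
    beta: float = 0.2
    gap_open: float = -22.0
    gap_ext: float = -1.0
    transform_rounds: int = 1
    refine_iters: int = 10
    sparsity_cutoff: float = 0.01
    seed: int = 0
    beta_scales_structure: bool = False

    def with_overrides(self, **kwargs) -> "WeightConfig":
        return validate_weights(replace(self, **kwargs))


def default_weights() -> WeightConfig:
    """The default configuration: w1/w2/w3 = 0.4/0.5/0.1, wc = 0.9,
    10 refinement iterations."""
    return validate_weights(WeightConfig())


def validate_weights(cfg: WeightConfig) -> WeightConfig:
    """Check all configuration invariants; return the config unchanged."""
    for name in ("w1", "w2", "w3", "wc"):
        v = getattr(cfg, name)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} must lie in [0, 1]")
    if abs(cfg.w1 + cfg.w2 + cfg.w3 - 1.0) > 1e-9:
        raise ValueError(
            f"w1+w2+w3 must equal 1 (got {cfg.w1 + cfg.w2 + cfg.w3!r})")
    if cfg.beta <= 0:
        raise ValueError(f"beta={cfg.beta} must be positive")
    if cfg.gap_open > 0:
        raise ValueError(f"gap_open={cfg.gap_open} must be <= 0")
    if cfg.gap_ext > 0:
        raise ValueError(f"gap_ext={cfg.gap_ext} must be <= 0")
    if cfg.transform_rounds < 1:
        raise ValueError("transform_rounds must be >= 1")
    if cfg.refine_iters < 0:
        raise ValueError("refine_iters must be >= 0")
    if not (0.0 <= cfg.sparsity_cutoff < 1.0):
        raise ValueError("sparsity_cutoff must lie in [0, 1)")
    return cfg


class SubstitutionMatrix:
    """Symmetric residue substitution scores over the 20 amino acids plus 'X'.

    The 'X' (unknown residue) row and column score 0 against everything.
    """

    def __init__(self, alphabet: str, scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(alphabet), len(alphabet)):
            raise ValueError("score table shape does not match alphabet")
        if not np.all(np.isfinite(scores)):
            raise ValueError("substitution scores must be finite")
        if np.abs(scores - scores.T).max() > 1e-9:
            raise ValueError("substitution matrix must be symmetric")
        self.alphabet = alphabet
        self.scores = scores
        self._index = {c: i for i, c in enumerate(alphabet)}

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])

    def pair_scores(self, xres: str, yres: str) -> np.ndarray:
        """len(x) x len(y) score matrix for two residue strings."""
        xi = np.fromiter((self._index[c] for c in xres), dtype=int, count=len(xres))
        yi = np.fromiter((self._index[c] for c in yres), dtype=int, count=len(yres))
        return self.scores[np.ix_(xi, yi)]

    _gonnet_cache = None

    @classmethod
    def gonnet(cls) -> "SubstitutionMatrix":
        """The Gonnet log-odds table shipped with Biopython, extended with a
        zero-scoring 'X' row/column."""
        if cls._gonnet_cache is not None:
            return cls._gonnet_cache
        from Bio.Align import substitution_matrices

        g = substitution_matrices.load("GONNET1992")
        full = np.zeros((21, 21))
        for i, a in enumerate(AA20):
            for j, b in enumerate(AA20):
                full[i, j] = g[a, b]
        cls._gonnet_cache = cls(AA20 + "X", full)
        return cls._gonnet_cache

    @classmethod
    def from_table(cls, path) -> "SubstitutionMatrix":
        """Load a whitespace table: first line is the alphabet, following
        lines are the score rows.  An 'X' row/column is added if absent."""
        lines = [ln for ln in Path(path).read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
        alphabet = "".join(lines[0].split())
        rows = [[float(v) for v in ln.split()] for ln in lines[1:]]
        scores = np.array(rows)
        if "X" not in alphabet:
            n = len(alphabet)
            ext = np.zeros((n + 1, n + 1))
            ext[:n, :n] = scores
            alphabet += "X"
            scores = ext
        return cls(alphabet, scores)


def ss_score(p: Optional[str], q: Optional[str]) -> float:
    """Identity scoring of two secondary-structure states (missing -> 0)."""
    if p is None or q is None:
        return 0.0
    if p not in SS_ALPHABET or q not in SS_ALPHABET:
        raise ValueError(f"unknown secondary-structure symbol in ({p!r}, {q!r})")
    return 1.0 if p == q else 0.0


def sa_score(p: Optional[str], q: Optional[str]) -> float:
    """Identity scoring of two solvent-accessibility states (missing -> 0)."""
    if p is None or q is None:
        return 0.0
    if p not in SA_ALPHABET or q not in SA_ALPHABET:
        raise ValueError(f"unknown solvent-accessibility symbol in ({p!r}, {q!r})")
    return 1.0 if p == q else 0.0


def similarity_scores(a, b, ssa=None, ssb=None, saa=None, sab=None,
                      S: Optional[SubstitutionMatrix] = None):
    """Return the (substitution, SS, SA) score triple for one residue pair."""
    if S is None:
        S = SubstitutionMatrix.gonnet()
    return S.score(a, b), ss_score(ssa, ssb), sa_score(saa, sab)
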