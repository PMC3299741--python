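"""Sequence, annotation and alignment I/O plus the core data model.

All coordinates are 0-based internally; CASP-RR contact files use 1-based
residue indices and are converted at the parsing boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

GAP = "-"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = AA20 + "X"
SS_ALPHABET = "HEC"
SA_ALPHABET = "eb"

#: DSSP 8-state -> 3-state folding. Helix-like states collapse to H,
#: strand-like to E, everything else (turns, bends, coil) to C.
DSSP_FOLD = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "L": "C", "-": "C", ".": "C",
}


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent annotations."""


@dataclass(frozen=True)
class ContactMap:
    """Symmetric matrix of residue-residue contact probabilities."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise FormatError("contact map must be a square matrix")
        if np.any(p < 0) or np.any(p > 1):
            raise FormatError("contact probabilities must lie in [0, 1]")
        if np.abs(p - p.T).max(initial=0.0) > 1e-12:
            raise FormatError("contact map must be symmetric (symmetrize at load)")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ContactMap":
        """Build a map from a possibly asymmetric array, keeping max(pij, pji)."""
        a = np.asarray(arr, dtype=float)
        return cls(np.maximum(a, a.T))

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class AnnotatedSequence:
    """A protein sequence with optional per-residue structural annotations.

    ``ss`` is a 3-state secondary-structure string over {H,E,C}, ``sa`` a
    2-state relative-solvent-accessibility string over {e,b} (exposed/buried
    at the 25%-surface-area cutoff), ``cmap`` an n x n contact-probability
    map.  Annotations, when present, must match the sequence length.
    """

    id: str
    residues: str
    ss: Optional[str] = None
    sa: Optional[str] = None
    cmap: Optional[ContactMap] = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(AA_ALPHABET)
        if bad:
            raise FormatError(f"sequence {self.id!r} has invalid residues {sorted(bad)}")
        if self.ss is not None:
            if len(self.ss) != n:
                raise FormatError(
                    f"SS annotation of {self.id!r} has length {len(self.ss)}, expected {n}")
            if set(self.ss) - set(SS_ALPHABET):
                raise FormatError(f"SS annotation of {self.id!r} has symbols outside H/E/C")
        if self.sa is not None:
            if len(self.sa) != n:
                raise FormatError(
                    f"SA annotation of {self.id!r} has length {len(self.sa)}, expected {n}")
            if set(self.sa) - set(SA_ALPHABET):
                raise FormatError(f"SA annotation of {self.id!r} has symbols outside e/b")
        if self.cmap is not None and self.cmap.n != n:
            raise FormatError(
                f"contact map of {self.id!r} is {self.cmap.n}x{self.cmap.n}, expected {n}x{n}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows over an ordered set of sequence ids."""

    ids: tuple
    rows: tuple

    def __init__(self, ids, rows):
        object.__setattr__(self, "ids", tuple(ids))
        object.__setattr__(self, "rows", tuple(rows))
        self.__post_init__()

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate sequence ids in alignment")
        if not self.rows:
            raise FormatError("alignment has no rows")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise FormatError("alignment rows have unequal lengths")
        if len(self.rows) > 1:
            for c in range(width):
                if all(r[c] == GAP for r in self.rows):
                    raise FormatError(f"alignment column {c} is all gaps")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")


def degap(row: str) -> str:
    return row.replace(GAP, "")


def drop_all_gap_columns(rows):
    """Return rows with every all-gap column removed (helper for profiles)."""
    keep = [c for c in range(len(rows[0])) if any(r[c] != GAP for r in rows)]
    return [("".join(r[c] for c in keep)) for r in rows]


def _parse_fasta_records(path):
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _dedup_ids(ids):
    seen: dict = {}
    out = []
    for raw in ids:
        if raw not in seen:
            seen[raw] = 0
            out.append(raw)
            continue
        seen[raw] += 1
        candidate = f"{raw}.{seen[raw]}"
        if candidate in seen:
            raise FormatError(f"duplicate id {raw!r} could not be deduplicated")
        warnings.warn(f"duplicate FASTA id {raw!r}; renamed to {candidate!r}")
        seen[candidate] = 0
        out.append(candidate)
    return out


def read_fasta(path) -> list:
    """Read unaligned protein sequences.

    Letters are uppercased, non-standard residues are mapped to 'X', and
    duplicate ids are suffix-deduplicated with a warning.
    """
    records = _parse_fasta_records(path)
    ids = _dedup_ids([r.id for r in records])
    seqs = []
    for name, rec in zip(ids, records):
        raw = str(rec.seq).upper().replace(".", "").replace(GAP, "")
        if not raw:
            raise FormatError(f"{path}: record {rec.id!r} has no residues")
        residues = "".join(c if c in AA20 else "X" for c in raw)
        seqs.append(AnnotatedSequence(id=name, residues=residues))
    return seqs


def read_alignment(path) -> MultipleAlignment:
    """Read a gapped FASTA alignment ('.' gaps normalized to '-')."""
    records = _parse_fasta_records(path)
    ids = _dedup_ids([r.id for r in records])
    rows = []
    for rec in records:
        row = str(rec.seq).upper().replace(".", GAP)
        rows.append("".join(c if (c in AA20 or c == GAP) else "X" for c in row))
    return MultipleAlignment(ids, rows)


def read_annotation(path, alphabet: str) -> dict:
    """Read FASTA-like per-residue annotation strings keyed by sequence id.

    For the secondary-structure alphabet (HEC), 8-state DSSP letters are
    folded to 3 states; for the accessibility alphabet (eb) letters are
    lowercased.  Symbols outside the target alphabet raise FormatError.
    """
    if set(alphabet) == set(SS_ALPHABET):
        mode = "ss"
    elif set(alphabet) == set(SA_ALPHABET):
        mode = "sa"
    else:
        raise ValueError(f"unsupported annotation alphabet {alphabet!r}")
    records = _parse_fasta_records(path)
    out = {}
    for rec in records:
        raw = str(rec.seq)
        if mode == "ss":
            folded = []
            for c in raw.upper():
                if c not in DSSP_FOLD:
                    raise FormatError(
                        f"{path}: record {rec.id!r}: unknown SS symbol {c!r}")
                folded.append(DSSP_FOLD[c])
            out[rec.id] = "".join(folded)
        else:
            low = raw.lower()
            bad = set(low) - set(SA_ALPHABET)
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r}: unknown SA symbol {sorted(bad)[0]!r}")
            out[rec.id] = low
    return out


def attach_annotations(seqs, ss=None, sa=None, cmaps=None) -> list:
    """Attach annotation maps (id -> string / ContactMap) to sequences.

    Length mismatches raise FormatError naming the offending record.
    """
    out = []
    for s in seqs:
        out.append(AnnotatedSequence(
            id=s.id,
            residues=s.residues,
            ss=(ss or {}).get(s.id, s.ss),
            sa=(sa or {}).get(s.id, s.sa),
            cmap=(cmaps or {}).get(s.id, s.cmap),
        ))
    return out


def read_contact_rr(path, n: int) -> ContactMap:
    """Read a contact map, either CASP-RR style ("i j d1 d2 p", 1-based) or a
    dense whitespace n x n matrix (auto-detected from the line shape).

    Unlisted pairs default to 0; the map is symmetrized by max(pij, pji).
    """
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    mat = np.zeros((n, n), dtype=float)
    if not lines:
        return ContactMap.from_array(mat)

    fields = [ln.split() for ln in lines]
    ncols = {len(f) for f in fields}

    def _is_rr(row) -> bool:
        if len(row) != 5:
            return False
        try:
            int(row[0]), int(row[1])
            float(row[4])
        except ValueError:
            return False
        return True

    if ncols == {5} and all(_is_rr(f) for f in fields):
        for row in fields:
            i, j = int(row[0]), int(row[1])
            p = float(row[4])
            if not (1 <= i <= n and 1 <= j <= n):
                raise FormatError(
                    f"{path}: contact indices ({i},{j}) outside [1,{n}]")
            if not (0.0 <= p <= 1.0):
                raise FormatError(f"{path}: contact probability {p} outside [0,1]")
            mat[i - 1, j - 1] = max(mat[i - 1, j - 1], p)
        return ContactMap.from_array(mat)

    if len(fields) == n and ncols == {n}:
        try:
            dense = np.array([[float(v) for v in row] for row in fields])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed dense contact matrix: {exc}") from exc
        if np.any(dense < 0) or np.any(dense > 1):
            raise FormatError(f"{path}: dense contact entries outside [0,1]")
        return ContactMap.from_array(dense)

    raise FormatError(
        f"{path}: not a 5-column RR file nor a dense {n}x{n} matrix")


def write_alignment(aln: MultipleAlignment, fmt: str = "fasta") -> str:
    """Render an alignment as FASTA or CLUSTAL text."""
    if fmt == "fasta":
        return "".join(f">{i}\n{r}\n" for i, r in zip(aln.ids, aln.rows))
    if fmt == "clustal":
        out = ["CLUSTAL format alignment\n\n"]
        width = max(len(i) for i in aln.ids) + 4
        for start in range(0, aln.width, 60):
            for i, r in zip(aln.ids, aln.rows):
                out.append(f"{i:<{width}}{r[start:start + 60]}\n")
            out.append("\n")
        return "".join(out)
    raise ValueError(f"unknown alignment format {fmt!r}")
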