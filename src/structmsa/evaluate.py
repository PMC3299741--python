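"""Sum-of-pairs (SP) and total-column (TC) accuracy versus a reference.

SP is the fraction of residue pairs aligned together in the reference's
core columns that the test alignment also aligns together; TC is the
fraction of core columns whose full residue set is reproduced intact in a
single test column.  Residues are identified by (sequence id, residue
ordinal), so both scores are invariant to row order and to gap placement.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

from .seqio import GAP, MultipleAlignment


def _column_residues(aln: MultipleAlignment):
    """Per column, the list of (seq id, residue ordinal) it contains."""
    counters = {i: 0 for i in aln.ids}
    cols = []
    for c in range(aln.width):
        col = []
        for i, row in zip(aln.ids, aln.rows):
            if row[c] != GAP:
                col.append((i, counters[i]))
                counters[i] += 1
        cols.append(col)
    return cols


def _check_same_sequences(test: MultipleAlignment, ref: MultipleAlignment):
    if set(test.ids) != set(ref.ids):
        raise ValueError("test and reference alignments cover different sequences")
    for i in ref.ids:
        if test.degapped(i) != ref.degapped(i):
            raise ValueError(f"sequence {i!r} differs between test and reference")


def _test_column_index(test: MultipleAlignment) -> dict:
    idx = {}
    for c, col in enumerate(_column_residues(test)):
        for key in col:
            idx[key] = c
    return idx


def _core_columns(ref: MultipleAlignment, core: Optional[Sequence[int]]):
    cols = _column_residues(ref)
    if core is None:
        return cols
    for c in core:
        if not (0 <= c < ref.width):
            raise ValueError(f"core column index {c} outside reference")
    return [cols[c] for c in sorted(set(core))]


def sp_score(test: MultipleAlignment, ref: MultipleAlignment,
             core: Optional[Sequence[int]] = None) -> float:
    """Fraction of reference core residue pairs recovered by the test
    alignment (1.0 if the reference contributes no pairs)."""
    _check_same_sequences(test, ref)
    where = _test_column_index(test)
    num = den = 0
    for col in _core_columns(ref, core):
        for a, b in combinations(col, 2):
            den += 1
            if where[a] == where[b]:
                num += 1
    return num / den if den else 1.0


def tc_score(test: MultipleAlignment, ref: MultipleAlignment,
             core: Optional[Sequence[int]] = None) -> float:
    """Fraction of reference core columns (those with at least two
    residues) whose residue set lands intact in one test column."""
    _check_same_sequences(test, ref)
    where = _test_column_index(test)
    num = den = 0
    for col in _core_columns(ref, core):
        if len(col) < 2:
            continue
        den += 1
        if len({where[key] for key in col}) == 1:
            num += 1
    return num / den if den else 1.0
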