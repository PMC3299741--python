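"""Synthetic annotated protein families with known true alignments.

The generator emulates the structure of curated alignment benchmarks: an
ancestor sequence with block-wise secondary structure (helix/strand/coil
runs) and run-wise burial states evolves by independent substitutions and
geometric-length indels, with full bookkeeping of the true alignment.
Secondary structure and accessibility are conserved across the family, the
way predictors applied to homologous sequences produce concordant strings.
Contact maps place probability 0.9 on antiparallel pairings of consecutive
strand blocks over a 0.05 background — a detectable but imperfect signal,
as sequence-based contact predictors give.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .seqio import (AA20, AnnotatedSequence, ContactMap, MultipleAlignment,
                    GAP)

CONTACT_HIGH = 0.9
CONTACT_BG = 0.05


def _run_string(rng, length, states, lo, hi, forbid_repeat=True):
    out = []
    prev = None
    while len(out) < length:
        choices = [s for s in states if not (forbid_repeat and s == prev)]
        state = choices[rng.integers(0, len(choices))]
        run = int(rng.integers(lo, hi + 1))
        out.extend(state * run)
        prev = state
    return "".join(out[:length])


def _contact_template(ss: str) -> np.ndarray:
    """Antiparallel contacts between consecutive strand blocks over a
    uniform background."""
    n = len(ss)
    cm = np.full((n, n), CONTACT_BG)
    blocks = []
    start = None
    for i, c in enumerate(ss + "$"):
        if c == "E" and start is None:
            start = i
        elif c != "E" and start is not None:
            blocks.append((start, i - 1))
            start = None
    for a, b in zip(blocks[::2], blocks[1::2]):
        m = min(a[1] - a[0], b[1] - b[0]) + 1
        for k in range(m):
            i, j = a[0] + k, b[1] - k
            cm[i, j] = cm[j, i] = CONTACT_HIGH
    return cm


def _mutate(rng, residue: str) -> str:
    others = AA20.replace(residue, "")
    return others[rng.integers(0, len(others))]


def make_family(n_seqs: int, length: int, sub_rate: float, indel_rate: float,
                seed: int):
    """Simulate a family of annotated sequences with a known alignment.

    Returns ``(sequences, truth, core)`` where ``truth`` is the true
    multiple alignment and ``core`` lists the truth columns untouched by
    any indel (every row has a residue there and the column is ancestral).
    """
    if n_seqs < 2:
        raise ValueError("n_seqs must be >= 2")
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= sub_rate < 1.0):
        raise ValueError("sub_rate must lie in [0, 1)")
    if not (0.0 <= indel_rate < 1.0):
        raise ValueError("indel_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    ss = _run_string(rng, length, "HEC", 4, 10)
    sa = _run_string(rng, length, "eb", 3, 7)
    template = _contact_template(ss)
    ancestor = "".join(AA20[rng.integers(0, 20)] for _ in range(length))

    # Per row: inserted residues before each ancestor slot (slot `length`
    # means appended at the end) and the surviving residue per position.
    inserts = []   # row -> {slot: [residues]}
    kept = []      # row -> list of (ancestor_pos, residue) or None if deleted
    for _ in range(n_seqs):
        row_ins: dict = {}
        row_res = []
        i = 0
        while i < length:
            if rng.random() < indel_rate:
                run = int(rng.geometric(0.5))
                for _k in range(int(run)):
                    if i < length:
                        row_res.append(None)
                        i += 1
                continue
            res = ancestor[i]
            if rng.random() < sub_rate:
                res = _mutate(rng, res)
            row_res.append(res)
            i += 1
        for slot in range(length + 1):
            if rng.random() < indel_rate:
                run = int(rng.geometric(0.5))
                row_ins[slot] = [AA20[rng.integers(0, 20)]
                                 for _k in range(int(run))]
        inserts.append(row_ins)
        kept.append(row_res)

    # Assemble truth columns: insertion columns (one per inserted residue,
    # rows in index order) interleaved before each ancestral column.
    columns = []  # (kind, payload); kind "ins": (row, residue), "anc": pos
    for slot in range(length + 1):
        for r in range(n_seqs):
            for res in inserts[r].get(slot, []):
                columns.append(("ins", (r, res)))
        if slot < length:
            columns.append(("anc", slot))

    rows = [[] for _ in range(n_seqs)]
    meta = []
    for kind, payload in columns:
        if kind == "ins":
            r0, res = payload
            for r in range(n_seqs):
                rows[r].append(res if r == r0 else GAP)
            meta.append(None)
        else:
            pos = payload
            present = 0
            for r in range(n_seqs):
                res = kept[r][pos]
                rows[r].append(res if res is not None else GAP)
                present += res is not None
            meta.append(pos if present == n_seqs else None)
    keep_cols = [c for c in range(len(columns))
                 if any(rows[r][c] != GAP for r in range(n_seqs))]
    rows = ["".join(rows[r][c] for c in keep_cols) for r in range(n_seqs)]
    core = [k for k, c in enumerate(keep_cols) if meta[c] is not None]

    seqs = []
    for r in range(n_seqs):
        residues, row_ss, row_sa, anc_pos = [], [], [], []
        for slot in range(length + 1):
            for res in inserts[r].get(slot, []):
                residues.append(res)
                row_ss.append("C")
                row_sa.append("e")
                anc_pos.append(None)
            if slot < length and kept[r][slot] is not None:
                residues.append(kept[r][slot])
                row_ss.append(ss[slot])
                row_sa.append(sa[slot])
                anc_pos.append(slot)
        n = len(residues)
        cm = np.full((n, n), CONTACT_BG)
        anc_idx = [(k, p) for k, p in enumerate(anc_pos) if p is not None]
        for ka, pa in anc_idx:
            for kb, pb in anc_idx:
                cm[ka, kb] = template[pa, pb]
        seqs.append(AnnotatedSequence(
            id=f"seq{r}", residues="".join(residues), ss="".join(row_ss),
            sa="".join(row_sa), cmap=ContactMap.from_array(cm)))

    truth = MultipleAlignment([s.id for s in seqs], rows)
    for s, row in zip(seqs, truth.rows):
        assert row.replace(GAP, "") == s.residues
    return seqs, truth, core


def make_twilight_pair(identity_target: float, seed: int, length: int = 100):
    """A sequence pair near a target identity with identical secondary
    structure and accessibility strings and a shared contact map — the
    remote-homolog regime where structure carries the alignment signal.

    Returns ``(seq_a, seq_b, truth, core)``; the true alignment is the
    gapless residue-by-residue pairing.
    """
    if not (0.0 < identity_target < 1.0):
        raise ValueError("identity_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ss = _run_string(rng, length, "HEC", 4, 10)
    sa = _run_string(rng, length, "eb", 3, 7)
    cmap = ContactMap.from_array(_contact_template(ss))
    x = "".join(AA20[rng.integers(0, 20)] for _ in range(length))
    n_mut = int(round((1.0 - identity_target) * length))
    pos = rng.choice(length, size=n_mut, replace=False)
    y = list(x)
    for p in pos:
        y[p] = _mutate(rng, y[p])
    y = "".join(y)
    realized = sum(a == b for a, b in zip(x, y)) / length
    if abs(realized - identity_target) > 0.05:
        raise RuntimeError("could not realize the requested identity")
    seq_a = AnnotatedSequence(id="twiA", residues=x, ss=ss, sa=sa, cmap=cmap)
    seq_b = AnnotatedSequence(id="twiB", residues=y, ss=ss, sa=sa, cmap=cmap)
    truth = MultipleAlignment(("twiA", "twiB"), (x, y))
    return seq_a, seq_b, truth, list(range(length))


def write_family(outdir, seqs, truth: MultipleAlignment, core) -> None:
    """Write a generated family to disk in the formats the aligner reads:
    FASTA sequences, FASTA-like SS/SA annotations, per-sequence RR contact
    files, the true alignment and the core-column mask."""
    out = Path(outdir)
    (out / "rr").mkdir(parents=True, exist_ok=True)
    with open(out / "sequences.fasta", "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")
    with open(out / "ss.fasta", "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.ss}\n")
    with open(out / "sa.fasta", "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.sa}\n")
    for s in seqs:
        with open(out / "rr" / f"{s.id}.rr", "w") as fh:
            p = s.cmap.probs
            for i in range(p.shape[0]):
                for j in range(i, p.shape[1]):
                    if p[i, j] > 0:
                        fh.write(f"{i + 1} {j + 1} 0 8 {p[i, j]:.6f}\n")
    with open(out / "truth.fasta", "w") as fh:
        for i, r in zip(truth.ids, truth.rows):
            fh.write(f">{i}\n{r}\n")
    with open(out / "core.txt", "w") as fh:
        fh.write("\n".join(str(c) for c in core) + "\n")
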