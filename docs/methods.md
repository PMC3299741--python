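# Methods

## Model overview

The aligner estimates, for every sequence pair, the matrix of posterior
probabilities that residue *i* of one sequence corresponds to residue *j* of
the other in the (unknown) true alignment, and then assembles a multiple
alignment that maximizes the accumulated posterior along a guide tree. Two
complementary posterior estimators are fused:

* a **partition function over global alignments** in which matched residue
  pairs are scored by a weighted sum of amino-acid substitution similarity,
  secondary-structure identity and solvent-accessibility identity — this is
  where predicted structure enters; and
* a **3-state pair hidden Markov model** decoded by forward–backward, which
  uses amino acids only and acts as a structure-agnostic prior.

The entrywise root mean square of the two matrices slightly favours the
larger estimate while preserving [0, 1] bounds, and means that structural
weighting can sharpen but never fully silence the sequence evidence (and
vice versa).

### Alignment grammar

The partition recursion uses one match state and two gap states with affine
penalties: the first column of a gap run costs `β·gap_open`, each further
column `β·gap_ext`. Gap states feed only from the match state and from
themselves, so a gap column in one sequence can never be directly adjacent
to a gap column in the other. This is the standard convention for affine
partition functions (it removes an ambiguity that would otherwise double-
count alignments differing only in the order of adjacent opposite gaps);
the enumeration oracles in the test suite implement the same grammar.
Terminal gaps are penalized like internal ones. One consequence worth
knowing: two length-1 sequences admit exactly one alignment (the match),
not three.

### Posterior from the lattice

With forward lattice `F` and the same recursion run on the reversed
sequences giving the suffix partition `F′`, the structure-aware posterior is

    p¹(i, j) = F(i−1, j−1) · e^{score(i,j)} · F′(i+1, j+1) / F(n₁, n₂).

Splitting at a match column is exact because the match breaks every gap run
and the grammar is reversal-symmetric. The reverse lattice is computed by
the identical code path on reversed inputs (one implementation, fewer
defects). Posteriors are validated to exceed 1 by at most 1e-6 (anything
larger aborts — it would indicate a defect, not rounding) and are then
clamped to [0, 1].

### Scoring terms and their scales

* **Substitution matrix.** A Gonnet-family log-odds table (tenth-bit units,
  from Biopython), with a zero-scoring 'X' row for unknown residues. Any
  whitespace table can be substituted via `SubstitutionMatrix.from_table`.
* **β = 0.2** (inverse temperature): controls how much probability mass
  suboptimal alignments keep. Smaller β → flatter posterior. The default and
  the gap penalties (open −22, extend −1 on the substitution-score scale)
  follow the established partition-function aligner lineage for
  Gonnet-style tables.
* **β placement.** As printed in the recursion, β multiplies only the
  amino-acid term; the structural terms enter the exponent unscaled, so with
  W₂ = 0.5 a secondary-structure match multiplies an alignment's weight by
  e^{0.5} ≈ 1.65 regardless of β. The alternative reading (β scales the
  whole sum) is available via `beta_scales_structure`.
* **W₁/W₂/W₃ = 0.4/0.5/0.1** weight amino acid, secondary structure and
  accessibility inside the exponent (they must sum to 1); **W₅ = wc = 0.9**
  weights the contact term in the distance, with W₄ = 1 − wc on the
  normalized optimal alignment score. When a sequence lacks a contact map
  the distance falls back to W₄ = 1 (mirroring benchmark practice where
  contact predictions are only available for a subset of inputs).

### Pair-HMM parameters

Transitions use a single-affine parameterization: gap-open δ = 0.019931223
(per insert state), gap-extend ε = 0.79433459; the initial distribution
equals the match row, i.e. a path behaves as if preceded by a virtual match.
Match emissions are the joint residue-pair probabilities implied by the
BLOSUM62 log-odds table at its canonical half-bit scale: background
frequencies *f* solve `Σ_b f_b·2^{S(a,b)/2} = 1`, the joint is
`p(a,b) = f_a·f_b·2^{S(a,b)/2}` (symmetrized, renormalized), and insert
emissions are its marginals. 'X' emits like an average residue. Deriving the
tables at import keeps the package free of copied data files while remaining
fully deterministic; experts can override everything from YAML
(`params_from_yaml`). Direct I_x ↔ I_y transitions are disallowed, matching
the partition grammar.

### Distances, guide tree, weights

The optimal pair alignment under the fused posterior is found by the
monotone-matching DP (`AS(i,j) = max(AS(i−1,j−1)+p(i,j), AS(i−1,j),
AS(i,j−1))`, gaps scoring 0, ties broken diagonal > up > left). The contact
score restricts both contact maps to the matched positions and takes
`(1/n²)·Σᵢⱼ x′ᵢⱼ y′ⱼᵢ` — computed diagonally, without forming the matrix
product; an empty matched set scores 0 by convention. Distances are clamped
to [0, 1] against floating-point drift (the un-clamped value is provably
≥ 0 because posterior entries are ≤ 1).

UPGMA merges the closest clusters with leaf-count-weighted distance updates
(equivalently: cluster distances stay the mean over original leaf pairs).
Ties are broken by the smallest cluster-index pair so runs are reproducible
across platforms. Sequence weights divide each branch length equally among
the leaves below it; identical sequences (an all-zero tree) fall back to
uniform 1/N, and individual zero weights (zero-length terminal branches) are
floored at 1e-8 of the total weight so that downstream weighted means are
always well defined.

### Consistency and progressive stages

One synchronous consistency round (configurable) re-estimates every P_XY
through all third sequences; entries below the sparsity cutoff (default
0.01, 0 in tests) are dropped *after* the relay products. For N = 2 the
transform is the identity and is returned without arithmetic so the fixed
point is exact. Profile–profile scores are the w_X·w_Y-weighted mean of
cross-pair posteriors at the residues occupying each column pair, gap
occupants contributing 0. Refinement draws a uniform nonempty proper
bipartition per iteration (rejection sampling over per-sequence coin flips),
strips all-gap columns from each half, realigns, and accepts
unconditionally — the predecessor aligners' behaviour; with no acceptance
rule stated for the method this is a documented design choice, and on easy
inputs refinement is close to neutral. Ten iterations by default; the RNG
seed is surfaced everywhere, and the whole pipeline is serial and
byte-deterministic (a `--threads` flag is accepted for compatibility but
results never depend on it).

## Synthetic data

`make_family` draws an ancestor with block-wise secondary structure (runs of
4–10), run-wise burial states (3–7), uniform residues, and evolves each
descendant by independent substitutions (probability `sub_rate` per site)
and geometric(0.5)-length insertions/deletions (probability `indel_rate`
per site), with exact truth bookkeeping. Structure strings are inherited at
surviving positions (insertions get coil/exposed); contact maps put 0.9 on
antiparallel pairings of consecutive strand blocks over a 0.05 background —
a detectable but deliberately imperfect signal. Core columns are those no
indel touched (all rows occupied, ancestral), matching how curated
benchmarks restrict scoring to reliably aligned blocks. `make_twilight_pair`
produces equal-length pairs at a controlled identity (default experiments
use 0.15) with *identical* structure strings and a shared contact map — the
remote-homolog regime the structural terms exist for.

What the generator does **not** emulate: realistic substitution processes
(no rate matrices or site-rate variation, so amino-acid composition is
uniform), structure-dependent mutation biases, predictor errors correlated
along the chain, or length-dependent indel placement. Passing tests
therefore demonstrate the machinery is correct and that structural signal
is exploited when present; they do not certify accuracy levels on real
protein families.

## Evaluation

SP is the fraction of residue pairs co-aligned in the reference's core
columns that the test alignment also co-aligns; TC the fraction of core
columns (those holding ≥ 2 residues) reproduced intact. Residues are
identified by (sequence, ordinal), making both scores invariant to row
order and gap placement. Note TC ≤ SP is guaranteed only when core columns
contain every sequence (as fixture cores do); with ragged cores a recovered
small column can outweigh its pair count.

## Problem sizes in the shipped experiments

The test suite and the acceptance script use families of 4–6 sequences of
length 25–80 and 25 twilight pairs of length 100; oracle-equivalence checks
enumerate alignments/paths exhaustively at lengths ≤ 4 over a reduced
alphabet (200 random pairs per dynamic program) and matchings up to 5×6.
These sizes exercise every code path (multiple merges, refinement splits,
contact pairing) while keeping a full run in seconds.

## Known limitations

* The consistency relay uses dense matrix products; beyond a few hundred
  sequences the O(N³) relay sum and O(N²) posterior storage dominate.
* Unconditional acceptance in refinement can (rarely) end on a slightly
  worse alignment than it started from; a score-guarded variant would need
  an objective the method does not define.
* Identity SS/SA matrices ignore near-miss states (H vs. G-like helices are
  already folded together at parsing); graded structural similarity
  matrices are a known possible refinement, deliberately out of scope.
* The partition grammar's exclusion of adjacent opposite gaps is a modelling
  convention; alignments requiring such renderings are representable (the
  gapless pairing is unchanged) but receive no separate probability mass.
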