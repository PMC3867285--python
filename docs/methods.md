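# Methods

This note documents the scoring model, its parameters and defaults, the
numerical conventions, and the limits of what the synthetic test fixtures
demonstrate.

## Setting

The input is a multiple sequence alignment of related proteins (FASTA or
GCG-MSF), optionally split into K ≥ 2 user-defined groups (typically
paralogous families, or orthologues from distinct taxonomic groups). All
scores are per-column heuristics: each alignment column i is summarized by
its amino-acid frequency vector f(i) over the 20 standard types, computed
over non-gap, non-missing symbols (any letter outside the 20 types is
normalized to `X` and treated as missing; MSF gap dialects `.`/`~` are
normalized to `-`). Columns are assumed independent; no probabilistic
model of the substitution process is fitted — these are frequentist
heuristics whose absolute values carry no intrinsic meaning, which is why
every score is reduced to a rank and a top fraction before presentation.

## Conservation scores

Five per-column scorers, each a function of f(i) (and, where noted, of
residue similarity or the sequence-similarity tree):

* **Shannon entropy**: s(i) = −Σ_a f_a ln f_a (natural log, 0·ln 0 := 0).
  Lower = more conserved; 0 for an invariant column, ln 20 ≈ 2.996 at the
  uniform maximum. Optionally computed over a reduced alphabet (below).
* **Majority fraction**: s(i) = max_a f_a. Higher = more conserved.
* **Valdar's score**: weighted mean pairwise similarity,
  s(i) = Σ_{j<k} w_j w_k m(s_j, s_k) / Σ_{j<k} w_j w_k over non-gap pairs,
  with m = BLOSUM62 min-max rescaled to [0, 1] over its 20×20 range (so a
  column of tryptophans, the diagonal maximum, scores exactly 1). The
  sequence weights w_j — mean distance of sequence j to all others
  (distance = 1 − fractional identity over jointly non-gap columns),
  normalized to mean 1, with a 1e−6 additive guard so duplicated
  sequences keep nonzero weight — correct for uneven taxonomic sampling.
* **Real-valued Evolutionary Trace (rvET)**:
  ρ(i) = 1 + Σ_{n=1}^{N−1} (1/n) Σ_{g ∈ cut(n)} H_g(i), where cut(n) is
  the partition of the sequences into n groups obtained from the
  similarity tree and H_g is the column entropy within group g (groups
  with no contributing symbol contribute 0). Lower = more conserved;
  exactly 1 for an invariant column. The 1/n level weighting is this
  package's fixed convention and the single most consequential knob:
  published ET variants weight tree levels differently, so ranks may
  differ from other implementations in detail.
* **Integer-valued ET (ivET)**: the smallest n such that the column is
  invariant (over contributing symbols; an all-gap group counts as
  invariant) within every group of cut(n); N if none. Lower = more
  conserved.

The similarity tree is UPGMA (average linkage) over 1 − fractional
identity, chosen over neighbor joining because its cuts are
height-monotone and nested by construction, which is all ET needs; the
tree can be exported as Newick. `cut(n)` is realized by replaying the
first N − n merges of the linkage, which guarantees exactly n groups and
nesting even under tied heights.

**Gap handling.** Frequencies ignore gaps; a column whose gap-plus-missing
fraction exceeds 0.5 is still scored but flagged, and ranking forces
flagged columns into the worst tier (all sharing the tail's mean rank).
An all-gap column is a sentinel: entropy gets ln 20 + 1 (strictly beyond
any attainable value), majority and Valdar get 0.

**Default method** is rvET.

## Specialization scores

For K groups, the per-column group profiles f^g(i) are compared pairwise
through the histogram-intersection overlap
o_gh(i) = Σ_a min(f_a^g, f_a^h) ∈ [0, 1] — symmetric, 1 for identical
distributions, 0 for disjoint supports. Two scores are derived, with
c_g = majority fraction within group g as the within-group conservation
factor (chosen over entropy so every factor, and hence every product,
lives in [0, 1]):

* **Discriminant** (positions unique to *one* group; type I divergence
  when that group is conserved): d_g = c_g · (1 − max_{h≠g} o_gh);
  pooled score max_g d_g. The max over competitors is the strictest
  reading of "unique": one similar group suffices to spoil it.
* **Determinant** (positions unique for *each* group —
  conserved-but-different, type II divergence):
  D = (min_g c_g) · (1 − max_{g<h} o_gh). Since min ≤ max over the same
  factors, D never exceeds the pooled discriminant.

**Similarity correction** ("cube with similarity"). A Markov chain on the
20 types is built from the BLOSUM62 joint frequencies: q(a, b) is
reconstructed as q ∝ p_a p_b 2^(s_ab/2) from the published background
frequencies p and the half-bit log-odds s, normalized to sum 1; then
M[a,b] = q(a,b)/Σ_c q(a,c) and π_a = Σ_b q(a,b). Symmetry of q gives
detailed balance π_a M[a,b] = π_b M[b,a] exactly, hence stationarity;
every initial distribution converges to π (L1 distance to π is
non-increasing and < 1e−6 after 512 steps). The corrected overlap is
o_gh / max(E_gh, 1e−6), clipped to [0, 1], where the expected overlap
E_gh is the overlap after both observed profiles evolve k steps under M
("freely evolving" null). Default k = 2 (`--evo-steps`): small enough
that E stays informative (at k → ∞ all E → 1 and the correction
vanishes), large enough to spread mass onto biochemical neighbours. The
calibration of k is this package's own choice and no claim is made that
it reproduces any other implementation.

*Known limitation*: for columns with zero raw overlap (fully disjoint
supports) the ratio is 0 regardless of the expected overlap, so the
correction cannot down-weight a conserved D-vs-E split relative to a
D-vs-K split; it only discounts columns with nonzero raw overlap.

A specialization run always also computes pooled-alignment Shannon
entropy, and the report lays conservation and specialization out
side-by-side per residue.

## Rank normalization and color coding

Each score vector is converted to ranks (best = most conserved, or most
specialized, first; ties share their mean rank, so output never depends
on input sequence order) and to top fractions rank/L ∈ (0, 1]. Top
fractions map to decile bins 1–10 on a fixed red→white→blue ramp (bin 1 =
top decile = red), used identically by the CSV/XLSX table, the 1D PNG map
(60 residues per row, solid color cells, ruler every 10 residues) and the
PyMOL script (one named selection per non-empty decile, per score set;
score sets are stored as scenes so conservation and specialization views
can be toggled; hiding a selection hides that tier). "xls" output is
realized as CSV plus XLSX with cell-identical content.

## Structure mapping

The reference sequence (default: first sequence of the first input file)
is globally aligned to the selected PDB chain's standard-residue sequence
(BLOSUM62, gap open −10, extend −1); aligned pairs become a monotone
one-to-one residue mapping, kept in the chain's author numbering with
insertion codes. Coverage < 0.3 triggers a mismatch warning. Surface
accessibility comes from a pre-computed classic-format DSSP file:
absolute ACC divided by the residue type's theoretical maximum ASA,
clipped to [0, 1]; a missing DSSP file degrades to NA, never to failure.
The PyMOL deliverable is a text `.pml` script (diffable, version-stable)
rather than a binary session; running it in PyMOL and saving reproduces
the session functionally.

## Reduced alphabets

Default 7-class partition {AVLIMC} {FWYH} {STNQ} {KR} {DE} {G} {P}
(aliphatic/sulfur, aromatic, polar, basic, acidic, glycine, proline),
user-overridable as `"CLASS1=AVLIMC;CLASS2=FWYH;..."`; applies to entropy
and majority only (Valdar already encodes similarity through BLOSUM; ET
operates on raw types).

## Synthetic fixtures: what they show and what they do not

The fixture generator emulates grouped, pre-aligned input: background
columns draw residues independently from the chain equilibrium π, and
three signal columns are planted at recorded positions — jointly
invariant, conserved-but-different (each group a distinct residue), and
group-unique (one group conserved, others free). Default conditions:
2 groups × 8 sequences × 30 columns, matching the recovery tests (100
seeded fixtures; the planted conserved-but-different column must win the
determinant ranking in ≥ 95, the invariant column the entropy ranking in
all). A deterministic CA-only poly-alanine chain of the reference's
length accompanies each fixture so the structure path runs end to end.

These fixtures have no gaps, no phylogenetic correlation between columns
and i.i.d. background, so passing them demonstrates correctness of the
scoring arithmetic and the planted-signal contrast — not robustness to
misalignment, fragmentary sequences, or skewed taxonomic sampling, which
in real data dominate the ranking quality. No fragment filter is applied
to sequences of unequal coverage.

## Numerical conventions

Natural logarithms throughout; entropy of an empty support is 0 by the
0·ln 0 convention. Oracle tests pin every scorer to an independent
direct-loop re-implementation at 1e−12 on small random alignments.
Problem sizes used by the verification script (200 random alignments of
≤ 6 sequences × ≤ 8 columns; 100 fixtures of 2 × 8 × 30; 100 random
profiles for chain convergence) were chosen so the whole run completes in
seconds while exercising every code path. CSV and `.pml` outputs are
byte-deterministic for identical inputs and flags; the `.pml` loads the
PDB by file name so the script is location-independent.
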