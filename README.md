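# cube-scoring

Per-residue **conservation** and **specialization** scoring for protein
multiple sequence alignments, for biochemists and molecular biologists
planning mutagenesis or binding-partner experiments: which residues are
important to the whole family, and which make the subfamilies differ?

Given an alignment (FASTA or GCG-MSF), the `cube` tool scores every
column with up to five conservation heuristics — Shannon entropy
s(i) = −Σ_a f_a(i) ln f_a(i), majority fraction max_a f_a(i), Valdar's
sequence-weighted BLOSUM62 similarity, and real-/integer-valued
Evolutionary Trace over a UPGMA similarity tree. Given the sequences
split into K ≥ 2 groups (paralogous families, taxonomic groups), it
scores group specialization from the pairwise histogram-intersection
overlap o_gh(i) = Σ_a min(f_a^g, f_a^h):

* **discriminant** — max_g c_g (1 − max_{h≠g} o_gh): the position is
  unique to one (conserved) group;
* **determinant** — (min_g c_g)(1 − max_{g<h} o_gh): the position is
  conserved in *every* group but as different types
  ("conserved-but-different");

with c_g the within-group majority fraction, and optionally a similarity
correction that divides each overlap by the overlap expected for
distributions evolving freely under a BLOSUM62-equilibrium Markov chain.
All scores are turned into ranks and expressed as the top fraction they
represent; a fixed red→white→blue decile ramp colors the spreadsheet
(CSV/XLSX), a 1D PNG sequence map, and a PyMOL `.pml` script that paints
the scores onto a PDB chain (with DSSP accessibility merged into the
table when available). See `docs/methods.md` for formulas, defaults and
limitations.

## Worked example

Generate a deterministic two-group fixture (8 sequences per group, 30
columns, with a planted jointly invariant column, a planted
conserved-but-different column and a planted group-unique column), then
run the specialization analysis with structure mapping:

```sh
cube fixture --seed 7 --out fx
cube spec --group fx/group_1.fasta --group fx/group_2.fasta \
     --pdb fx/toy.pdb --out run
# INFO cube: scored 30 columns (0 flagged); wrote 3 files
```

`run.spec.csv` holds one row per residue of the reference sequence
(`g1_s1`), conservation and specialization side-by-side. The three
planted positions (fixture manifest: columns 5, 15, 25) come out as:

```
residue_number,residue,...,entropy_score,entropy_top_fraction,discriminant_score,...,determinant_score,determinant_top_fraction,...
5,G,5,0.0,0.0333...,0.0,...,0.0,1.0,...
15,D,15,0.6931...,0.0666...,1.0,...,1.0,0.0333...,...
25,R,25,1.6462...,0.1,...,0.25,0.1333...,...
```

Residue 5 is the jointly invariant column: entropy 0, the best (top-3%)
conservation rank, but zero specialization. Residue 15 is
conserved-but-different (all D in group 1, all K in group 2): entropy
ln 2 ≈ 0.693 yet determinant 1.0 and determinant top fraction 1/30 — the
top-ranked determinant position. Residue 25 is unique to group 1 (all R;
group 2 free): discriminant 1.0 for group 1, but determinant only 0.25
because group 2 is not conserved. `run.map.png` shows the same ranks as
a color strip along the sequence, and `run.pml` (opened in PyMOL from
the directory holding the PDB) colors the chain by decile, with
conservation and specialization stored as switchable scenes and each
decile in a named selection (`cube_bin01` … `cube_bin10`) so poorly
scoring tiers can be hidden.

Conservation-only analysis works the same way from a single alignment:

```sh
cube cons --aln fx/group_1.fasta --method rvet --method entropy \
     --annot notes.csv --dssp chain.dssp --out run2
```

optionally merging a user annotation table (`seq_id,residue_number,note`,
numbered on *any* sequence of the alignment) and DSSP accessibility into
the report.

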