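"""Synthetic grouped-alignment fixtures with planted signal columns.

The generator emulates the tool's target input: K paralogous groups of
pre-aligned protein sequences. Background columns draw residues
independently from the equilibrium distribution of the BLOSUM substitution
chain (the "freely evolving" null); on top of that it plants, at recorded
positions,

* a jointly invariant column (conserved across all groups),
* a conserved-but-different column (each group invariant, all groups
  pairwise distinct) — the determinant-score signal,
* a group-unique column (one group invariant, the others free) — the
  discriminant-score signal.

A manifest records the planted positions so recovery tests can consume
them, and a matching CA-only toy PDB chain (poly-alanine, same length as
the reference) supports the structure pipeline end to end.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .msa_io import Alignment, GroupedAlignment, write_fasta
from .profiles import AA, blosum_chain

# Planted residues per group for the conserved-but-different column; chosen
# pairwise dissimilar under BLOSUM62.
_DETERMINANT_RESIDUES = "DKWGPFHC"
_INVARIANT_RESIDUE = "G"
_UNIQUE_RESIDUE = "R"


def synthesize_groups(seed: int, n_groups: int = 2, n_seqs: int = 8,
                      n_cols: int = 30,
                      ) -> tuple[GroupedAlignment, dict[str, int]]:
    """Build the grouped alignment in memory; returns it with the plant map.

    Planted 1-based columns sit at roughly 1/6, 1/2 and 5/6 of the
    alignment width (invariant, determinant, discriminant).
    """
    if n_groups < 2 or n_groups > len(_DETERMINANT_RESIDUES):
        raise ValueError(f"n_groups must be in 2..{len(_DETERMINANT_RESIDUES)}")
    if n_cols < 3:
        raise ValueError("need at least 3 columns to plant 3 signals")
    rng = np.random.default_rng(seed)
    pi = blosum_chain().pi
    col_invariant = max(1, round(n_cols / 6))
    col_determinant = max(col_invariant + 1, round(n_cols / 2))
    col_discriminant = min(n_cols, max(col_determinant + 1, round(5 * n_cols / 6)))
    planted = {
        "invariant_column": col_invariant,
        "determinant_column": col_determinant,
        "discriminant_column": col_discriminant,
    }
    aa = np.array(list(AA))
    ids: list[str] = []
    seqs: list[str] = []
    group_of: dict[str, int] = {}
    for g in range(n_groups):
        block = aa[rng.choice(20, size=(n_seqs, n_cols), p=pi)]
        block[:, col_invariant - 1] = _INVARIANT_RESIDUE
        block[:, col_determinant - 1] = _DETERMINANT_RESIDUES[g]
        if g == 0:
            block[:, col_discriminant - 1] = _UNIQUE_RESIDUE
        for s in range(n_seqs):
            sid = f"g{g + 1}_s{s + 1}"
            ids.append(sid)
            seqs.append("".join(block[s]))
            group_of[sid] = g
    grouped = GroupedAlignment(Alignment(tuple(ids), tuple(seqs)), group_of)
    return grouped, planted


def write_toy_pdb(path: str | Path, n_residues: int, chain_id: str = "A") -> None:
    """CA-only poly-alanine chain on a deterministic helical spiral."""
    lines = []
    for i in range(n_residues):
        t = i * 100.0 * math.pi / 180.0  # ~100 deg per residue, helix-like
        x, y, z = 2.3 * math.cos(t), 2.3 * math.sin(t), 1.5 * i
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA {chain_id}{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f" C")
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def make_fixture(seed: int, out_dir: str | Path, n_groups: int = 2,
                 n_seqs: int = 8, n_cols: int = 30) -> dict:
    """Write grouped FASTA fixtures, a manifest, and a toy PDB.

    Byte-identical on repeat invocation with the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grouped, planted = synthesize_groups(seed, n_groups, n_seqs, n_cols)
    aln = grouped.alignment
    group_files = []
    for g in range(n_groups):
        members = grouped.group_ids(g)
        sub = Alignment(tuple(members), tuple(aln.sequence(i) for i in members))
        path = out_dir / f"group_{g + 1}.fasta"
        write_fasta(sub, path)
        group_files.append(path.name)
    pdb_path = out_dir / "toy.pdb"
    reference_id = aln.ids[0]
    write_toy_pdb(pdb_path, len(aln.ungapped(reference_id)))
    manifest = {
        "seed": seed,
        "n_groups": n_groups,
        "n_seqs_per_group": n_seqs,
        "n_cols": n_cols,
        "reference_id": reference_id,
        "group_files": group_files,
        "pdb_file": pdb_path.name,
        "planted": planted,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
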