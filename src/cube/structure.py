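"""Structure adapter: PDB chain extraction, reference-to-chain mapping,
DSSP accessibility, and the PyMOL coloring script.

The scored chain is identified in the PDB file (first chain with standard
residues, or user-specified), its sequence is globally aligned to the
reference sequence to obtain a monotone one-to-one residue mapping, and
per-residue decile bins are emitted as PyMOL selections colored with the
same red-white-blue ramp as the table and the PNG map. Surface
accessibility comes from a pre-computed classic-format DSSP file,
normalized by per-type maximum accessible surface area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser

from .ranking import bin_color

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Theoretical maximum accessible surface area per residue type (A^2),
#: Tien et al. theoretical values; used to normalize DSSP ACC to [0, 1].
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

ResidueId = tuple[int, str]  # author residue number, insertion code ('' if none)


@dataclass
class ChainModel:
    """One PDB chain's mappable residues plus surrounding context."""

    chain_id: str
    residues: list[tuple[ResidueId, str]]  # ((resnum, icode), 1-letter type)
    other_chains: list[str]
    het_records: list[str]  # ligand residue names (waters excluded)

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)


@dataclass
class StructureMapping:
    """Monotone one-to-one pairing of reference residues to chain residues."""

    pairs: list[tuple[int, ResidueId]]  # (reference residue number, chain id)
    coverage: float
    unmapped_reference: list[int]
    unmapped_chain: list[ResidueId]

    def chain_residue(self, ref_resnum: int) -> ResidueId | None:
        for r, c in self.pairs:
            if r == ref_resnum:
                return c
        return None


def read_pdb_chain(path: str | Path, chain_id: str | None = None) -> ChainModel:
    """Extract one chain (first MODEL only) from a PDB file.

    Standard amino acids form the mappable sequence; HETATM residues are
    kept as ligand context. Without ``chain_id``, the first chain holding
    at least one standard residue is used.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sloppy toy PDB headers
        model = PDBParser(QUIET=True).get_structure("s", str(path))[0]
    chains = list(model)
    available = [c.id for c in chains]
    target = None
    if chain_id is None:
        for c in chains:
            if any(r.id[0] == " " and r.resname in THREE_TO_ONE for r in c):
                target = c
                break
        if target is None:
            raise ValueError(f"{path}: no chain with standard residues found")
    else:
        for c in chains:
            if c.id == chain_id:
                target = c
                break
        if target is None:
            raise ValueError(
                f"{path}: chain '{chain_id}' not found; available: "
                f"{', '.join(available)}")

    residues: list[tuple[ResidueId, str]] = []
    hets: list[str] = []
    for r in target:
        hetfield, resnum, icode = r.id
        if hetfield == " " and r.resname in THREE_TO_ONE:
            residues.append(((resnum, icode.strip()), THREE_TO_ONE[r.resname]))
        elif hetfield.startswith("H_"):
            hets.append(r.resname)
    for c in chains:
        if c is not target:
            for r in c:
                if r.id[0].startswith("H_"):
                    hets.append(r.resname)
    if not residues:
        raise ValueError(
            f"{path}: chain '{target.id}' has no standard residues")
    others = [c.id for c in chains if c is not target]
    return ChainModel(chain_id=target.id, residues=residues,
                      other_chains=others, het_records=sorted(set(hets)))


def map_reference_to_chain(reference_seq: str,
                           chain: ChainModel) -> StructureMapping:
    """Global pairwise alignment of reference to chain sequence.

    BLOSUM62, gap open -10, extend -1; aligned residue pairs (identical or
    substituted) become mapping entries. Coverage below 0.3 logs a warning
    that the structure may not match the reference.
    """
    if not reference_seq or not chain.residues:
        raise ValueError("both sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(reference_seq, chain.sequence)[0]
    pairs: list[tuple[int, ResidueId]] = []
    for (rs, re_), (cs, ce) in zip(*aln.aligned):
        for off in range(re_ - rs):
            pairs.append((rs + off + 1, chain.residues[cs + off][0]))
    mapped_ref = {r for r, _ in pairs}
    mapped_chain = {c for _, c in pairs}
    coverage = len(pairs) / len(reference_seq)
    if coverage < 0.3:
        log.warning("structure may not match reference (coverage %.2f)", coverage)
    return StructureMapping(
        pairs=pairs,
        coverage=coverage,
        unmapped_reference=[i for i in range(1, len(reference_seq) + 1)
                            if i not in mapped_ref],
        unmapped_chain=[rid for rid, _ in chain.residues
                        if rid not in mapped_chain])


def read_dssp(path: str | Path | None, chain_id: str) -> dict[ResidueId, float]:
    """Relative accessibility per chain residue from classic DSSP output.

    Absolute ACC is divided by the per-type maximum ASA and clipped to
    [0, 1]. A missing file yields an empty map (all accessibilities NA);
    malformed data lines are skipped with a logged warning.
    """
    out: dict[ResidueId, float] = {}
    if path is None:
        return out
    path = Path(path)
    if not path.exists():
        log.warning("DSSP file %s not found; accessibility reported as NA", path)
        return out
    in_body = False
    for line in path.read_text().splitlines():
        if not in_body:
            if line.lstrip().startswith("#  RESIDUE AA"):
                in_body = True
            continue
        if len(line) < 38:
            if line.strip():
                log.warning("skipping malformed DSSP line: %r", line)
            continue
        aa = line[13]
        if aa == "!":  # chain break
            continue
        if line[11].strip() != chain_id.strip():
            continue
        try:
            resnum = int(line[5:10])
            icode = line[10].strip()
            acc = float(line[34:38])
        except ValueError:
            log.warning("skipping malformed DSSP line: %r", line)
            continue
        max_asa = MAX_ASA.get(aa.upper())
        if max_asa is None:
            continue
        rel = acc / max_asa
        if rel > 1.0:
            log.warning("DSSP ACC %.0f exceeds max ASA for %s; clipped", acc, aa)
            rel = 1.0
        out[(resnum, icode)] = max(0.0, rel)
    return out


def _resi_token(rid: ResidueId) -> str:
    resnum, icode = rid
    return f"{resnum}{icode}" if icode else str(resnum)


def emit_pymol_script(chain: ChainModel, mapping: StructureMapping,
                      tracks: Mapping[str, Mapping[int, int]],
                      out_path: str | Path, pdb_path: str | Path) -> Path:
    """Write a PyMOL .pml script coloring the scored chain by decile.

    ``tracks`` maps a track name (e.g. "rvet" or "determinant") to
    {reference residue number -> decile bin}. Each track contributes ten
    named selections (<prefix>_bin01..10, first track prefix ``cube``) and
    a stored scene, so multiple score sets can be toggled; hiding a
    selection hides its poorly scoring residues. Other chains are drawn as
    cartoon and ligands as sticks for context.
    """
    if not mapping.pairs:
        raise ValueError("empty structure mapping")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    by_ref = dict(mapping.pairs)
    # load by file name: the script is portable and meant to be run from
    # the directory holding the PDB file
    lines = [
        f"load {Path(pdb_path).name}, cube_struct",
        "hide everything",
        "bg_color white",
        "show cartoon, cube_struct",
        "color grey80, cube_struct",
    ]
    if chain.other_chains:
        sel = " or ".join(f"chain {c}" for c in chain.other_chains)
        lines += [f"select cube_context, cube_struct and ({sel})",
                  "show cartoon, cube_context"]
    lines += ["select cube_ligands, cube_struct and hetatm and not resn HOH",
              "show sticks, cube_ligands"]
    for b in range(1, 11):
        r, g, bl = (v / 255.0 for v in bin_color(b))
        lines.append(f"set_color cube_col{b:02d}, [{r:.3f},{g:.3f},{bl:.3f}]")

    for t_idx, (track, bins) in enumerate(tracks.items()):
        prefix = "cube" if t_idx == 0 else f"cube{t_idx + 1}"
        lines.append(f"# score set '{track}' -> selections {prefix}_bin01..10")
        for b in range(1, 11):
            members = sorted(
                (by_ref[r] for r, bb in bins.items() if bb == b and r in by_ref))
            if not members:
                continue
            resi = "+".join(_resi_token(m) for m in members)
            lines.append(
                f"select {prefix}_bin{b:02d}, cube_struct and chain "
                f"{chain.chain_id} and resi {resi}")
            lines.append(f"color cube_col{b:02d}, {prefix}_bin{b:02d}")
        lines += [
            f"show surface, cube_struct and chain {chain.chain_id}",
            f"show cartoon, cube_struct and chain {chain.chain_id}",
            f"scene {track}, store",
        ]
    lines += [
        "# hide a poorly scoring tier with e.g.: hide surface, cube_bin10",
        "deselect",
    ]
    out_path.write_text("\n".join(lines) + "\n")
    return out_path
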