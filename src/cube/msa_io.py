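"""Alignment input/output and validation.

Reads aligned FASTA and GCG-MSF files into a single :class:`Alignment`
container, assembles grouped inputs for specialization scoring, and parses
user annotation tables keyed by per-sequence residue numbers.

All sequences are normalized on input: upper-cased, MSF gap dialects
(``.`` and ``~``) mapped to ``-``, and any letter outside the 20 standard
amino acids mapped to ``X`` (treated as missing by every scorer).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING = "X"

_GAP_DIALECTS = str.maketrans({".": GAP, "~": GAP})


class AlignmentError(ValueError):
    """Raised on malformed or inconsistent alignment input."""


def normalize_sequence(seq: str) -> str:
    """Upper-case, unify gap dialects, map non-standard letters to 'X'."""
    s = seq.upper().translate(_GAP_DIALECTS)
    return "".join(c if (c in STANDARD_AA or c == GAP) else MISSING for c in s)


@dataclass(frozen=True)
class Alignment:
    """An in-memory multiple sequence alignment.

    ``ids`` and ``seqs`` are parallel, order-preserving lists; every
    sequence has the same length and is drawn from the alphabet of the 20
    standard amino acids plus ``X`` (missing) and ``-`` (gap).
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in count")
        if not self.ids:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            bad = next(i for i, s in zip(self.ids, self.seqs)
                       if len(s) != len(self.seqs[0]))
            raise AlignmentError(
                f"sequences are not aligned: '{bad}' has a different length")
        if self.length < 1:
            raise AlignmentError("alignment has zero columns")
        seen: set[str] = set()
        for i in self.ids:
            if i in seen:
                raise AlignmentError(f"duplicate sequence id '{i}'")
            seen.add(i)

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def sequence(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"unknown sequence id '{seq_id}'") from None

    def ungapped(self, seq_id: str) -> str:
        return self.sequence(seq_id).replace(GAP, "")

    def column(self, column_index: int, subset: Iterable[str] | None = None) -> str:
        """Column symbols (1-based index), optionally restricted to ``subset`` ids."""
        if not 1 <= column_index <= self.length:
            raise IndexError(f"column {column_index} out of range 1..{self.length}")
        j = column_index - 1
        if subset is None:
            return "".join(s[j] for s in self.seqs)
        wanted = set(subset)
        return "".join(s[j] for i, s in zip(self.ids, self.seqs) if i in wanted)

    def residue_to_column(self, seq_id: str, residue_number: int) -> int:
        """1-based ungapped residue number -> 1-based alignment column."""
        seq = self.sequence(seq_id)
        count = 0
        for j, c in enumerate(seq, start=1):
            if c != GAP:
                count += 1
                if count == residue_number:
                    return j
        raise IndexError(
            f"residue {residue_number} beyond ungapped length of '{seq_id}'")

    def column_to_residue(self, seq_id: str, column_index: int) -> int | None:
        """1-based column -> 1-based residue number on ``seq_id``; None on gap."""
        seq = self.sequence(seq_id)
        if seq[column_index - 1] == GAP:
            return None
        return sum(1 for c in seq[:column_index] if c != GAP)


@dataclass(frozen=True)
class GroupedAlignment:
    """A joint alignment plus an id -> group-index assignment (K >= 2 groups)."""

    alignment: Alignment
    group_of: dict[str, int]

    def __post_init__(self) -> None:
        ids = set(self.alignment.ids)
        if set(self.group_of) != ids:
            raise AlignmentError("group assignment does not cover all sequence ids")
        groups = set(self.group_of.values())
        k = len(groups)
        if k < 2:
            raise AlignmentError("need at least two groups")
        if groups != set(range(k)):
            raise AlignmentError("group indices must be contiguous from 0")

    @property
    def n_groups(self) -> int:
        return len(set(self.group_of.values()))

    def group_ids(self, g: int) -> tuple[str, ...]:
        return tuple(i for i in self.alignment.ids if self.group_of[i] == g)


@dataclass
class AnnotationTable:
    """User annotations: (seq_id, 1-based ungapped residue number, note)."""

    rows: list[tuple[str, int, str]] = field(default_factory=list)

    def validate_against(self, alignment: Alignment) -> None:
        for seq_id, resnum, note in self.rows:
            if seq_id not in alignment.ids:
                raise AlignmentError(
                    f"annotation row ({seq_id},{resnum},{note!r}): unknown sequence id")
            if resnum > len(alignment.ungapped(seq_id)):
                raise AlignmentError(
                    f"annotation row ({seq_id},{resnum},{note!r}): residue number "
                    f"exceeds ungapped length of '{seq_id}'")

    def merged(self) -> dict[tuple[str, int], str]:
        """Notes per (seq_id, residue), duplicates concatenated with '; '."""
        out: dict[tuple[str, int], str] = {}
        for seq_id, resnum, note in self.rows:
            key = (seq_id, resnum)
            out[key] = f"{out[key]}; {note}" if key in out else note
        return out


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (>= 2 equal-length records)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    if len(records) < 2:
        raise AlignmentError(f"{path}: an alignment needs at least 2 sequences")
    ids = tuple(r.id for r in records)
    seqs = tuple(normalize_sequence(str(r.seq)) for r in records)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        ref_len = len(seqs[0])
        bad = next(i for i, s in zip(ids, seqs) if len(s) != ref_len)
        raise AlignmentError(
            f"{path}: sequences are not aligned ('{bad}' differs in length); "
            "align them first, e.g. with MAFFT or MUSCLE")
    return Alignment(ids=ids, seqs=seqs)


def write_fasta(alignment: Alignment, path: str | Path, width: int = 60) -> None:
    """Write an alignment as FASTA, preserving id order and sequences."""
    with open(path, "w") as fh:
        for i, s in zip(alignment.ids, alignment.seqs):
            fh.write(f">{i}\n")
            for off in range(0, len(s), width):
                fh.write(s[off:off + width] + "\n")


def read_msf_alignment(path: str | Path) -> Alignment:
    """Read a GCG-MSF interleaved alignment.

    A checksum or declared-length mismatch is logged as a warning and
    otherwise ignored; a missing ``..`` header separator is fatal.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()

    sep_idx = None
    declared_len = None
    for idx, line in enumerate(lines):
        if "MSF:" in line:
            toks = line.split()
            if "MSF:" in toks:
                try:
                    declared_len = int(toks[toks.index("MSF:") + 1])
                except (IndexError, ValueError):
                    pass
        if line.rstrip().endswith(".."):
            sep_idx = idx
            break
    if sep_idx is None:
        raise AlignmentError(f"{path}: not an MSF file (missing '..' separator)")

    order: list[str] = []
    checksums: dict[str, int] = {}
    body_start = sep_idx + 1
    for idx in range(body_start, len(lines)):
        line = lines[idx]
        if line.strip().startswith("Name:"):
            toks = line.split()
            name = toks[toks.index("Name:") + 1]
            order.append(name)
            if "Check:" in toks:
                try:
                    checksums[name] = int(toks[toks.index("Check:") + 1])
                except (IndexError, ValueError):
                    pass
        elif line.strip().startswith("//"):
            body_start = idx + 1
            break
    else:
        raise AlignmentError(f"{path}: truncated MSF file (no '//' line)")
    if not order:
        raise AlignmentError(f"{path}: no Name: lines in MSF header")

    chunks: dict[str, list[str]] = {n: [] for n in order}
    for line in lines[body_start:]:
        toks = line.split()
        if len(toks) >= 2 and toks[0] in chunks:
            chunks[toks[0]].append("".join(toks[1:]))
    seqs = {n: normalize_sequence("".join(parts)) for n, parts in chunks.items()}
    missing = [n for n in order if not seqs[n]]
    if missing:
        raise AlignmentError(
            f"{path}: truncated MSF file (no sequence blocks for {missing[0]})")

    for name, seq in seqs.items():
        if declared_len is not None and len(seq) != declared_len:
            log.warning("%s: sequence '%s' length %d differs from declared MSF: %d",
                        path, name, len(seq), declared_len)
        if name in checksums:
            if _gcg_checksum(chunks[name]) != checksums[name]:
                log.warning("%s: checksum mismatch for '%s'", path, name)

    return Alignment(ids=tuple(order), seqs=tuple(seqs[n] for n in order))


def _gcg_checksum(raw_chunks: list[str]) -> int:
    total = 0
    pos = 0
    for chunk in raw_chunks:
        for c in chunk:
            total += ((pos % 57) + 1) * ord(c.upper())
            pos += 1
    return total % 10000


def read_alignment(path: str | Path) -> Alignment:
    """Dispatch on content: MSF if the header carries 'MSF:'/'..', else FASTA."""
    head = Path(path).read_text()[:2048]
    if "MSF:" in head or (head.lstrip().startswith("!!") or "Name:" in head):
        return read_msf_alignment(path)
    return read_fasta_alignment(path)


def load_groups(paths: Sequence[str | Path]) -> GroupedAlignment:
    """Assemble >= 2 per-group alignment files into one grouped alignment.

    All files must share one column count; group indices follow file order.
    """
    if len(paths) < 2:
        raise AlignmentError("need at least two groups")
    parts = [read_alignment(p) for p in paths]
    widths = {a.length for a in parts}
    if len(widths) != 1:
        raise AlignmentError(
            "group files have different column counts; supply one joint "
            "alignment split into groups of identical width")
    ids: list[str] = []
    seqs: list[str] = []
    group_of: dict[str, int] = {}
    for g, part in enumerate(parts):
        for i, s in zip(part.ids, part.seqs):
            if i in group_of:
                raise AlignmentError(f"duplicate id across groups: '{i}'")
            ids.append(i)
            seqs.append(s)
            group_of[i] = g
    return GroupedAlignment(Alignment(tuple(ids), tuple(seqs)), group_of)


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a 3-column CSV/TSV annotation table (seq_id, residue_number, note)."""
    path = Path(path)
    text = path.read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    rows: list[tuple[str, int, str]] = []
    for lineno, rec in enumerate(csv.reader(text.splitlines(), delimiter=delim), 1):
        if not rec or not "".join(rec).strip():
            continue
        if lineno == 1 and rec[0].strip().lower() in ("seq_id", "seqid", "sequence"):
            continue
        if len(rec) < 3:
            raise AlignmentError(f"{path} line {lineno}: expected 3 columns, got {len(rec)}")
        seq_id = rec[0].strip()
        try:
            resnum = int(rec[1])
        except ValueError:
            raise AlignmentError(
                f"{path} line {lineno}: residue number '{rec[1]}' is not an integer")
        if resnum < 1:
            raise AlignmentError(
                f"{path} line {lineno}: residue numbering is 1-based, got {resnum}")
        rows.append((seq_id, resnum, ",".join(rec[2:]).strip()))
    return AnnotationTable(rows=rows)
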