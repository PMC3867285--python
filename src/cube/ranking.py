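"""Rank normalization, color binning, per-residue tabulation, 1D PNG map.

Raw scores from different methods live on incomparable scales, so every
score is turned into a rank over the alignment columns and expressed as
the top fraction it represents (rank / L, ties sharing their mean rank;
the best column has the smallest fraction). Top fractions feed a fixed
10-color decile ramp, red (top decile) through white to blue (bottom),
used identically by the table, the PNG map and the PyMOL script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw, ImageFont
from scipy.stats import rankdata

from .msa_io import Alignment, AnnotationTable

#: Decile color ramp, bin 1 (top-ranked, red) .. bin 10 (bottom, blue).
COLOR_RAMP: tuple[tuple[int, int, int], ...] = (
    (255, 0, 0), (255, 57, 57), (255, 113, 113), (255, 170, 170),
    (255, 227, 227), (227, 227, 255), (170, 170, 255), (113, 113, 255),
    (57, 57, 255), (0, 0, 255),
)


def rank_to_top_fraction(raw: np.ndarray, higher_is_better: bool,
                         flagged: np.ndarray | None = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Ranks (ties -> mean rank) and top fractions rank/L in (0, 1].

    Flagged columns are excluded from ranking and appended as the worst
    tier, all sharing the mean rank of the tail positions.
    """
    raw = np.asarray(raw, dtype=float)
    L = len(raw)
    if L == 0:
        raise ValueError("cannot rank an empty score vector")
    if flagged is None:
        flagged = np.zeros(L, dtype=bool)
    ranks = np.empty(L)
    ok = ~flagged
    oriented = -raw[ok] if higher_is_better else raw[ok]
    ranks[ok] = rankdata(oriented, method="average")
    m = int(ok.sum())
    if m < L:
        ranks[flagged] = (m + 1 + L) / 2.0  # mean of positions m+1..L
    return ranks, ranks / L


def color_bin(top_fraction: float) -> int:
    """Decile bin 1..10 for a top fraction in (0, 1]."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top fraction {top_fraction} outside (0, 1]")
    return min(10, int(np.ceil(top_fraction * 10.0)))


def bin_color(b: int) -> tuple[int, int, int]:
    if not 1 <= b <= 10:
        raise ValueError(f"color bin {b} outside 1..10")
    return COLOR_RAMP[b - 1]


@dataclass
class ScoreTable:
    """Per-column scores with ranks, top fractions and color bins.

    One track per scoring method; the first track added is the primary one
    used for map and structure coloring unless overridden.
    """

    n_columns: int
    tracks: dict[str, pd.DataFrame] = field(default_factory=dict)

    def add(self, name: str, raw: np.ndarray, higher_is_better: bool,
            flagged: np.ndarray | None = None) -> None:
        raw = np.asarray(raw, dtype=float)
        if len(raw) != self.n_columns:
            raise ValueError("score length does not match column count")
        if flagged is None:
            flagged = np.zeros(self.n_columns, dtype=bool)
        ranks, fractions = rank_to_top_fraction(raw, higher_is_better, flagged)
        self.tracks[name] = pd.DataFrame({
            "score": raw,
            "rank": ranks,
            "top_fraction": fractions,
            "color_bin": [color_bin(f) for f in fractions],
            "flagged": np.asarray(flagged, dtype=bool),
        }, index=pd.RangeIndex(1, self.n_columns + 1, name="aln_column"))

    @property
    def primary(self) -> str:
        if not self.tracks:
            raise ValueError("no score tracks added")
        return next(iter(self.tracks))

    def bins(self, name: str | None = None) -> np.ndarray:
        return self.tracks[name or self.primary]["color_bin"].to_numpy()


def build_residue_report(alignment: Alignment, reference_id: str,
                         table: ScoreTable) -> pd.DataFrame:
    """One row per non-gap reference residue, joining all score tracks.

    Columns: residue_number, residue, aln_column, then per method its
    score and top_fraction, then accessibility and notes placeholders
    (filled by the structure and annotation mergers).
    """
    ref = alignment.sequence(reference_id)
    rows = []
    resnum = 0
    for col, c in enumerate(ref, start=1):
        if c == "-":
            continue
        resnum += 1
        rows.append((resnum, c, col))
    df = pd.DataFrame(rows, columns=["residue_number", "residue", "aln_column"])
    for name, track in table.tracks.items():
        sub = track.loc[df["aln_column"]]
        df[f"{name}_score"] = sub["score"].to_numpy()
        df[f"{name}_top_fraction"] = sub["top_fraction"].to_numpy()
    df["accessibility"] = pd.NA
    df["structure_residue"] = pd.NA
    df["notes"] = ""
    return df


def merge_annotations(report: pd.DataFrame, annotations: AnnotationTable,
                      alignment: Alignment, reference_id: str,
                      ) -> tuple[pd.DataFrame, list[tuple[str, int, str]]]:
    """Project annotations through alignment columns onto reference rows.

    Each (seq_id, residue_number) is mapped to its alignment column, then
    to the reference residue occupying that column. Annotations landing on
    a reference gap go to the returned ``unmapped`` list, never dropped.
    """
    annotations.validate_against(alignment)
    report = report.copy()
    unmapped: list[tuple[str, int, str]] = []
    by_resnum = {int(r): idx for idx, r in report["residue_number"].items()}
    for (seq_id, resnum), note in annotations.merged().items():
        col = alignment.residue_to_column(seq_id, resnum)
        ref_resnum = alignment.column_to_residue(reference_id, col)
        if ref_resnum is None:
            unmapped.append((seq_id, resnum, note))
            continue
        idx = by_resnum[ref_resnum]
        old = report.at[idx, "notes"]
        report.at[idx, "notes"] = f"{old}; {note}" if old else note
    return report, unmapped


# ---------------------------------------------------------------------------
# Outputs

RESIDUES_PER_ROW = 60
_CELL_W = 10
_CELL_H = 12
_LETTER_H = 12
_RULER_H = 10
_MARGIN = 46
_BLOCK_PAD = 8


def render_1d_map(alignment: Alignment, reference_id: str, table: ScoreTable,
                  out_path: str | Path, track: str | None = None) -> None:
    """Color-coded 1D map of the reference sequence as a PNG.

    Sixty residues per row; each residue cell is filled with its decile
    ramp color (cell centers decode exactly to the bin color); a ruler
    marks every 10th residue.
    """
    ref = alignment.sequence(reference_id)
    bins = table.bins(track)
    residues = [(c, bins[col]) for col, c in enumerate(ref) if c != "-"]
    n = len(residues)
    n_rows = max(1, (n + RESIDUES_PER_ROW - 1) // RESIDUES_PER_ROW)
    block_h = _RULER_H + _LETTER_H + _CELL_H + _BLOCK_PAD
    width = _MARGIN + RESIDUES_PER_ROW * _CELL_W + 10
    height = n_rows * block_h + _BLOCK_PAD
    img = Image.new("RGB", (width, height), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    font = ImageFont.load_default()
    for row in range(n_rows):
        y0 = _BLOCK_PAD + row * block_h
        start = row * RESIDUES_PER_ROW
        chunk = residues[start:start + RESIDUES_PER_ROW]
        draw.text((4, y0 + _RULER_H), str(start + 1), fill=(0, 0, 0), font=font)
        for k, (letter, b) in enumerate(chunk):
            x0 = _MARGIN + k * _CELL_W
            resnum = start + k + 1
            if resnum % 10 == 0:
                draw.text((x0, y0), str(resnum), fill=(120, 120, 120), font=font)
                draw.line([(x0 + _CELL_W // 2, y0 + _RULER_H - 2),
                           (x0 + _CELL_W // 2, y0 + _RULER_H)], fill=(120, 120, 120))
            draw.text((x0 + 2, y0 + _RULER_H), letter, fill=(0, 0, 0), font=font)
            ytop = y0 + _RULER_H + _LETTER_H
            draw.rectangle([x0, ytop, x0 + _CELL_W - 1, ytop + _CELL_H - 1],
                           fill=bin_color(int(b)))
    img.save(str(out_path), format="PNG")


def cell_center(residue_number: int) -> tuple[int, int]:
    """Pixel coordinates of the center of a residue's color cell."""
    row, k = divmod(residue_number - 1, RESIDUES_PER_ROW)
    block_h = _RULER_H + _LETTER_H + _CELL_H + _BLOCK_PAD
    x = _MARGIN + k * _CELL_W + _CELL_W // 2
    y = _BLOCK_PAD + row * block_h + _RULER_H + _LETTER_H + _CELL_H // 2
    return x, y


def write_report(report: pd.DataFrame, out_prefix: str | Path,
                 kind: str = "cons", formats: tuple[str, ...] = ("csv",),
                 ) -> list[Path]:
    """Write the residue report as <prefix>.<kind>.csv (and .xlsx on request).

    CSV and XLSX contain identical values cell for cell.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = out_prefix.with_name(out_prefix.name + f".{kind}.csv")
    report.to_csv(csv_path, index=False, lineterminator="\n")
    written.append(csv_path)
    if "xlsx" in formats:
        xlsx_path = out_prefix.with_name(out_prefix.name + f".{kind}.xlsx")
        report.to_excel(xlsx_path, index=False)
        written.append(xlsx_path)
    return written


def write_unmapped(unmapped: list[tuple[str, int, str]],
                   out_prefix: str | Path) -> Path | None:
    """Sidecar list of annotations that land on reference gaps."""
    if not unmapped:
        return None
    path = Path(out_prefix).with_name(Path(out_prefix).name + ".unmapped.csv")
    pd.DataFrame(unmapped, columns=["seq_id", "residue_number", "note"]).to_csv(
        path, index=False, lineterminator="\n")
    return path
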