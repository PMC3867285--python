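"""Per-column conservation scoring.

Five heuristics, all functions of the per-column frequency distribution
(possibly informed by residue similarity or by the sequence-similarity
tree):

* ``entropy`` — Shannon entropy of the column (lower = more conserved)
* ``majority`` — largest type fraction (higher = more conserved)
* ``valdar`` — sequence-weighted mean pairwise BLOSUM62 similarity,
  rescaled to [0,1] (higher = more conserved)
* ``rvet`` — real-valued Evolutionary Trace: entropy summed over the
  nested cuts of the similarity tree (lower = more conserved)
* ``ivet`` — integer-valued Evolutionary Trace: shallowest cut level at
  which every group is invariant (lower = more conserved)

Columns whose gap fraction exceeds 0.5 are scored but flagged; ranking
forces flagged columns into the worst tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .msa_io import GAP, MISSING, Alignment
from .profiles import (
    AA_INDEX,
    ColumnProfile,
    ReducedAlphabet,
    SimilarityTree,
    blosum62_matrix,
    build_tree,
    column_profile,
    profile_from_symbols,
    reduce,
    valdar_weights,
)

METHODS = ("entropy", "majority", "valdar", "rvet", "ivet")

#: Per-method orientation: True if a larger raw value means more conserved.
HIGHER_IS_CONSERVED = {
    "entropy": False,
    "majority": True,
    "valdar": True,
    "rvet": False,
    "ivet": False,
}

GAP_FLAG_THRESHOLD = 0.5

# Worst-value surrogate for sentinel (all-gap) columns under entropy:
# the entropy maximum plus a penalty placing it strictly beyond any
# attainable value.
_ENTROPY_WORST = float(np.log(20.0) + 1.0)


@dataclass
class ConservationScore:
    """Raw per-column values of one conservation method."""

    method: str
    values: np.ndarray
    higher_is_conserved: bool
    flagged: np.ndarray = field(default=None)  # gap-heavy or undefined columns

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(len(self.values), dtype=bool)


def _entropy(freq: np.ndarray) -> float:
    nz = freq[freq > 0]
    return float(-(nz * np.log(nz)).sum()) + 0.0  # avoid -0.0


def score_entropy(profile: ColumnProfile,
                  alphabet: ReducedAlphabet | None = None) -> float:
    """Shannon entropy (natural log) of the column distribution."""
    if profile.is_sentinel:
        return _ENTROPY_WORST
    freq = reduce(profile, alphabet) if alphabet is not None else profile.freq
    return _entropy(freq)


def score_majority(profile: ColumnProfile,
                   alphabet: ReducedAlphabet | None = None) -> float:
    """Largest type (or class) fraction at the column."""
    if profile.is_sentinel:
        return 0.0
    freq = reduce(profile, alphabet) if alphabet is not None else profile.freq
    return float(freq.max())


def rescaled_blosum() -> np.ndarray:
    """BLOSUM62 min-max rescaled to [0,1] over the 20x20 score range."""
    b = blosum62_matrix()
    return (b - b.min()) / (b.max() - b.min())


def score_valdar(alignment: Alignment, column_index: int,
                 weights: Mapping[str, float],
                 similarity: np.ndarray | None = None) -> float:
    """Weighted mean pairwise similarity of the column's residues.

    Sum over non-gap, non-X pairs of w_j w_k m(s_j, s_k), normalized by the
    weight mass; m is BLOSUM62 rescaled to [0,1]. Columns with fewer than
    two contributing symbols score 0 (worst).
    """
    if similarity is None:
        similarity = rescaled_blosum()
    symbols = alignment.column(column_index)
    contrib = [(weights[i], c) for i, c in zip(alignment.ids, symbols)
               if c != GAP and c != MISSING]
    if len(contrib) < 2:
        return 0.0
    num = 0.0
    den = 0.0
    for j in range(len(contrib)):
        wj, sj = contrib[j]
        for k in range(j + 1, len(contrib)):
            wk, sk = contrib[k]
            ww = wj * wk
            num += ww * similarity[AA_INDEX[sj], AA_INDEX[sk]]
            den += ww
    return num / den if den > 0 else 0.0


def score_rvet(alignment: Alignment, column_index: int,
               tree: SimilarityTree) -> float:
    """Real-valued ET: 1 + Σ_{n=1}^{N-1} (1/n) Σ_{g in cut(n)} H_g.

    H_g is the Shannon entropy of the column restricted to group g; groups
    with no contributing symbol contribute 0.
    """
    N = tree.n_leaves
    total = 1.0
    for n in range(1, N):
        level = 0.0
        for group in tree.cut(n):
            p = column_profile(alignment, column_index, subset=group)
            if p.n_effective > 0:
                level += _entropy(p.freq)
        total += level / n
    return total


def score_ivet(alignment: Alignment, column_index: int,
               tree: SimilarityTree) -> int:
    """Integer-valued ET: smallest n with every cut(n) group invariant.

    Gaps and missing symbols are ignored; an all-gap group counts as
    invariant. Returns N when no cut level achieves invariance.
    """
    N = tree.n_leaves
    for n in range(1, N + 1):
        if all(_is_invariant(alignment.column(column_index, subset=g))
               for g in tree.cut(n)):
            return n
    return N


def _is_invariant(symbols: str) -> bool:
    types = {c for c in symbols if c != GAP and c != MISSING}
    return len(types) <= 1


def score_alignment(alignment: Alignment, method: str,
                    alphabet: ReducedAlphabet | None = None,
                    tree: SimilarityTree | None = None) -> ConservationScore:
    """Apply one conservation scorer to every column of the alignment."""
    if method not in METHODS:
        raise ValueError(
            f"unknown conservation method '{method}'; valid: {', '.join(METHODS)}")
    if alphabet is not None and method not in ("entropy", "majority"):
        raise ValueError("reduced alphabets apply to entropy and majority only")

    L = alignment.length
    values = np.empty(L)
    flagged = np.zeros(L, dtype=bool)
    profiles = [column_profile(alignment, j) for j in range(1, L + 1)]
    for j, p in enumerate(profiles):
        flagged[j] = p.gap_fraction > GAP_FLAG_THRESHOLD or p.is_sentinel

    if method == "entropy":
        values[:] = [score_entropy(p, alphabet) for p in profiles]
    elif method == "majority":
        values[:] = [score_majority(p, alphabet) for p in profiles]
    elif method == "valdar":
        weights = valdar_weights(alignment)
        sim = rescaled_blosum()
        values[:] = [score_valdar(alignment, j, weights, sim)
                     for j in range(1, L + 1)]
    else:
        if tree is None:
            tree = build_tree(alignment)
        scorer = score_rvet if method == "rvet" else score_ivet
        values[:] = [scorer(alignment, j, tree) for j in range(1, L + 1)]

    return ConservationScore(method=method, values=values,
                             higher_is_conserved=HIGHER_IS_CONSERVED[method],
                             flagged=flagged)
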