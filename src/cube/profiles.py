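"""Column frequency profiles, sequence weights, the BLOSUM substitution
chain, reduced alphabets, and the sequence-similarity tree.

These are the shared primitives behind the conservation and specialization
scorers: every score is a function of per-column amino-acid frequency
distributions, optionally informed by residue similarity (the BLOSUM chain
or a reduced alphabet) and by the similarity tree over the sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .msa_io import GAP, MISSING, STANDARD_AA, Alignment

AA = STANDARD_AA  # canonical 20-letter order used by every frequency vector
AA_INDEX = {a: i for i, a in enumerate(AA)}

# BLOSUM62 background (marginal) amino-acid frequencies, in AA order.
# Published alongside the matrix; the substitution chain is anchored to them.
_BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


@lru_cache(maxsize=1)
def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 integer log-odds scores as a 20x20 array in AA order."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = m[a, b]
    return out


@dataclass(frozen=True)
class ColumnProfile:
    """Amino-acid frequencies at one alignment column.

    ``freq`` holds the 20 fractions over contributing (non-gap, non-X)
    symbols; ``gap_fraction`` counts gaps *and* missing symbols over the
    subset size; ``n_effective`` is the number of contributing sequences.
    An all-gap column is the sentinel: ``n_effective == 0``, zero freq.
    """

    freq: np.ndarray
    gap_fraction: float
    n_effective: int

    @property
    def is_sentinel(self) -> bool:
        return self.n_effective == 0

    def majority(self) -> float:
        return float(self.freq.max()) if self.n_effective else 0.0


def column_profile(alignment: Alignment, column_index: int,
                   subset: Iterable[str] | None = None) -> ColumnProfile:
    """Frequency profile of one column, optionally over a subset of ids."""
    if subset is not None and not set(subset):
        raise ValueError("empty subset")
    symbols = alignment.column(column_index, subset)
    return profile_from_symbols(symbols)


def profile_from_symbols(symbols: str) -> ColumnProfile:
    """Profile from a raw string of column symbols."""
    n_total = len(symbols)
    counts = np.zeros(20)
    for c in symbols:
        if c != GAP and c != MISSING:
            counts[AA_INDEX[c]] += 1
    n_eff = int(counts.sum())
    freq = counts / n_eff if n_eff else counts
    gap_fraction = (n_total - n_eff) / n_total if n_total else 1.0
    return ColumnProfile(freq=freq, gap_fraction=gap_fraction, n_effective=n_eff)


# ---------------------------------------------------------------------------
# Pairwise distances and Valdar sequence weights

def pairwise_distance(alignment: Alignment) -> np.ndarray:
    """d(j,k) = 1 - fractional identity over columns where both are non-gap.

    Pairs with no jointly non-gap column get distance 1.
    """
    n = alignment.n_sequences
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in alignment.seqs]
    gap = GAP.encode()
    d = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            both = (arrs[j] != gap) & (arrs[k] != gap)
            m = int(both.sum())
            ident = float((arrs[j][both] == arrs[k][both]).sum()) / m if m else 0.0
            d[j, k] = d[k, j] = 1.0 - ident
    return d


def valdar_weights(alignment: Alignment) -> dict[str, float]:
    """Per-sequence weights correcting for uneven taxonomic sampling.

    w_j is the mean distance of sequence j to all others, normalized to
    mean 1. Exact duplicates are tolerated via a small epsilon guard.
    """
    if alignment.n_sequences < 2:
        raise ValueError("need at least 2 sequences for weighting")
    d = pairwise_distance(alignment)
    n = alignment.n_sequences
    w = d.sum(axis=1) / (n - 1)
    w = w + 1e-6  # guard: identical duplicated sequences keep nonzero weight
    w = w / w.mean()
    return dict(zip(alignment.ids, w.tolist()))


# ---------------------------------------------------------------------------
# BLOSUM-equilibrium substitution chain

@dataclass(frozen=True)
class SubstitutionModel:
    """Discrete Markov chain on amino-acid types with BLOSUM equilibrium.

    ``M`` is the row-stochastic one-step transition matrix, ``pi`` its
    stationary distribution, and ``blosum`` the integer BLOSUM62 log-odds
    table. Detailed balance pi_a M[a,b] = pi_b M[b,a] holds by construction
    because the underlying joint table is symmetric.
    """

    M: np.ndarray
    pi: np.ndarray
    blosum: np.ndarray


@lru_cache(maxsize=1)
def blosum_chain() -> SubstitutionModel:
    """Build the substitution chain from the BLOSUM62 joint frequencies.

    The joint table is reconstructed from the published background
    frequencies p and the half-bit log-odds s: q(a,b) ∝ p_a p_b 2^(s_ab/2),
    normalized to sum 1. M[a,b] = q(a,b)/Σ_c q(a,c); pi_a = Σ_b q(a,b).
    """
    s = blosum62_matrix()
    p = np.array([_BACKGROUND[a] for a in AA])
    q = np.outer(p, p) * np.power(2.0, s / 2.0)
    q = q / q.sum()
    pi = q.sum(axis=1)
    M = q / pi[:, None]
    return SubstitutionModel(M=M, pi=pi, blosum=s)


def evolve(profile: np.ndarray, model: SubstitutionModel, steps: int) -> np.ndarray:
    """Propagate a 20-vector distribution ``steps`` times through the chain."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    v = np.asarray(profile, dtype=float)
    if v.shape != (20,):
        raise ValueError("profile must be a 20-vector")
    for _ in range(steps):
        v = v @ model.M
    return v


# ---------------------------------------------------------------------------
# Similarity tree (UPGMA) and nested cuts

@dataclass(frozen=True)
class SimilarityTree:
    """UPGMA tree over the sequences, queried through nested cuts.

    ``cut(n)`` returns the partition into exactly n groups obtained by
    undoing the last n-1 merges; cuts are nested by construction.
    """

    ids: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy (N-1) x 4 linkage

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def cut(self, n: int) -> list[tuple[str, ...]]:
        """Partition of the ids into n groups (1 <= n <= N)."""
        N = self.n_leaves
        if not 1 <= n <= N:
            raise ValueError(f"cut level {n} out of range 1..{N}")
        clusters: dict[int, list[int]] = {i: [i] for i in range(N)}
        for step in range(N - n):
            a, b = int(self.linkage_matrix[step, 0]), int(self.linkage_matrix[step, 1])
            clusters[N + step] = clusters.pop(a) + clusters.pop(b)
        groups = []
        for members in clusters.values():
            groups.append(tuple(self.ids[i] for i in sorted(members)))
        groups.sort(key=lambda g: self.ids.index(g[0]))
        return groups

    def to_newick(self) -> str:
        N = self.n_leaves
        if N == 1:
            return f"{self.ids[0]};"
        labels: dict[int, str] = {i: self.ids[i] for i in range(N)}
        heights: dict[int, float] = {i: 0.0 for i in range(N)}
        for step in range(N - 1):
            a, b = int(self.linkage_matrix[step, 0]), int(self.linkage_matrix[step, 1])
            h = float(self.linkage_matrix[step, 2]) / 2.0
            la = f"{labels[a]}:{h - heights[a]:.6g}"
            lb = f"{labels[b]}:{h - heights[b]:.6g}"
            labels[N + step] = f"({la},{lb})"
            heights[N + step] = h
        return labels[2 * N - 2] + ";"


def build_tree(alignment: Alignment) -> SimilarityTree:
    """UPGMA tree over 1 - fractional-identity distances."""
    if alignment.n_sequences < 2:
        raise ValueError("need at least 2 sequences to build a tree")
    d = pairwise_distance(alignment)
    z = linkage(squareform(d, checks=False), method="average")
    return SimilarityTree(ids=alignment.ids, linkage_matrix=z)


# ---------------------------------------------------------------------------
# Reduced alphabets

#: Default 7-class physicochemical grouping: aliphatic/sulfur, aromatic,
#: polar, basic, acidic, glycine, proline.
DEFAULT_REDUCED_ALPHABET: dict[str, str] = {
    "ALIPHATIC": "AVLIMC",
    "AROMATIC": "FWYH",
    "POLAR": "STNQ",
    "BASIC": "KR",
    "ACIDIC": "DE",
    "GLYCINE": "G",
    "PROLINE": "P",
}


@dataclass(frozen=True)
class ReducedAlphabet:
    """A named partition of the 20 amino-acid types into classes."""

    classes: tuple[tuple[str, str], ...]  # (name, members) pairs

    def __post_init__(self) -> None:
        seen = "".join(m for _, m in self.classes)
        if sorted(seen) != sorted(AA):
            raise ValueError(
                "reduced alphabet classes must be disjoint and cover all 20 types")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def membership(self) -> np.ndarray:
        """20 x n_classes 0/1 matrix mapping types to classes."""
        m = np.zeros((20, self.n_classes))
        for k, (_, members) in enumerate(self.classes):
            for a in members:
                m[AA_INDEX[a], k] = 1.0
        return m

    def class_of(self, aa: str) -> int:
        for k, (_, members) in enumerate(self.classes):
            if aa in members:
                return k
        raise KeyError(aa)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "ReducedAlphabet":
        return cls(tuple((name, members.upper()) for name, members in mapping.items()))

    @classmethod
    def from_string(cls, spec: str) -> "ReducedAlphabet":
        """Parse "CLASS1=AVLIMC;CLASS2=FWYH;..." configuration strings."""
        pairs = []
        for part in spec.split(";"):
            part = part.strip()
            if not part:
                continue
            name, _, members = part.partition("=")
            if not members:
                raise ValueError(f"malformed alphabet class '{part}'")
            pairs.append((name.strip(), members.strip().upper()))
        return cls(tuple(pairs))

    @classmethod
    def default(cls) -> "ReducedAlphabet":
        return cls.from_mapping(DEFAULT_REDUCED_ALPHABET)

    @classmethod
    def singletons(cls) -> "ReducedAlphabet":
        return cls(tuple((a, a) for a in AA))


def reduce(profile: ColumnProfile, alphabet: ReducedAlphabet) -> np.ndarray:
    """Class-frequency vector: each class sums its member-type frequencies."""
    return profile.freq @ alphabet.membership()
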