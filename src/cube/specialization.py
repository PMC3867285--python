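"""Specialization scoring across user-defined sequence groups.

A column is *discriminant* when its residue-type distribution in one group
barely overlaps every other group's — the position is unique to that group
(type I divergence when the group is also internally conserved). It is
*determinant* when every group is internally conserved but the groups
disagree with each other — "conserved-but-different" (type II divergence).

Both are built from the pairwise histogram-intersection overlap

    o_gh(i) = Σ_a min(f_a^g(i), f_a^h(i))  ∈ [0, 1],

optionally corrected for biochemical similarity: each pair's overlap is
divided by the overlap *expected* for distributions evolving freely under
the BLOSUM substitution chain for a few steps, so pairs of similar residue
types (large expected overlap after evolution) are not rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .conservation import score_entropy
from .msa_io import GroupedAlignment
from .profiles import (
    ColumnProfile,
    SubstitutionModel,
    blosum_chain,
    column_profile,
    evolve,
)

VARIANTS = ("plain", "similarity")
DEFAULT_EVO_STEPS = 2
_EPS = 1e-6


def overlap(profile_a: ColumnProfile, profile_b: ColumnProfile) -> float:
    """Histogram intersection of two column distributions."""
    if profile_a.is_sentinel or profile_b.is_sentinel:
        raise ValueError("overlap undefined for an all-gap (sentinel) profile")
    return float(np.minimum(profile_a.freq, profile_b.freq).sum())


def expected_overlap(profile_a: ColumnProfile, profile_b: ColumnProfile,
                     model: SubstitutionModel, steps: int) -> float:
    """Overlap after both distributions evolve ``steps`` chain steps.

    As steps grow both profiles converge to the chain's equilibrium, so the
    expected overlap tends to 1 for any pair.
    """
    if profile_a.is_sentinel or profile_b.is_sentinel:
        raise ValueError("overlap undefined for an all-gap (sentinel) profile")
    a = evolve(profile_a.freq, model, steps)
    b = evolve(profile_b.freq, model, steps)
    return float(np.minimum(a, b).sum())


def _overlap_matrix(profiles: Sequence[ColumnProfile], variant: str,
                    model: SubstitutionModel | None, steps: int) -> np.ndarray:
    """Symmetric K x K matrix of (possibly similarity-corrected) overlaps."""
    k = len(profiles)
    o = np.eye(k)
    for g in range(k):
        for h in range(g + 1, k):
            raw = overlap(profiles[g], profiles[h])
            if variant == "similarity":
                exp = expected_overlap(profiles[g], profiles[h], model, steps)
                val = min(1.0, raw / max(exp, _EPS))
            else:
                val = raw
            o[g, h] = o[h, g] = val
    return o


def discriminant_score(profiles: Sequence[ColumnProfile],
                       variant: str = "plain",
                       model: SubstitutionModel | None = None,
                       steps: int = DEFAULT_EVO_STEPS,
                       ) -> tuple[np.ndarray, float]:
    """Per-group and pooled discriminant score at one column.

    d_g = c_g · (1 − max_{h≠g} o_gh) with c_g the majority fraction within
    group g; pooled score is max_g d_g. A group rewarded here is both
    internally conserved and non-overlapping with every other group.
    """
    _check(profiles, variant)
    if model is None and variant == "similarity":
        model = blosum_chain()
    o = _overlap_matrix(profiles, variant, model, steps)
    k = len(profiles)
    d = np.empty(k)
    for g in range(k):
        worst = max(o[g, h] for h in range(k) if h != g)
        d[g] = profiles[g].majority() * (1.0 - worst)
    return d, float(d.max())


def determinant_score(profiles: Sequence[ColumnProfile],
                      variant: str = "plain",
                      model: SubstitutionModel | None = None,
                      steps: int = DEFAULT_EVO_STEPS) -> float:
    """Determinant score: D = (min_g c_g) · (1 − max_{g<h} o_gh).

    Rewards columns conserved within *every* group but as different types
    across groups (conserved-but-different).
    """
    _check(profiles, variant)
    if model is None and variant == "similarity":
        model = blosum_chain()
    o = _overlap_matrix(profiles, variant, model, steps)
    k = len(profiles)
    worst = max(o[g, h] for g in range(k) for h in range(g + 1, k))
    c_min = min(p.majority() for p in profiles)
    return float(c_min * (1.0 - worst))


def _check(profiles: Sequence[ColumnProfile], variant: str) -> None:
    if len(profiles) < 2:
        raise ValueError("specialization needs at least 2 group profiles")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant '{variant}'; valid: {', '.join(VARIANTS)}")
    for p in profiles:
        if p.is_sentinel:
            raise ValueError("sentinel profile; column must be flagged by caller")


@dataclass
class SpecializationScore:
    """Per-column specialization results over a grouped alignment.

    ``overlap_matrices[i]`` is the K x K pairwise overlap matrix at column
    i; ``discriminant_per_group`` is L x K, with pooled max per column in
    ``discriminant``; ``determinant`` is the pooled conserved-but-different
    score; ``entropy`` is Shannon entropy over the pooled alignment,
    always computed as the companion conservation track.
    """

    variant: str
    overlap_matrices: np.ndarray  # L x K x K, NaN where flagged
    discriminant_per_group: np.ndarray  # L x K
    discriminant: np.ndarray  # L
    determinant: np.ndarray  # L
    entropy: np.ndarray  # L, pooled-alignment Shannon entropy
    flagged: np.ndarray  # L bool: any group sentinel or gap-heavy pooled column


def score_specialization(grouped: GroupedAlignment,
                         variant: str = "plain",
                         model: SubstitutionModel | None = None,
                         steps: int = DEFAULT_EVO_STEPS) -> SpecializationScore:
    """Score every column of a grouped alignment.

    Columns where any group has no contributing symbol are flagged and get
    pooled scores 0 (NaN overlap matrix); they are forced to the worst rank
    tier downstream.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant '{variant}'; valid: {', '.join(VARIANTS)}")
    if variant == "similarity" and model is None:
        model = blosum_chain()
    aln = grouped.alignment
    K = grouped.n_groups
    L = aln.length
    members = [grouped.group_ids(g) for g in range(K)]

    omats = np.full((L, K, K), np.nan)
    d_groups = np.zeros((L, K))
    d_pooled = np.zeros(L)
    det = np.zeros(L)
    ent = np.empty(L)
    flagged = np.zeros(L, dtype=bool)

    for j in range(1, L + 1):
        i = j - 1
        pooled = column_profile(aln, j)
        ent[i] = score_entropy(pooled)
        group_profiles = [column_profile(aln, j, subset=m) for m in members]
        if any(p.is_sentinel for p in group_profiles) or \
                pooled.gap_fraction > 0.5:
            flagged[i] = True
            if any(p.is_sentinel for p in group_profiles):
                continue
        o = _overlap_matrix(group_profiles, variant, model, steps)
        omats[i] = o
        dg, dp = discriminant_score(group_profiles, variant, model, steps)
        d_groups[i] = dg
        d_pooled[i] = dp
        det[i] = determinant_score(group_profiles, variant, model, steps)

    return SpecializationScore(
        variant=variant, overlap_matrices=omats,
        discriminant_per_group=d_groups, discriminant=d_pooled,
        determinant=det, entropy=ent, flagged=flagged)
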