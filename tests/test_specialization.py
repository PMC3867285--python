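"""Overlap, discriminant/determinant scores and planted-signal recovery."""

import numpy as np
import pytest

from cube.msa_io import Alignment, GroupedAlignment
from cube.profiles import blosum_chain, profile_from_symbols
from cube.specialization import (
    determinant_score,
    discriminant_score,
    expected_overlap,
    overlap,
    score_specialization,
)
from cube.fixtures import synthesize_groups
import naive


def profiles(*columns):
    return [profile_from_symbols(c) for c in columns]


class TestOverlap:
    def test_identical_profiles(self):
        a, b = profiles("ACAC", "CACA")
        assert overlap(a, b) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a, b = profiles("DDDD", "KKKK")
        assert overlap(a, b) == 0.0

    def test_half_overlap(self):
        a, b = profiles("AC", "AW")
        assert overlap(a, b) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            sa = "".join(rng.choice(list("ACDEFG"), size=6))
            sb = "".join(rng.choice(list("ACDEFG"), size=6))
            a, b = profiles(sa, sb)
            o = overlap(a, b)
            assert 0.0 <= o <= 1.0
            assert o == pytest.approx(overlap(b, a), abs=1e-15)
            assert o == pytest.approx(naive.naive_overlap(sa, sb), abs=1e-12)

    def test_sentinel_rejected(self):
        a, s = profiles("AC", "--")
        with pytest.raises(ValueError, match="sentinel"):
            overlap(a, s)


class TestExpectedOverlap:
    def test_zero_steps_equals_plain(self):
        a, b = profiles("DDDD", "KKKK")
        m = blosum_chain()
        assert expected_overlap(a, b, m, 0) == overlap(a, b)

    def test_long_time_limit_is_one(self):
        a, b = profiles("DDDD", "KKKK")
        m = blosum_chain()
        assert expected_overlap(a, b, m, 512) == pytest.approx(1.0, abs=1e-6)

    def test_deficit_shrinks_with_steps(self, rng):
        m = blosum_chain()
        aa = list("ACDEFGHIKL")
        for _ in range(100):
            a = profile_from_symbols("".join(rng.choice(aa, size=5)))
            b = profile_from_symbols("".join(rng.choice(aa, size=5)))
            deficits = [1.0 - expected_overlap(a, b, m, k)
                        for k in (0, 2, 8, 32, 128)]
            assert all(d2 <= d1 + 1e-12
                       for d1, d2 in zip(deficits, deficits[1:]))


class TestDiscriminant:
    def test_unique_conserved_group(self):
        ps = profiles("RRRR", "AGST")
        d, pooled = discriminant_score(ps)
        assert d[0] == pytest.approx(1.0)
        assert d[1] == pytest.approx(0.25)
        assert pooled == pytest.approx(1.0)

    def test_no_specialization(self):
        ps = profiles("GGGG", "GGGG")
        _, pooled = discriminant_score(ps)
        assert pooled == 0.0

    def test_conserved_but_different_scores_one(self):
        ps = profiles("DDDD", "KKKK")
        _, pooled = discriminant_score(ps)
        assert pooled == pytest.approx(1.0)

    def test_similarity_variant_discounts_partial_overlap(self):
        # the expected (freely evolving) overlap inflates the denominator,
        # so a given raw overlap counts for more once corrected
        m = blosum_chain()
        ps = profiles("DDDD", "DDEE")
        _, plain = discriminant_score(ps, "plain")
        _, corrected = discriminant_score(ps, "similarity", m)
        assert corrected < plain

    def test_similarity_variant_zero_steps_equals_plain_when_unclipped(self):
        m = blosum_chain()
        ps = profiles("RRRR", "AGST")
        _, p0 = discriminant_score(ps, "plain")
        _, s0 = discriminant_score(ps, "similarity", m, steps=0)
        # disjoint supports: raw overlap 0, so the correction changes nothing
        assert s0 == pytest.approx(p0, abs=1e-12)


class TestDeterminant:
    def test_conserved_but_different(self):
        assert determinant_score(profiles("DDDD", "KKKK")) == pytest.approx(1.0)

    def test_partially_conserved_group_caps_score(self):
        ps = profiles("DDDD", "AGST")
        o = overlap(*ps)
        assert determinant_score(ps) == pytest.approx(0.25 * (1 - o))
        _, pooled = discriminant_score(ps)
        assert determinant_score(ps) < pooled

    def test_no_difference_scores_zero(self):
        assert determinant_score(profiles("GGGG", "GGGG")) == 0.0

    def test_determinant_never_exceeds_pooled_discriminant(self, rng):
        aa = list("ACDEFGHIKL")
        for _ in range(100):
            ps = profiles("".join(rng.choice(aa, size=4)),
                          "".join(rng.choice(aa, size=4)),
                          "".join(rng.choice(aa, size=4)))
            _, pooled = discriminant_score(ps)
            assert determinant_score(ps) <= pooled + 1e-12

    def test_matches_naive(self, rng):
        aa = list("ACDEFGHIKL")
        for _ in range(50):
            cols = ["".join(rng.choice(aa, size=5)) for _ in range(2)]
            ps = profiles(*cols)
            d, pooled = discriminant_score(ps)
            nd, npooled = naive.naive_discriminant(cols)
            np.testing.assert_allclose(d, nd, atol=1e-12)
            assert pooled == pytest.approx(npooled, abs=1e-12)
            assert determinant_score(ps) == pytest.approx(
                naive.naive_determinant(cols), abs=1e-12)


class TestScoreSpecialization:
    def test_planted_fixture_recovery(self):
        grouped, planted = synthesize_groups(seed=11)
        res = score_specialization(grouped)
        assert int(res.determinant.argmax()) + 1 == planted["determinant_column"]
        assert int(res.entropy.argmin()) + 1 == planted["invariant_column"]

    def test_within_group_permutation_invariance(self, grouped_toy):
        base = score_specialization(grouped_toy)
        aln = grouped_toy.alignment
        order = ("g1c", "g1a", "g1b", "g2b", "g2c", "g2a")
        shuffled = GroupedAlignment(
            Alignment(order, tuple(aln.sequence(i) for i in order)),
            grouped_toy.group_of)
        res = score_specialization(shuffled)
        np.testing.assert_allclose(res.determinant, base.determinant, atol=1e-15)
        np.testing.assert_allclose(res.discriminant, base.discriminant,
                                   atol=1e-15)

    def test_group_label_swap_symmetry(self, grouped_toy):
        base = score_specialization(grouped_toy)
        swapped_map = {i: 1 - g for i, g in grouped_toy.group_of.items()}
        res = score_specialization(
            GroupedAlignment(grouped_toy.alignment, swapped_map))
        np.testing.assert_allclose(res.determinant, base.determinant, atol=1e-15)
        np.testing.assert_allclose(res.discriminant, base.discriminant,
                                   atol=1e-15)
        np.testing.assert_allclose(res.discriminant_per_group,
                                   base.discriminant_per_group[:, ::-1],
                                   atol=1e-15)

    def test_overlap_matrix_diagonal_and_symmetry(self, grouped_toy):
        res = score_specialization(grouped_toy)
        for i in range(grouped_toy.alignment.length):
            if res.flagged[i]:
                continue
            o = res.overlap_matrices[i]
            np.testing.assert_allclose(o, o.T, atol=1e-15)
            np.testing.assert_allclose(np.diag(o), 1.0)

    def test_group_sentinel_column_flagged(self):
        aln = Alignment(("a", "b", "c", "d"), ("A-", "C-", "GA", "GC"))
        grouped = GroupedAlignment(aln, {"a": 0, "b": 0, "c": 1, "d": 1})
        res = score_specialization(grouped)
        assert res.flagged[1] and not res.flagged[0]
        assert res.determinant[1] == 0.0
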