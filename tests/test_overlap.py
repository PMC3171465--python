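import numpy as np
import pytest

from sdpscan.alphabet import AA_INDEX, N_TYPES, index_of
from sdpscan.errors import InputError
from sdpscan.overlap import (
    corrected_overlap,
    kl_between_groups,
    mutual_information,
    orient_and_rescale,
    overlap_eq9,
    overlap_o,
    pairwise_mi,
    sequence_harmony,
    squared_difference,
)
from sdpscan.rate_model import free_distribution

from conftest import random_distribution


def dist(**freqs):
    p = np.zeros(N_TYPES)
    for aa, v in freqs.items():
        p[AA_INDEX[aa]] = v
    return p


class TestOverlapO:
    def test_identical_gives_one_irrespective_of_variability(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = random_distribution(rng, support=rng.choice(20, rng.integers(1, 20), replace=False))
            assert overlap_o(p, p) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_gives_zero(self):
        assert overlap_o(dist(A=0.5, C=0.5), dist(D=0.5, E=0.5)) == 0.0

    def test_partial_overlap_hand_value(self):
        # p uniform on {A,C}, q uniform on {C,D}: 2·(.5·.5)/((.25+.25)+(.25+.25)) = 0.5
        v = overlap_o(dist(A=0.5, C=0.5), dist(C=0.5, D=0.5))
        assert v == pytest.approx(0.5)
        assert 0 < v < 1

    def test_bounds_extremes_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            ks = rng.integers(1, 21, size=2)
            sup_p = rng.choice(20, ks[0], replace=False)
            sup_q = rng.choice(20, ks[1], replace=False)
            p, q = random_distribution(rng, sup_p), random_distribution(rng, sup_q)
            v = overlap_o(p, q)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(overlap_o(q, p), abs=1e-12)
            if np.abs(p - q).max() < 1e-12:
                assert v == pytest.approx(1.0, abs=1e-9)
            if not set(sup_p) & set(sup_q):
                assert v == 0.0
            else:
                assert v > 0.0

    def test_non_normalized_rejected(self):
        with pytest.raises(InputError):
            overlap_o(np.full(20, 0.1), dist(A=1.0))


class TestOverlapEq9:
    def test_disjoint_extreme_is_zero(self):
        assert overlap_eq9(dist(A=1.0), dist(C=1.0)) == 0.0

    def test_identical_value_depends_on_spread(self):
        sharp = overlap_eq9(dist(A=1.0), dist(A=1.0))
        broad4 = dist(A=0.25, C=0.25, D=0.25, E=0.25)
        assert sharp == pytest.approx(1.0)
        assert overlap_eq9(broad4, broad4) == pytest.approx(0.25)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        p, q = random_distribution(rng), random_distribution(rng)
        brute = sum(p[i] * q[i] for i in range(20))
        assert overlap_eq9(p, q) == pytest.approx(brute, abs=1e-12)


class TestSquaredDifference:
    def test_zero_iff_identical(self):
        p = dist(A=0.3, C=0.7)
        assert squared_difference(p, p) == 0.0

    def test_disjoint_indicators_give_two(self):
        assert squared_difference(dist(A=1.0), dist(C=1.0)) == pytest.approx(2.0)

    def test_hand_value(self):
        v = squared_difference(dist(A=0.5, C=0.5), dist(C=0.5, D=0.5))
        assert v == pytest.approx(0.5)  # 0.25 + 0 + 0.25

    def test_disjoint_value_depends_on_variability(self):
        # unlike the normalized overlap, the SSD's disjoint value shrinks with spread
        sharp = squared_difference(dist(A=1.0), dist(C=1.0))
        broad = squared_difference(
            dist(A=0.5, R=0.5), dist(C=0.5, D=0.5)
        )
        assert sharp == pytest.approx(2.0) and broad == pytest.approx(1.0)


class TestKLBetweenGroups:
    def test_zero_for_identical(self):
        p = dist(A=0.4, C=0.6)
        assert kl_between_groups(p, p) == pytest.approx(0.0, abs=1e-4)

    def test_asymmetric(self):
        p, q = dist(A=0.5, C=0.5), dist(A=0.9, C=0.1)
        assert kl_between_groups(p, q) != pytest.approx(kl_between_groups(q, p))

    def test_hand_value(self):
        p, q = dist(A=0.5, C=0.5), dist(A=0.9, C=0.1)
        want = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert kl_between_groups(p, q) == pytest.approx(want, abs=1e-4)

    def test_floor_keeps_value_finite(self):
        v = kl_between_groups(dist(A=1.0), dist(C=1.0))
        assert np.isfinite(v) and v > 10  # ~ -ln(1e-6)


class TestSequenceHarmony:
    def test_identical_constant_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = random_distribution(rng)
            assert sequence_harmony(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_constant_ln2(self):
        # JS between groups is ln 2 for any disjoint pair, sharp or broad
        sharp = sequence_harmony(dist(A=1.0), dist(C=1.0))
        broad = sequence_harmony(dist(A=0.5, R=0.5), dist(C=0.25, D=0.25, E=0.25, G=0.25))
        assert sharp == pytest.approx(np.log(2))
        assert broad == pytest.approx(np.log(2))

    def test_symmetric_and_matches_brute_force(self):
        rng = np.random.default_rng(3)
        p, q = random_distribution(rng), random_distribution(rng)
        m = (p + q) / 2
        brute = 0.5 * sum(a * np.log(a / b) for a, b in zip(p, m) if a > 0) + 0.5 * sum(
            a * np.log(a / b) for a, b in zip(q, m) if a > 0
        )
        assert sequence_harmony(p, q) == pytest.approx(brute, abs=1e-12)
        assert sequence_harmony(p, q) == pytest.approx(sequence_harmony(q, p))


class TestMutualInformation:
    def test_independence_gives_zero(self):
        counts = dist(A=6, C=4)
        assert mutual_information([counts, counts * 3]) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_assortment_equal_sizes_gives_ln2(self):
        a = dist(A=10)
        c = dist(C=10)
        assert mutual_information([a, c]) == pytest.approx(np.log(2))

    def test_matches_joint_table_oracle(self):
        rng = np.random.default_rng(7)
        counts = [rng.integers(0, 9, size=20) + (i == 0) for i in range(3)]
        got = mutual_information(counts)
        table = np.asarray(counts, dtype=float)
        joint = table / table.sum()
        pg = joint.sum(axis=1)
        pa = joint.sum(axis=0)
        brute = sum(
            joint[g, a] * np.log(joint[g, a] / (pg[g] * pa[a]))
            for g in range(3)
            for a in range(20)
            if joint[g, a] > 0
        )
        assert got == pytest.approx(brute, abs=1e-12)

    def test_pairwise_mi_symmetric(self):
        rng = np.random.default_rng(12)
        p = rng.integers(0, 10, size=20).astype(float)
        q = rng.integers(0, 10, size=20).astype(float) + 1
        assert pairwise_mi(p, q) == pytest.approx(pairwise_mi(q, p), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            mutual_information([np.zeros(20), np.zeros(20)])


class TestCorrectedOverlap:
    def test_zero_when_both_observed_equal_free(self, wag):
        a, b = index_of("A"), index_of("D")
        t = 0.8
        p = free_distribution(wag, a, t).p
        q = free_distribution(wag, b, t).p
        assert corrected_overlap(p, q, wag, a, b, t) == pytest.approx(0.0, abs=1e-12)

    def test_same_ancestral_at_time_zero(self, wag):
        a = index_of("A")
        p = dist(A=1.0)
        assert corrected_overlap(p, p, wag, a, a, 0.0) == pytest.approx(0.0)

    def test_bounded(self, wag):
        rng = np.random.default_rng(21)
        for _ in range(50):
            p, q = random_distribution(rng), random_distribution(rng)
            v = corrected_overlap(p, q, wag, rng.integers(20), rng.integers(20), 1.0)
            assert -1.0 <= v <= 1.0

    def test_exchangeable_conserved_pair_scores_higher(self, wag):
        # I vs L (fast exchange) should look less diverged than I vs W after correction
        t = 1.0
        i, l, w = index_of("I"), index_of("L"), index_of("W")
        v_il = corrected_overlap(dist(I=1.0), dist(L=1.0), wag, i, l, t)
        v_iw = corrected_overlap(dist(I=1.0), dist(W=1.0), wag, i, w, t)
        assert v_il < v_iw  # observed overlap 0 in both; larger expected → lower corrected
        # equivalently: the expected-overlap term is larger for the exchangeable pair
        pe_il = overlap_o(free_distribution(wag, i, t).p, free_distribution(wag, l, t).p)
        pe_iw = overlap_o(free_distribution(wag, i, t).p, free_distribution(wag, w, t).p)
        assert pe_il > pe_iw


class TestOrientation:
    def test_lower_always_means_more_diverged(self):
        # three positions: identical pair, partial, disjoint — for every method id
        p_id = dist(A=0.5, C=0.5)
        pairs = [
            (p_id, p_id.copy()),
            (dist(A=0.5, C=0.5), dist(C=0.5, D=0.5)),
            (dist(A=1.0), dist(W=1.0)),
        ]
        for mid in ("o", "f", "eq9", "klg", "sh"):
            from sdpscan.overlap import raw_overlap
            from sdpscan.msa_io import ColumnProfile

            raw = []
            for p, q in pairs:
                pp = ColumnProfile(0, "A", p, 10)
                qq = ColumnProfile(0, "B", q, 10)
                raw.append(raw_overlap(mid, pp, qq, None, None, 0.0))
            v = orient_and_rescale(mid, np.array(raw))
            assert v[0] > v[1] > v[2], mid
            assert v.min() >= 0 and v.max() <= 1
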