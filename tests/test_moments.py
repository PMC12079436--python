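"""Moment-family correctness against independent brute-force oracles."""

from fractions import Fraction

import numpy as np
import pytest

from bbbpep.moments import (
    MAX_HAHN_ORDER,
    ORDER_PAIRS,
    MomentSet,
    central_moments,
    hahn_basis,
    hahn_full,
    hahn_moments,
    inverse_hahn,
    matrix_moment_features,
    raw_moments,
    sequence_to_matrix,
)
from bbbpep.sequences import Peptide


def brute_raw(M, a, b):
    k = M.shape[0]
    return sum(
        (e + 1) ** a * (f + 1) ** b * M[e, f] for e in range(k) for f in range(k)
    )


def brute_central(M, a, b):
    k = M.shape[0]
    u00 = brute_raw(M, 0, 0)
    if u00 == 0:
        return 0.0
    xb = brute_raw(M, 1, 0) / u00
    yb = brute_raw(M, 0, 1) / u00
    return sum(
        (e + 1 - xb) ** a * (f + 1 - yb) ** b * M[e, f] for e in range(k) for f in range(k)
    )


def exact_basis_matrix(Q):
    """Independent oracle: exact Gram-Schmidt on monomials over {0..Q-1} in
    rational arithmetic, then float normalization. A degree-n orthogonal
    polynomial with positive leading coefficient is positive at the largest
    grid point, which fixes the sign convention."""
    xs = list(range(Q))
    raw_vecs = []
    for n in range(Q):
        vec = [Fraction(x) ** n for x in xs]
        for prev in raw_vecs:
            pnorm2 = sum(a * a for a in prev)
            dot = sum(a * b for a, b in zip(vec, prev))
            coef = dot / pnorm2
            vec = [a - coef * b for a, b in zip(vec, prev)]
        raw_vecs.append(vec)
    B = np.zeros((Q, Q))
    for n, vec in enumerate(raw_vecs):
        fv = np.array([float(a) for a in vec])
        B[n] = fv / np.sqrt(float(sum(a * a for a in vec)))
        if n > 0 and B[n, -1] < 0:
            B[n] = -B[n]
    return B


class TestSequenceToMatrix:
    def test_perfect_square_has_no_padding(self):
        M = sequence_to_matrix(Peptide("p", "ACDEFGHIK"))
        assert M.shape == (3, 3) and (M != 0).all()

    def test_acd_layout(self):
        M = sequence_to_matrix(Peptide("p", "ACD"))
        assert np.array_equal(M, [[1, 2], [3, 0]])

    def test_ceil_rule_pads_with_zeros(self):
        M = sequence_to_matrix(Peptide("p", "ACDEFGHIKL"))
        assert M.shape == (4, 4) and (M == 0).sum() == 6


class TestRawAndCentralMoments:
    def test_zero_matrix_all_zero(self):
        assert not raw_moments(np.zeros((3, 3))).values.any()
        assert not central_moments(np.zeros((3, 3))).values.any()

    def test_hand_summation_example(self):
        ms = raw_moments(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert ms[(0, 0)] == 10 and ms[(1, 0)] == 17 and ms[(0, 1)] == 16 and ms[(1, 1)] == 27

    def test_central_hand_example(self):
        ms = central_moments(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert ms[(1, 1)] == pytest.approx(-0.20)
        assert ms[(0, 0)] == pytest.approx(10.0)

    def test_centering_identity_and_u00(self, rng):
        for _ in range(20):
            M = rng.normal(size=(5, 5)) ** 2
            cm = central_moments(M)
            assert cm[(1, 0)] == pytest.approx(0.0, abs=1e-9)
            assert cm[(0, 1)] == pytest.approx(0.0, abs=1e-9)
            assert cm[(0, 0)] == pytest.approx(raw_moments(M)[(0, 0)])

    def test_brute_force_agreement_random_6x6(self, rng):
        for _ in range(100):
            M = rng.normal(size=(6, 6))
            rm, cm = raw_moments(M), central_moments(M)
            for a, b in ORDER_PAIRS:
                assert rm[(a, b)] == pytest.approx(brute_raw(M, a, b), rel=1e-10)
                assert cm[(a, b)] == pytest.approx(brute_central(M, a, b), rel=1e-9, abs=1e-9)

    def test_momentset_validates_family_and_size(self):
        with pytest.raises(ValueError):
            MomentSet("bogus", np.zeros(10))
        with pytest.raises(ValueError):
            MomentSet("raw", np.zeros(9))


class TestHahnBasis:
    def test_q1_single_value(self):
        assert hahn_basis(1).ravel() == pytest.approx([1.0])

    @pytest.mark.parametrize("Q", list(range(1, 17)))
    def test_gram_matrix_is_identity(self, Q):
        B = hahn_basis(Q)
        assert np.abs(B @ B.T - np.eye(Q)).max() < 1e-8

    def test_order_zero_row_is_constant(self):
        B = hahn_basis(8)
        assert np.allclose(B[0], 1 / np.sqrt(8))

    @pytest.mark.parametrize("Q", [2, 3, 5, 8])
    def test_matches_exact_rational_gram_schmidt_oracle(self, Q):
        B = hahn_basis(Q)
        E = exact_basis_matrix(Q)
        assert np.abs(B - E).max() < 1e-10

    def test_cap_is_enforced(self):
        with pytest.raises(ValueError):
            hahn_basis(MAX_HAHN_ORDER + 1)
        with pytest.raises(ValueError):
            hahn_basis(0)


class TestHahnMoments:
    def test_zero_matrix(self):
        assert not hahn_moments(np.zeros((5, 5))).values.any()

    def test_linearity(self, rng):
        M = rng.normal(size=(6, 6))
        assert np.allclose(hahn_moments(2 * M).values, 2 * hahn_moments(M).values)

    def test_brute_force_double_sum_random_5x5(self, rng):
        for _ in range(20):
            M = rng.normal(size=(5, 5))
            B = hahn_basis(5)
            hm = hahn_moments(M)
            for p, q in ORDER_PAIRS:
                expected = sum(
                    M[i, j] * B[p, j] * B[q, i] for i in range(5) for j in range(5)
                )
                assert hm[(p, q)] == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_small_matrix_higher_orders_are_zero(self):
        hm = hahn_moments(np.ones((2, 2)))
        for p, q in ORDER_PAIRS:
            if p > 1 or q > 1:
                assert hm[(p, q)] == 0.0


class TestInverseHahn:
    @pytest.mark.parametrize("k", [1, 4, 8, 12])
    def test_roundtrip(self, k, rng):
        M = rng.normal(size=(k, k))
        assert np.abs(inverse_hahn(hahn_full(M), k) - M).max() < 1e-6

    def test_zero_coefficients_give_zero_matrix(self):
        assert not inverse_hahn(np.zeros((4, 4)), 4).any()

    def test_incomplete_coefficient_set_rejected(self):
        with pytest.raises(ValueError):
            inverse_hahn(np.zeros((3, 4)), 4)


class TestMatrixMomentFeatures:
    def test_zero_matrix_gives_30_zeros(self):
        feats = matrix_moment_features(np.zeros((4, 4)))
        assert feats.shape == (30,) and not feats.any()

    def test_layout_contract(self, rng):
        M = rng.normal(size=(6, 6))
        feats = matrix_moment_features(M)
        assert feats.shape == (30,)
        assert np.array_equal(feats[:10], raw_moments(M).values)
        assert np.array_equal(feats[10:20], central_moments(M).values)
        assert np.array_equal(feats[20:], hahn_moments(M).values)
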