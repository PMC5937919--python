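"""Interference-correction combinatorics, cascade and fraction computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluxmu as fm
from fluxmu.errors import InvalidCompositionError, UndefinedRatioError

from .oracles import enumerate_shift_terms, solve_correction_linear


def terms_as_dict(dist, shift):
    return {(t.p, t.q, t.r): t.multiplier for t in dist.terms.get(shift, ())}


class TestShiftDistribution:
    def test_reference_derivative_terms(self, rl5p_distribution):
        """16 extra C / 5 Si: the published cascade terms, coefficient by coefficient."""
        d = rl5p_distribution
        assert terms_as_dict(d, 0) == {(0, 0, 0): 1}
        assert terms_as_dict(d, 1) == {(0, 1, 0): 5, (0, 0, 1): 16}
        assert terms_as_dict(d, 2) == {
            (1, 0, 0): 5,
            (0, 2, 0): 10,
            (0, 1, 1): 80,  # 16c x 5b
            (0, 0, 2): 120,
        }
        # pure 13C multipliers are binomial(16, k)
        assert [d.pure_carbon_multiplier(k) for k in range(1, 6)] == [
            16,
            120,
            560,
            1820,
            4368,
        ]
        # a selection of mixed higher-order terms from the M+3/M+4 rows
        assert terms_as_dict(d, 3)[(1, 1, 0)] == 20  # 20ab
        assert terms_as_dict(d, 3)[(0, 0, 3)] == 560
        assert terms_as_dict(d, 4)[(1, 2, 0)] == 30  # 30ab^2
        assert terms_as_dict(d, 4)[(2, 0, 0)] == 10  # 10a^2
        assert terms_as_dict(d, 5)[(0, 5, 0)] == 1  # b^5

    def test_no_interfering_atoms(self):
        comp = fm.DerivativeComposition("bare", 3)
        dist = fm.build_shift_distribution(comp)
        assert set(dist.terms) == {0}
        assert terms_as_dict(dist, 0) == {(0, 0, 0): 1}

    @pytest.mark.parametrize("n_c,n_si", [(3, 1), (2, 2), (5, 0), (0, 3)])
    def test_matches_exhaustive_enumeration(self, n_c, n_si):
        """Multipliers equal counts from brute-force isotope assignment."""
        comp = fm.DerivativeComposition(
            "toy", 2, groups=(fm.DerivativeGroup("g", n_c, n_si),)
        )
        dist = fm.build_shift_distribution(comp)
        expected = enumerate_shift_terms(n_c, n_si)
        assert set(dist.terms) == set(expected)
        for shift, counter in expected.items():
            assert terms_as_dict(dist, shift) == dict(counter)

    def test_shift2_example_three_carbons_one_silicon(self):
        comp = fm.DerivativeComposition("toy", 2, groups=(fm.DerivativeGroup("g", 3, 1),))
        dist = fm.build_shift_distribution(comp)
        assert terms_as_dict(dist, 2) == {(1, 0, 0): 1, (0, 1, 1): 3, (0, 0, 2): 3}

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidCompositionError):
            fm.DerivativeGroup("bad", carbons=-1)
        with pytest.raises(InvalidCompositionError):
            fm.DerivativeComposition("bad", 5, neutral_loss_carbons=4)

    def test_cascade_expressions_shape(self, rl5p_distribution):
        rows = rl5p_distribution.cascade_expressions()
        assert len(rows) == 6
        assert str(rows[0]) == "A_0"
        assert "4368" in str(rows[5])


class TestCascade:
    def test_documented_overcorrection_example(self, rl5p_distribution, abundances):
        """A1 = 40000 - (5b + 16c) * 100000 = -2712 -> clamped to 0, F1 = 0."""
        A = np.array([100000.0, 40000.0, 0.0, 0.0, 0.0, 0.0])
        corr = fm.correct_areas(A, rl5p_distribution, abundances)
        assert corr.signed[1] == pytest.approx(-2712.0)
        assert corr.a_corr[1] == 0.0
        assert corr.flags[1] == 0
        assert corr.a_corr[0] == A[0]  # monoisotopic area never modified

    def test_zero_abundances_identity(self, rl5p_distribution):
        A = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        corr = fm.correct_areas(A, rl5p_distribution, fm.IsotopeAbundances().exact())
        np.testing.assert_allclose(corr.a_corr, A)
        assert np.all(corr.flags == 1)

    def test_zero_input(self, rl5p_distribution, abundances):
        corr = fm.correct_areas(np.zeros(6), rl5p_distribution, abundances)
        np.testing.assert_array_equal(corr.a_corr, 0.0)
        assert np.all(corr.flags == 1)

    def test_length_mismatch(self, rl5p_distribution, abundances):
        with pytest.raises(ValueError, match="expected 6 areas"):
            fm.correct_areas(np.ones(4), rl5p_distribution, abundances)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        backbone=st.integers(1, 6),
        extra_c=st.integers(0, 20),
        si=st.integers(0, 6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_unclamped_cascade_equals_linear_solve(self, backbone, extra_c, si, seed):
        """The sequential cascade is the triangular solve of M x = A."""
        comp = fm.DerivativeComposition(
            "prop", backbone, groups=(fm.DerivativeGroup("g", extra_c, si),)
        )
        dist = fm.build_shift_distribution(comp)
        ab = fm.IsotopeAbundances()
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1e6, backbone + 1)
        corr = fm.correct_areas(A, dist, ab, clamp=False)
        oracle = solve_correction_linear(A, dist.coefficients(ab, backbone + 1))
        np.testing.assert_allclose(corr.a_corr, oracle, rtol=1e-10, atol=1e-10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        backbone=st.integers(1, 6),
        extra_c=st.integers(0, 20),
        si=st.integers(0, 6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_convolve_correct_round_trip(self, backbone, extra_c, si, seed):
        comp = fm.DerivativeComposition(
            "prop", backbone, groups=(fm.DerivativeGroup("g", extra_c, si),)
        )
        dist = fm.build_shift_distribution(comp)
        ab = fm.IsotopeAbundances()
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1e5, backbone + 1)
        measured = fm.forward_convolve(x, dist, ab)
        corr = fm.correct_areas(measured, dist, ab, clamp=False)
        np.testing.assert_allclose(corr.a_corr, x, rtol=1e-8, atol=1e-8 * x.max())

    def test_unlabeled_standard_collapses_to_m0(self, rl5p_distribution, abundances):
        """A pure natural-abundance envelope corrects to all mass in M+0."""
        x = np.zeros(6)
        x[0] = 1e6
        measured = fm.forward_convolve(x, rl5p_distribution, abundances)
        assert measured[1] > 0  # envelope really spreads signal upward
        ifs = fm.compute_ifs(fm.correct_areas(measured, rl5p_distribution, abundances))
        np.testing.assert_allclose(ifs, [1, 0, 0, 0, 0, 0], atol=1e-12)


class TestFractionsAndShare:
    def test_single_nonzero(self, rl5p_distribution):
        corr = fm.correct_areas(
            np.array([5.0, 0, 0, 0, 0, 0]), rl5p_distribution, fm.IsotopeAbundances().exact()
        )
        np.testing.assert_allclose(fm.compute_ifs(corr), [1, 0, 0, 0, 0, 0])

    def test_normalization(self, rl5p_distribution):
        corr = fm.correct_areas(
            np.array([60.0, 40, 0, 0, 0, 0]), rl5p_distribution, fm.IsotopeAbundances().exact()
        )
        ifs = fm.compute_ifs(corr)
        np.testing.assert_allclose(ifs[:2], [0.6, 0.4])
        assert ifs.sum() == pytest.approx(1.0)

    def test_all_zero_denominator(self, rl5p_distribution, abundances):
        corr = fm.correct_areas(np.zeros(6), rl5p_distribution, abundances)
        with pytest.raises(UndefinedRatioError):
            fm.compute_ifs(corr)

    def test_interference_share_arithmetic(self, rl5p_distribution, abundances):
        A = np.array([100.0, 60, 30, 8, 1.5, 0.5])
        corr = fm.correct_areas(A, rl5p_distribution, abundances)
        expected = 100 * (A.sum() - corr.retained.sum()) / A.sum()
        assert fm.interference_share(A, corr) == pytest.approx(expected)
        # corrected equal to measured -> share 0
        ident = fm.correct_areas(A, rl5p_distribution, fm.IsotopeAbundances().exact())
        assert fm.interference_share(A, ident) == pytest.approx(0.0)

    def test_share_undefined_for_zero_signal(self, rl5p_distribution, abundances):
        corr = fm.correct_areas(np.zeros(6), rl5p_distribution, abundances)
        with pytest.raises(UndefinedRatioError):
            fm.interference_share(np.zeros(6), corr)


class TestCorrectorEstimator:
    def test_sklearn_protocol(self, rl5p_composition):
        from sklearn.base import clone

        est = fm.NaturalAbundanceCorrector(rl5p_composition, clamp=False)
        cloned = clone(est)
        assert cloned.get_params()["clamp"] is False
        est.set_params(clamp=True).fit()
        assert est.coefficients_[0] == 1.0

    def test_transform_batches(self, rl5p_composition, abundances):
        est = fm.NaturalAbundanceCorrector(rl5p_composition).fit()
        X = np.array(
            [[1e5, 9e4, 3e4, 5e3, 4e2, 10.0], [2e5, 1.2e5, 2e4, 1e3, 1e2, 5.0]]
        )
        out = est.transform(X)
        assert out.shape == X.shape
        row0 = fm.correct_areas(
            X[0], fm.build_shift_distribution(rl5p_composition), abundances
        )
        np.testing.assert_allclose(out[0], row0.a_corr)
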