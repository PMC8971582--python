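"""Unit and property tests for the BEC kernel, Gaussian baseline and Gram repairs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from becseg.kernel import (
    GaussianParams,
    GramMatrix,
    KernelParams,
    as_feature_table,
    bec_kernel_value,
    gaussian_kernel_value,
    gram,
    pairwise_kernel,
    psd_project,
    symmetrize,
)


class TestBecKernelValue:
    @pytest.mark.parametrize(
        "delta,T,mu,expected",
        [
            # closed form 1/(exp(a/(1.38 T)) - 1)
            (1.38, 1.0, 0.0, 1.0 / (math.e - 1.0)),
            (1.38, -1.0, 0.0, 1.0 / (math.exp(-1.0) - 1.0)),
            (2.76, 1.0, 0.0, 1.0 / (math.exp(2.0) - 1.0)),
            (0.0, 5.0, 3.0, 1.0 / (math.exp(3.0 / (1.38 * 5.0)) - 1.0)),
        ],
    )
    def test_closed_form(self, delta, T, mu, expected):
        value = bec_kernel_value(delta, KernelParams(T=T, mu=mu))
        assert value == pytest.approx(expected, rel=1e-12)

    def test_singularity_is_capped(self):
        # delta = mu makes the argument 0, exp(0) - 1 = 0: capped, not inf
        params = KernelParams(T=3.0, mu=2.0, kernel_cap=1e6)
        assert bec_kernel_value(2.0, params) == 1e6

    def test_large_argument_decays_to_zero_from_above(self):
        params = KernelParams(T=1.0)
        v = bec_kernel_value(1e4, params)
        assert 0.0 <= v < 1e-100

    def test_zero_temperature_rejected(self):
        with pytest.raises(ValueError, match="T"):
            KernelParams(T=0.0)

    def test_non_finite_delta_rejected(self):
        with pytest.raises(ValueError):
            bec_kernel_value(np.nan, KernelParams(T=1.0))

    def test_symmetric_distance_mode_uses_shifted_norm(self):
        params = KernelParams(T=1.0, mu=2.0, mode="symmetric_distance")
        # a = | ||delta|| - mu | = |3 - 2| = 1
        expected = 1.0 / (math.expm1(1.0 / 1.38))
        assert bec_kernel_value([0.0, 3.0], params) == pytest.approx(expected)

    def test_negative_temperature_values_at_most_minus_one(self):
        params = KernelParams(T=-4.0)
        a = np.linspace(0.01, 50, 500)
        values = [bec_kernel_value(x, params) for x in a]
        assert all(v <= -1.0 for v in values)

    def test_monotone_decrease_for_positive_temperature(self):
        params = KernelParams(T=6.0)
        a = np.linspace(1e-3, 20, 1000)
        values = np.array([bec_kernel_value(x, params) for x in a])
        assert np.all(np.diff(values) < 0)
        assert np.all(values > 0)


class TestGaussianKernelValue:
    def test_identity_at_zero(self):
        assert gaussian_kernel_value(0.0, GaussianParams()) == 1.0

    def test_one_sigma_displacement(self):
        v = gaussian_kernel_value(0.125, GaussianParams(sigma=0.125))
        assert v == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_decays_to_zero(self):
        assert 0 < gaussian_kernel_value(10.0, GaussianParams()) < 1e-100 or \
            gaussian_kernel_value(10.0, GaussianParams()) == 0.0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            GaussianParams(sigma=0.0)


class TestGram:
    def test_two_point_scalar_gram(self):
        params = KernelParams(T=1.0, mu=0.0)
        K = gram([0.0, 1.38], [0.0, 1.38], params).values
        off = 1.0 / (math.e - 1.0)
        assert K[0, 0] == K[1, 1] == params.kernel_cap
        assert K[0, 1] == pytest.approx(off, rel=1e-12)
        assert K[1, 0] == pytest.approx(off, rel=1e-12)

    def test_literal_mode_is_asymmetric_when_mu_nonzero(self):
        params = KernelParams(T=1.0, mu=2.0)
        KXY = gram([0.0], [1.0], params).values
        KYX = gram([1.0], [0.0], params).values
        # arguments are |0-1-2| = 3 and |1-0-2| = 1
        assert KXY[0, 0] == pytest.approx(bec_kernel_value(3.0, KernelParams(T=1.0)))
        assert KYX[0, 0] == pytest.approx(bec_kernel_value(1.0, KernelParams(T=1.0)))
        assert KXY[0, 0] != KYX[0, 0]

    def test_literal_mode_symmetric_iff_mu_zero(self, rng):
        X = rng.normal(size=(12, 3))
        K0 = gram(X, X, KernelParams(T=2.0, mu=0.0)).values
        assert np.array_equal(K0, K0.T)
        K1 = gram(X, X, KernelParams(T=2.0, mu=1.5)).values
        assert not np.array_equal(K1, K1.T)

    def test_symmetric_distance_mode_always_symmetric(self, rng):
        X = rng.normal(size=(15, 4))
        for mu in (0.0, 1.7, -2.3):
            K = gram(X, X, KernelParams(T=3.0, mu=mu, mode="symmetric_distance")).values
            assert np.array_equal(K, K.T)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            gram(np.zeros((3, 2)), np.zeros((3, 4)), KernelParams(T=1.0))

    @pytest.mark.parametrize("mode", ["literal", "symmetric_distance"])
    @pytest.mark.parametrize("T,mu", [(-3.0, 0.0), (1.0, 3.0), (6.0, 3.0)])
    def test_vectorized_gram_matches_scalar_loop(self, rng, mode, T, mu):
        params = KernelParams(T=T, mu=mu, mode=mode)
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(8, 3))
        K = pairwise_kernel(X, Y, params)
        expected = np.array(
            [[bec_kernel_value(x - y, params) for y in Y] for x in X]
        )
        np.testing.assert_allclose(K, expected, atol=1e-10)

    def test_pairwise_symmetrized_matches_matrix_symmetrization(self, rng):
        params = KernelParams(T=2.0, mu=1.0)
        X = rng.normal(size=(9, 2))
        Ksym = pairwise_kernel(X, X, params, symmetric_pair=True)
        expected = symmetrize(gram(X, X, params)).values
        np.testing.assert_array_equal(Ksym, expected)

    def test_scale_invariance_of_kb_temperature_product(self, rng):
        X = rng.normal(size=(8, 2))
        a = pairwise_kernel(X, X, KernelParams(T=3.0, kb_scale=1.38))
        b = pairwise_kernel(X, X, KernelParams(T=6.0, kb_scale=0.69))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestSymmetrize:
    def test_fixed_point_on_symmetric_input(self, rng):
        A = rng.normal(size=(6, 6))
        S = GramMatrix(values=A + A.T, params=KernelParams(T=1.0))
        np.testing.assert_array_equal(symmetrize(S).values, S.values)

    def test_two_by_two_average(self):
        K = GramMatrix(values=np.array([[0.0, 2.0], [0.0, 0.0]]),
                       params=KernelParams(T=1.0))
        np.testing.assert_array_equal(symmetrize(K).values,
                                      np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_output_exactly_equals_transpose(self, rng):
        K = GramMatrix(values=rng.normal(size=(5, 5)), params=KernelParams(T=1.0))
        out = symmetrize(K).values
        assert np.array_equal(out, out.T)

    def test_idempotent(self, rng):
        K = GramMatrix(values=rng.normal(size=(5, 5)), params=KernelParams(T=1.0))
        once = symmetrize(K)
        twice = symmetrize(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.symmetrized and twice.symmetrized

    def test_non_square_rejected(self):
        K = GramMatrix(values=np.zeros((2, 3)), params=KernelParams(T=1.0))
        with pytest.raises(ValueError, match="square"):
            symmetrize(K)


class TestPsdProject:
    def _sym(self, values):
        return GramMatrix(values=np.asarray(values, dtype=float),
                          params=KernelParams(T=1.0), symmetrized=True)

    def test_psd_input_unchanged(self, rng):
        A = rng.normal(size=(8, 8))
        K = self._sym(A @ A.T)
        out = psd_project(K)
        assert np.max(np.abs(out.values - K.values)) < 1e-10

    def test_indefinite_diagonal_clipped(self):
        out = psd_project(self._sym(np.diag([1.0, -1.0])), tol=0.0)
        np.testing.assert_allclose(out.values, np.diag([1.0, 0.0]), atol=1e-12)

    def test_minimum_eigenvalue_nonnegative(self, rng):
        A = rng.normal(size=(10, 10))
        out = psd_project(self._sym(A + A.T))
        assert np.linalg.eigvalsh(out.values).min() >= -1e-10
        assert out.psd_corrected

    def test_requires_symmetrized_state(self):
        K = GramMatrix(values=np.eye(3), params=KernelParams(T=1.0))
        with pytest.raises(ValueError, match="symmetrize"):
            psd_project(K)


class TestFeatureTable:
    def test_scalar_rows_promoted_to_column(self):
        X = as_feature_table([1.0, 2.0, 3.0])
        assert X.shape == (3, 1)

    @pytest.mark.parametrize("bad", [[], [[1.0, np.inf]], np.zeros((2, 2, 2))])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            as_feature_table(bad)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    a=st.floats(min_value=1e-3, max_value=50.0),
    T=st.floats(min_value=0.1, max_value=10.0),
    scale=st.floats(min_value=0.25, max_value=4.0),
)
def test_only_product_of_kb_and_temperature_matters(a, T, scale):
    """Rescaling T by c and kb_scale by 1/c leaves the kernel invariant."""
    v1 = bec_kernel_value(a, KernelParams(T=T, kb_scale=1.38))
    v2 = bec_kernel_value(a, KernelParams(T=T * scale, kb_scale=1.38 / scale))
    assert v2 == pytest.approx(v1, rel=1e-9, abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_symmetrized_gram_is_exactly_symmetric(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(7, 2))
    K = symmetrize(gram(X, X, KernelParams(T=1.5, mu=0.8)))
    assert np.array_equal(K.values, K.values.T)
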