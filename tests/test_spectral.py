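"""Scaled Laplacian, Chebyshev basis, attention-masked graph convolution
and temporal convolution, each against hand-derived or brute-force oracles."""

import numpy as np
import pytest

from stgdan import (
    TemporalConvParams,
    cheb_basis,
    collapse_time,
    scaled_laplacian,
    spatial_graph_conv,
    temporal_conv,
)


def sgc_oracle(X_hat, P, basis, theta):
    """Triple-loop evaluation of sum_k (xi_k ⊙ P) X_hat[t] theta_k."""
    T, N, F = X_hat.shape
    K, _, F_out = theta.shape
    out = np.zeros((T, N, F_out))
    for t in range(T):
        for k in range(K):
            M = basis[k] * P
            for m in range(N):
                acc = np.zeros(F_out)
                for n in range(N):
                    acc += M[m, n] * (X_hat[t, n] @ theta[k])
                out[t, m] += acc
    return out


def tconv_oracle(X, Phi, bias):
    """Direct sliding-window summation of ReLU(Phi * ReLU(X))."""
    T, N, F = X.shape
    k_t = Phi.shape[0]
    half = k_t // 2
    Y = np.maximum(X, 0.0)
    padded = np.zeros((T + 2 * half, N, F))
    padded[half:half + T] = Y
    out = np.zeros((T, N, F))
    for t in range(T):
        for j in range(k_t):
            out[t] += padded[t + j] @ Phi[j]
    return np.maximum(out + bias, 0.0)


class TestScaledLaplacian:
    def test_two_node_graph_by_hand(self):
        """A=[[0,1],[1,0]]: L has spectrum {0,2}, so L~ = L - I."""
        sl = scaled_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert sl.lambda_max == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(sl.L_tilde, [[0.0, -1.0], [-1.0, 0.0]], atol=1e-12)

    def test_uniform_triangle_by_hand(self):
        """K3 with off-diagonal 1/2: spectrum of L is {0, 1.5, 1.5}."""
        A = np.full((3, 3), 0.5) - 0.5 * np.eye(3)
        sl = scaled_laplacian(A)
        assert sl.lambda_max == pytest.approx(1.5, abs=1e-12)
        L = np.diag(A.sum(1)) - A
        np.testing.assert_allclose(sl.L_tilde, (4.0 / 3.0) * L - np.eye(3), atol=1e-12)

    def test_edgeless_graph_fallback(self):
        with pytest.warns(UserWarning, match="edgeless"):
            sl = scaled_laplacian(np.zeros((3, 3)))
        assert sl.lambda_max == 2.0
        np.testing.assert_allclose(sl.L_tilde, -np.eye(3), atol=1e-12)

    def test_spectrum_in_unit_interval(self, rng):
        for _ in range(20):
            M = np.abs(rng.normal(size=(6, 6)))
            A = 0.5 * (M + M.T)
            np.fill_diagonal(A, 0.0)
            sl = scaled_laplacian(A)
            eig = np.linalg.eigvalsh(sl.L_tilde)
            assert eig.min() >= -1.0 - 1e-6 and eig.max() <= 1.0 + 1e-6
            np.testing.assert_allclose(sl.L_tilde, sl.L_tilde.T, atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            scaled_laplacian(np.array([[0.0, 1.0], [0.2, 0.0]]))


class TestChebBasis:
    def test_first_two_terms(self, rng):
        Lt = rng.normal(size=(4, 4))
        Lt = 0.5 * (Lt + Lt.T) / 4
        basis = cheb_basis(Lt, K=2)
        np.testing.assert_array_equal(basis[0], np.eye(4))
        np.testing.assert_allclose(basis[1], Lt)
        assert len(cheb_basis(Lt, K=1)) == 1

    def test_recursion_third_term_closed_form(self):
        """For L~=[[0,-1],[-1,0]], L~^2 = I so xi_2 = 2L~^2 - I = I."""
        Lt = np.array([[0.0, -1.0], [-1.0, 0.0]])
        basis = cheb_basis(Lt, K=3)
        np.testing.assert_allclose(basis[2], np.eye(2), atol=1e-12)

    def test_matches_polynomial_recursion(self, rng):
        Lt = rng.normal(size=(5, 5))
        Lt = 0.5 * (Lt + Lt.T) / 5
        basis = cheb_basis(Lt, K=5)
        for k in range(2, 5):
            np.testing.assert_allclose(
                basis[k], 2 * Lt @ basis[k - 1] - basis[k - 2], atol=1e-10)


class TestSpatialGraphConv:
    def test_identity_everything_is_identity(self, rng):
        """K=1, theta_0=I, P=I: xi_0 ⊙ I = I so the window passes through."""
        X = rng.normal(size=(3, 4, 5))
        out = spatial_graph_conv(X, np.eye(4), [np.eye(4)], np.eye(5)[None])
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_uniform_mask_scales_by_inverse_N(self, rng):
        """P uniform: xi_0 ⊙ P = (1/N) I, a pure diagonal rescaling."""
        N = 4
        X = rng.normal(size=(3, N, 5))
        out = spatial_graph_conv(X, np.full((N, N), 1 / N), [np.eye(N)], np.eye(5)[None])
        np.testing.assert_allclose(out, X / N, atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(10):
            T, N, F, F_out, K = 3, 3, 4, 2, 2
            X = rng.normal(size=(T, N, F))
            P = rng.uniform(0, 1, (N, N))
            A = np.abs(rng.normal(size=(N, N)))
            A = 0.5 * (A + A.T)
            np.fill_diagonal(A, 0.0)
            basis = cheb_basis(scaled_laplacian(A).L_tilde, K)
            theta = rng.normal(size=(K, F, F_out))
            np.testing.assert_allclose(
                spatial_graph_conv(X, P, basis, theta),
                sgc_oracle(X, P, basis, theta), atol=1e-10)

    def test_shape_errors(self, rng):
        X = rng.normal(size=(3, 4, 5))
        with pytest.raises(ValueError, match="P_norm"):
            spatial_graph_conv(X, np.eye(3), [np.eye(4)], np.eye(5)[None])
        with pytest.raises(ValueError, match="theta"):
            spatial_graph_conv(X, np.eye(4), [np.eye(4)], np.eye(4)[None])


class TestSpectralEquivalence:
    def test_chebyshev_equals_eigendecomposition_filtering(self, rng):
        """With the attention mask all-ones, sum_k theta_k xi_k(L~) x equals
        U (sum_k theta_k xi_k(Lambda)) U^T x from an eigendecomposition."""
        for trial in range(10):
            N, K = rng.integers(2, 9), int(rng.integers(1, 6))
            M = np.abs(rng.normal(size=(N, N)))
            A = 0.5 * (M + M.T)
            np.fill_diagonal(A, 0.0)
            Lt = scaled_laplacian(A).L_tilde
            basis = cheb_basis(Lt, K)
            theta = rng.normal(size=K)
            x = rng.normal(size=(N, 1))

            lhs = sum(theta[k] * basis[k] @ x for k in range(K))

            lam, U = np.linalg.eigh(Lt)
            polys = [np.ones_like(lam), lam]
            for _ in range(2, K):
                polys.append(2 * lam * polys[-1] - polys[-2])
            filt = sum(theta[k] * polys[k] for k in range(K))
            rhs = U @ np.diag(filt) @ U.T @ x
            np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_locality_disconnected_blocks(self, rng):
        """K=2 on a two-component graph: perturbing block-1 channels leaves
        block-2 outputs unchanged."""
        N, F, F_out = 6, 3, 2
        A = np.zeros((N, N))
        A[:3, :3] = 0.5
        A[3:, 3:] = 0.5
        np.fill_diagonal(A, 0.0)
        basis = cheb_basis(scaled_laplacian(A).L_tilde, K=2)
        theta = rng.normal(size=(2, F, F_out))
        P = np.ones((N, N))
        X = rng.normal(size=(4, N, F))
        X2 = X.copy()
        X2[:, :3] += rng.normal(size=(4, 3, F))
        out1 = spatial_graph_conv(X, P, basis, theta)
        out2 = spatial_graph_conv(X2, P, basis, theta)
        np.testing.assert_allclose(out1[:, 3:], out2[:, 3:], atol=1e-10)
        assert not np.allclose(out1[:, :3], out2[:, :3])


class TestTemporalConv:
    def test_zero_kernel_gives_zero(self, rng):
        X = rng.normal(size=(5, 3, 4))
        out = temporal_conv(X, TemporalConvParams(Phi=np.zeros((3, 4, 4))))
        np.testing.assert_array_equal(out, np.zeros_like(X))

    def test_centered_identity_kernel_is_relu(self, rng):
        X = rng.normal(size=(5, 3, 4))
        Phi = np.zeros((3, 4, 4))
        Phi[1] = np.eye(4)
        out = temporal_conv(X, TemporalConvParams(Phi=Phi))
        np.testing.assert_allclose(out, np.maximum(X, 0.0), atol=1e-12)

    def test_matches_sliding_window_oracle(self, rng):
        for _ in range(10):
            X = rng.normal(size=(6, 3, 4))
            Phi = rng.normal(size=(3, 4, 4))
            bias = rng.normal(size=4)
            params = TemporalConvParams(Phi=Phi, bias=bias)
            np.testing.assert_allclose(temporal_conv(X, params),
                                       tconv_oracle(X, Phi, bias), atol=1e-10)

    def test_output_nonnegative(self, rng):
        X = rng.normal(size=(7, 2, 3)) * 10
        params = TemporalConvParams(Phi=rng.normal(size=(5, 3, 3)))
        assert np.all(temporal_conv(X, params) >= 0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            TemporalConvParams(Phi=np.zeros((2, 3, 3)))


class TestCollapseTime:
    def test_single_step_is_flatten(self, rng):
        X = rng.normal(size=(1, 3, 2))
        np.testing.assert_allclose(collapse_time(X), X[0].ravel(), atol=1e-12)

    def test_constant_in_time_equals_any_slice(self, rng):
        X = np.repeat(rng.normal(size=(1, 3, 2)), 4, axis=0)
        np.testing.assert_allclose(collapse_time(X), X[2].ravel(), atol=1e-12)

    def test_reference_width_62_channels_5_features(self, rng):
        assert collapse_time(rng.normal(size=(7, 62, 5))).shape == (310,)
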