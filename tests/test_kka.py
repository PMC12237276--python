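"""Kernel construction, Nystrom extrapolation, the spectrum QP, and the union kernel."""

import numpy as np
import pytest

from farka import (
    EigenSystem,
    KernelSpec,
    build_union_kernel,
    kernel_matrix,
    kka_adapt,
    nystrom_extrapolate,
    solve_spectrum_qp,
    target_eigensystem,
)


def _objective(phi_s, K_s, sigma):
    return np.linalg.norm((phi_s * sigma[None, :]) @ phi_s.T - K_s, "fro") ** 2


def _grid_argmin(phi_s, K_s, mu, r, s_max, n_grid):
    """Brute-force minimizer over the power-law cone — independent oracle."""
    axes = [np.linspace(0, s_max, n_grid)] * r
    grids = np.meshgrid(*axes, indexing="ij")
    sig = np.stack([g.ravel() for g in grids], axis=1)
    ok = np.ones(len(sig), dtype=bool)
    for i in range(r - 1):
        ok &= sig[:, i] >= mu * sig[:, i + 1]
    sig = sig[ok]
    A = phi_s
    G = (A.T @ A) ** 2
    h = np.einsum("ni,nm,mi->i", A, K_s, A)
    vals = np.einsum("ki,ij,kj->k", sig, G, sig) - 2 * sig @ h
    const = np.linalg.norm(K_s, "fro") ** 2
    return sig[np.argmin(vals)], float(vals.min() + const)


class TestKernelMatrix:
    def test_rbf_diagonal_is_one(self, rng):
        X = rng.standard_normal((5, 3))
        K = kernel_matrix(X, X, KernelSpec("rbf", 1.0))
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)

    def test_linear_on_orthonormal_vectors(self):
        X = np.eye(3)
        K = kernel_matrix(X, X, KernelSpec("linear"))
        assert np.allclose(K, np.eye(3))

    def test_rbf_known_value(self):
        K = kernel_matrix([[0.0, 0.0]], [[1.0, 1.0]], KernelSpec("rbf", 1.0))
        assert K[0, 0] == pytest.approx(np.exp(-2.0))

    def test_laplacian_uses_l1_distance(self):
        K = kernel_matrix([[0.0, 0.0]], [[1.0, 1.0]], KernelSpec("laplacian", 1.0))
        assert K[0, 0] == pytest.approx(np.exp(-2.0))  # |1|+|1| = 2

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            kernel_matrix(rng.standard_normal((2, 3)), rng.standard_normal((2, 4)),
                          KernelSpec("linear"))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            KernelSpec("polynomial")
        with pytest.raises(ValueError):
            KernelSpec("rbf", -1.0)


class TestTargetEigensystem:
    def test_identity_kernel(self):
        es = target_eigensystem(np.eye(4), r_max=4)
        assert es.r == 4
        assert np.allclose(es.delta_t, 1.0)
        assert np.allclose(es.phi_t.T @ es.phi_t, np.eye(4), atol=1e-8)

    def test_rank_one_kernel_keeps_single_pair(self, rng):
        v = rng.standard_normal(5)
        es = target_eigensystem(np.outer(v, v), r_max=5)
        assert es.r == 1
        assert es.delta_t[0] == pytest.approx(np.dot(v, v))

    def test_full_rank_reconstruction(self, rng):
        A = rng.standard_normal((6, 6))
        K = A @ A.T
        es = target_eigensystem(K, r_max=6, floor_ratio=0.0)
        assert np.allclose((es.phi_t * es.delta_t) @ es.phi_t.T, K, atol=1e-8)

    def test_descending_positive_spectrum(self, rng):
        A = rng.standard_normal((8, 4))
        es = target_eigensystem(A @ A.T, r_max=8)
        assert np.all(np.diff(es.delta_t) <= 0)
        assert np.all(es.delta_t > 0)

    def test_degenerate_kernel_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            target_eigensystem(np.zeros((3, 3)))


class TestNystromExtrapolate:
    def test_source_equals_target_recovers_eigenvectors(self, rng):
        A = rng.standard_normal((5, 5))
        K = A @ A.T
        es = target_eigensystem(K, floor_ratio=0.0)
        es = nystrom_extrapolate(K, es)
        assert np.allclose(es.phi_s_tilde, es.phi_t, atol=1e-8)

    def test_empty_source(self, rng):
        K = np.eye(3)
        es = nystrom_extrapolate(np.empty((0, 3)), target_eigensystem(K))
        assert es.phi_s_tilde.shape == (0, 3)

    def test_extrapolation_is_not_renormalized(self, rng):
        X_t = rng.standard_normal((6, 3))
        X_s = rng.standard_normal((4, 3))
        spec = KernelSpec("rbf", 0.5)
        es = target_eigensystem(kernel_matrix(X_t, X_t, spec))
        es = nystrom_extrapolate(kernel_matrix(X_s, X_t, spec), es)
        gram = es.phi_s_tilde.T @ es.phi_s_tilde
        assert not np.allclose(gram, np.eye(es.r), atol=1e-3)


class TestSpectrumQP:
    def test_identity_case_recovers_target_spectrum(self, rng):
        A = rng.standard_normal((6, 6))
        K = A @ A.T
        es = nystrom_extrapolate(K, target_eigensystem(K, floor_ratio=0.0))
        sigma = solve_spectrum_qp(es, K, mu=1.0)
        assert np.allclose(sigma, es.delta_t, atol=1e-6 * es.delta_t[0])

    def test_zero_source_kernel_gives_zero_spectrum(self, rng):
        X = rng.standard_normal((5, 3))
        spec = KernelSpec("rbf", 1.0)
        es = target_eigensystem(kernel_matrix(X, X, spec))
        es = nystrom_extrapolate(kernel_matrix(X, X, spec), es)
        sigma = solve_spectrum_qp(es, np.zeros((5, 5)), mu=1.0)
        assert np.allclose(sigma, 0, atol=1e-8)

    @pytest.mark.parametrize("r,n_grid", [(2, 201), (3, 61)])
    @pytest.mark.parametrize("mu", [1.0, 1.5, 3.0])
    def test_matches_grid_oracle(self, rng, r, n_grid, mu):
        for _ in range(7):
            phi_s = rng.standard_normal((6, r))
            B = rng.standard_normal((6, 6))
            K_s = B @ B.T / 6
            es = EigenSystem(
                phi_t=np.eye(r + 1)[:, :r], delta_t=np.ones(r), phi_s_tilde=phi_s
            )
            sigma = solve_spectrum_qp(es, K_s, mu=mu)
            s_max = max(2.0 * sigma.max(), 1.0)
            _, f_grid = _grid_argmin(phi_s, K_s, mu, r, s_max, n_grid)
            f_qp = _objective(phi_s, K_s, sigma)
            step = s_max / (n_grid - 1)
            assert f_qp <= f_grid + 1e-9 + 10 * step  # solver at least as good
            # feasibility
            assert np.all(sigma >= -1e-8)
            assert np.all(sigma[:-1] - mu * sigma[1:] >= -1e-8)

    def test_objective_monotone_in_mu(self, rng):
        X_t = rng.standard_normal((8, 4))
        X_s = rng.standard_normal((10, 4))
        spec = KernelSpec("rbf", 0.3)
        K_s = kernel_matrix(X_s, X_s, spec)
        es = target_eigensystem(kernel_matrix(X_t, X_t, spec))
        es = nystrom_extrapolate(kernel_matrix(X_s, X_t, spec), es)
        objs = [
            _objective(es.phi_s_tilde, K_s, solve_spectrum_qp(es, K_s, mu=mu))
            for mu in (1.0, 1.5, 2.0, 3.0, 5.0)
        ]
        assert np.all(np.diff(objs) >= -1e-9)

    def test_power_law_constraint_on_realistic_instance(self, rng):
        X_t = rng.standard_normal((12, 5))
        X_s = rng.standard_normal((15, 5))
        spec = KernelSpec("rbf", 0.5)
        es = target_eigensystem(kernel_matrix(X_t, X_t, spec))
        es = nystrom_extrapolate(kernel_matrix(X_s, X_t, spec), es)
        for mu in (1.0, 2.0, 4.0):
            sigma = solve_spectrum_qp(es, kernel_matrix(X_s, X_s, spec), mu=mu)
            assert np.all(sigma[:-1] - mu * sigma[1:] >= -1e-8)

    def test_mu_below_one_rejected(self, rng):
        es = EigenSystem(np.eye(2), np.ones(2), np.eye(2))
        with pytest.raises(ValueError):
            solve_spectrum_qp(es, np.eye(2), mu=0.5)


class TestUnionKernel:
    def test_zero_spectrum_gives_zero_kernel(self, rng):
        es = EigenSystem(np.eye(3), np.ones(3), rng.standard_normal((4, 3)))
        K_s_tilde, K_union = build_union_kernel(es, np.zeros(3))
        assert np.allclose(K_union, 0)
        assert np.allclose(K_s_tilde, 0)

    def test_identity_case_blocks_equal_target_kernel(self, rng):
        X = rng.standard_normal((10, 4))
        b = kka_adapt(X, X, KernelSpec("rbf", 0.5), mu=1.0, r_max=10, floor_ratio=0.0)
        n = 10
        for block in (b.K_union[:n, :n], b.K_union[:n, n:], b.K_union[n:, n:]):
            assert np.allclose(block, b.K_t, atol=1e-6)

    def test_union_kernel_is_psd(self, rng):
        X_t = rng.standard_normal((7, 3))
        X_s = rng.standard_normal((9, 3))
        b = kka_adapt(X_s, X_t, KernelSpec("laplacian", 0.7), mu=2.0)
        w = np.linalg.eigvalsh(b.K_union)
        assert w.min() >= -1e-10
        assert np.allclose(b.K_union[: b.n_s, : b.n_s], b.K_s_tilde)

    def test_source_permutation_equivariance(self, rng):
        X_t = rng.standard_normal((6, 3))
        X_s = rng.standard_normal((8, 3))
        perm = rng.permutation(8)
        spec = KernelSpec("rbf", 0.4)
        b1 = kka_adapt(X_s, X_t, spec, mu=1.5)
        b2 = kka_adapt(X_s[perm], X_t, spec, mu=1.5)
        idx = np.concatenate([perm, 8 + np.arange(6)])
        assert np.allclose(b2.K_union, b1.K_union[np.ix_(idx, idx)], atol=1e-8)
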