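"""Channel graph: correlation adjacency, sparsification, Laplacians and the
Chebyshev recursion against spectral and closed-form oracles."""

import numpy as np
import pytest

import fatiguegcn as fg
from fatiguegcn.graph import build_channel_graph, chebyshev_matrices


def random_adjacency(n, rng, density=0.7):
    A = rng.uniform(0, 1, size=(n, n))
    A = (A + A.T) / 2
    A *= rng.random((n, n)) < density
    A = np.triu(A, 1)
    A = A + A.T
    return A


def spectral_chebyshev(Lt, X, K):
    """Oracle: T_k applied through the eigendecomposition of L~."""
    lam, U = np.linalg.eigh(Lt)
    out = []
    for k in range(K):
        Tk_diag = np.cos(k * np.arccos(np.clip(lam, -1.0, 1.0)))
        out.append(U @ np.diag(Tk_diag) @ U.T @ X)
    return out


class TestCorrelationAdjacency:
    def test_identical_channels_give_unit_edge(self):
        x = np.sin(np.linspace(0, 10, 200))
        A = fg.correlation_adjacency(np.stack([x, x.copy()]))
        assert A[0, 1] == pytest.approx(1.0)
        assert A[0, 0] == 0.0

    def test_negated_channel_gives_unit_edge(self):
        x = np.sin(np.linspace(0, 10, 200))
        A = fg.correlation_adjacency(np.stack([x, -x]))
        assert A[0, 1] == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        X = rng.standard_normal((4, 200))
        A = fg.correlation_adjacency(X)
        for i in range(4):
            for j in range(i + 1, 4):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert A[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_constant_channel_rejected_by_name(self):
        X = np.vstack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="ch0"):
            fg.correlation_adjacency(X)

    def test_pools_over_windows(self, rng):
        W = rng.standard_normal((5, 3, 40))
        A = fg.correlation_adjacency(W)
        flat = np.concatenate(list(W), axis=1)
        np.testing.assert_allclose(A, fg.correlation_adjacency(flat))


class TestSparsify:
    def test_zero_threshold_is_identity(self, rng):
        A = random_adjacency(5, rng)
        np.testing.assert_array_equal(fg.sparsify(A, 0.0), A)

    def test_threshold_one_keeps_only_exact_ones(self):
        A = np.array([[0.0, 1.0, 0.9], [1.0, 0.0, 0.3], [0.9, 0.3, 0.0]])
        out = fg.sparsify(A, 1.0)
        assert out[0, 1] == 1.0 and out[0, 2] == 0.0 and out[1, 2] == 0.0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            fg.sparsify(np.zeros((2, 2)), 1.0 + 1e-9)

    def test_edge_count_matches_brute_force(self, rng):
        A = random_adjacency(6, rng, density=1.0)
        out = fg.sparsify(A, 0.5)
        expected = sum(
            1 for i in range(6) for j in range(i + 1, 6) if A[i, j] >= 0.5
        )
        assert np.count_nonzero(np.triu(out, 1)) == expected
        np.testing.assert_array_equal(out, out.T)


class TestNormalizedLaplacian:
    def test_edgeless_graph_gives_identity(self):
        np.testing.assert_array_equal(fg.normalized_laplacian(np.zeros((4, 4))), np.eye(4))

    def test_single_edge_closed_form(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        L = fg.normalized_laplacian(A)
        np.testing.assert_allclose(L, [[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(L)), [0.0, 2.0], atol=1e-12)

    def test_eigenvalues_in_zero_two(self, rng):
        for _ in range(20):
            A = random_adjacency(6, rng)
            ev = np.linalg.eigvalsh(fg.normalized_laplacian(A))
            assert ev.min() > -1e-8 and ev.max() < 2 + 1e-8

    def test_negative_entries_rejected(self):
        A = np.array([[0.0, -0.5], [-0.5, 0.0]])
        with pytest.raises(ValueError, match="non-negative"):
            fg.normalized_laplacian(A)


class TestScaledLaplacian:
    def test_identity_laplacian_unchanged(self):
        Lt, lam = fg.scaled_laplacian(np.eye(3))
        assert lam == pytest.approx(1.0)
        np.testing.assert_allclose(Lt, np.eye(3), atol=1e-12)

    def test_single_edge_closed_form(self):
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        Lt, lam = fg.scaled_laplacian(L)
        assert lam == pytest.approx(2.0)
        np.testing.assert_allclose(Lt, [[0.0, -1.0], [-1.0, 0.0]], atol=1e-12)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(Lt)), [-1.0, 1.0], atol=1e-12)

    def test_spectrum_bounded_by_one(self, rng):
        for _ in range(20):
            A = random_adjacency(7, rng)
            L = fg.normalized_laplacian(A)
            Lt, _ = fg.scaled_laplacian(L)
            assert np.max(np.abs(np.linalg.eigvalsh(Lt))) <= 1 + 1e-8

    def test_null_graph_rejected(self):
        with pytest.raises(ValueError):
            fg.scaled_laplacian(np.zeros((3, 3)))

    def test_approx_mode_uses_upper_bound(self):
        L = np.eye(4)
        Lt, lam = fg.scaled_laplacian(L, mode="approx")
        assert lam == 2.0
        np.testing.assert_allclose(Lt, np.zeros((4, 4)), atol=1e-12)


class TestChebyshevBasis:
    def test_order_one_is_input(self, rng):
        X = rng.standard_normal((4, 3))
        Lt = np.zeros((4, 4))
        out = fg.chebyshev_basis(Lt, X, 1)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0], X)

    def test_identity_laplacian_repeats_input(self, rng):
        X = rng.standard_normal((3, 2))
        out = fg.chebyshev_basis(np.eye(3), X, 2)
        np.testing.assert_allclose(out[1], X)

    def test_t3_matches_explicit_polynomial_and_spectral_oracle(self, rng):
        A = random_adjacency(4, rng, density=1.0)
        Lt, _ = fg.scaled_laplacian(fg.normalized_laplacian(A))
        X = rng.standard_normal((4, 5))
        T = fg.chebyshev_basis(Lt, X, 4)
        explicit = (4 * np.linalg.matrix_power(Lt, 3) - 3 * Lt) @ X
        np.testing.assert_allclose(T[3], explicit, atol=1e-9)
        spectral = spectral_chebyshev(Lt, X, 4)
        np.testing.assert_allclose(T[3], spectral[3], atol=1e-9)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            fg.chebyshev_basis(np.eye(2), np.ones((2, 1)), 0)

    def test_recursion_matches_spectral_oracle_many_graphs(self, rng):
        """Recursion vs eigendecomposition on random graphs, n <= 8, K <= 6."""
        for _ in range(25):
            n = rng.integers(2, 9)
            A = random_adjacency(n, rng)
            if A.sum() == 0:
                continue
            Lt, _ = fg.scaled_laplacian(fg.normalized_laplacian(A))
            X = rng.standard_normal((n, 3))
            K = int(rng.integers(1, 7))
            rec = fg.chebyshev_basis(Lt, X, K)
            spec = spectral_chebyshev(Lt, X, K)
            for r, s in zip(rec, spec):
                np.testing.assert_allclose(r, s, atol=1e-8)

    def test_permutation_equivariance(self, rng):
        A = random_adjacency(5, rng, density=1.0)
        Lt, _ = fg.scaled_laplacian(fg.normalized_laplacian(A))
        X = rng.standard_normal((5, 4))
        perm = rng.permutation(5)
        P = np.eye(5)[perm]
        Lt_p = P @ Lt @ P.T
        for k, (T, Tp) in enumerate(zip(fg.chebyshev_basis(Lt, X, 4),
                                        fg.chebyshev_basis(Lt_p, P @ X, 4))):
            np.testing.assert_allclose(P @ T, Tp, atol=1e-10)


class TestBuildChannelGraph:
    def test_zero_threshold_equals_dense_path(self, rng):
        W = rng.standard_normal((6, 4, 100))
        g0 = build_channel_graph(W, threshold=0.0)
        A = fg.correlation_adjacency(W)
        np.testing.assert_array_equal(g0.adjacency, A)
        np.testing.assert_allclose(
            g0.laplacian_norm, fg.normalized_laplacian(A), atol=1e-12
        )

    def test_degree_matrix(self, rng):
        W = rng.standard_normal((6, 4, 100))
        g = build_channel_graph(W, threshold=0.0)
        np.testing.assert_allclose(np.diag(g.degree), g.adjacency.sum(axis=1))

    def test_disconnection_warns(self, rng):
        W = rng.standard_normal((6, 4, 2000))  # near-zero correlations
        with pytest.warns(RuntimeWarning, match="disconnected"):
            build_channel_graph(W, threshold=0.9)

    def test_binarize_flag(self, rng):
        x = np.sin(np.linspace(0, 20, 300))
        W = np.stack([x, 0.9 * x + 0.1 * rng.standard_normal(300), -x])[None]
        g = build_channel_graph(W, threshold=0.5, binarize=True)
        assert set(np.unique(g.adjacency)) <= {0.0, 1.0}

    def test_chebyshev_matrices_start_with_identity(self, rng):
        W = rng.standard_normal((6, 4, 100))
        g = build_channel_graph(W, threshold=0.0)
        T = chebyshev_matrices(g.laplacian_scaled, 3)
        np.testing.assert_array_equal(T[0], np.eye(4))
        np.testing.assert_allclose(T[1], g.laplacian_scaled)
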