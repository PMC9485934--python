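"""Core multi-kernel LPP: neighbor graph, scatter identities, generalized
eigensolve, simplex weight optimization, and the alternating fit."""

import numpy as np
import pytest

from rmkllpp.kernels import KernelSet, KernelWeights
from rmkllpp.mkl_lpp import (
    MKLLPP,
    _minimize_simplex_ratio,
    _relative_ridge,
    _solve_projection,
    _weight_step_matrices,
    build_neighbor_graph,
    fit_mkl_lpp,
    optimize_projection,
    optimize_weights,
    project,
    projected_scatter,
)
from tests.conftest import random_kernel_set


def linear_kernel_set(positions):
    x = np.asarray(positions, dtype=float)
    k = np.outer(x, x)
    return KernelSet([k], sample_ids=[f"S{i}" for i in range(len(x))])


class TestNeighborGraph:
    def test_full_k_gives_complete_graph(self, rng):
        ks = random_kernel_set(rng, n=12, m=2)
        g = build_neighbor_graph(ks, k_neighbors=11)
        assert (g.degrees == 11).all()
        assert np.array_equal(g.W, 1 - np.eye(12))

    def test_adjacency_always_symmetric(self, rng):
        for _ in range(5):
            ks = random_kernel_set(rng, n=25, m=3)
            g = build_neighbor_graph(ks, k_neighbors=4)
            np.testing.assert_array_equal(g.W, g.W.T)
            assert np.diag(g.W).sum() == 0
            np.testing.assert_array_equal(g.degrees, g.W.sum(1))

    def test_matches_brute_force_or_rule_on_line(self):
        # samples at 0, 1, 3, 7: nearest neighbours are 1<-0, 0<-1, 1<-3, 3<-7
        ks = linear_kernel_set([0.0, 1.0, 3.0, 7.0])
        g = build_neighbor_graph(ks, k_neighbors=1)
        expected = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (2, 3)]:  # OR-rule union of the k-NN lists
            expected[a, b] = expected[b, a] = 1
        np.testing.assert_array_equal(g.W, expected)

    def test_k_out_of_range_rejected(self, rng):
        ks = random_kernel_set(rng, n=10, m=1)
        with pytest.raises(ValueError):
            build_neighbor_graph(ks, k_neighbors=10)
        with pytest.raises(ValueError):
            build_neighbor_graph(ks, k_neighbors=0)


class TestProjectedScatter:
    def test_zero_adjacency_zero_sw(self, rng):
        ks = random_kernel_set(rng, n=8, m=2)
        g = build_neighbor_graph(ks, 3)
        g.W[:] = 0
        g.degrees[:] = 0
        s_w, _ = projected_scatter(ks, g, KernelWeights.uniform(2))
        np.testing.assert_allclose(s_w, 0.0)

    def test_two_sample_direct_summation(self):
        k = np.eye(2)
        ks = KernelSet([k], sample_ids=["a", "b"])
        g = build_neighbor_graph(ks, 1)
        s_w, s_d = projected_scatter(ks, g, KernelWeights(np.ones(1)))
        u = k  # combined kernel
        diff = (u[:, 0] - u[:, 1])[:, None]
        expected_sw = 2 * diff @ diff.T  # w01 = w10 = 1
        expected_sd = np.outer(u[:, 0], u[:, 0]) + np.outer(u[:, 1], u[:, 1])
        np.testing.assert_allclose(s_w, expected_sw, atol=1e-12)
        np.testing.assert_allclose(s_d, expected_sd, atol=1e-12)

    def test_laplacian_identity_vs_pairwise_sum(self, rng):
        ks = random_kernel_set(rng, n=15, m=3)
        g = build_neighbor_graph(ks, 4)
        w = KernelWeights(rng.dirichlet(np.ones(3)))
        s_w, s_d = projected_scatter(ks, g, w)
        from rmkllpp.kernels import combine_kernels

        u = combine_kernels(ks, w)
        sw_direct = np.zeros((15, 15))
        sd_direct = np.zeros((15, 15))
        for i in range(15):
            sd_direct += g.degrees[i] * np.outer(u[:, i], u[:, i])
            for j in range(15):
                if g.W[i, j]:
                    d = u[:, i] - u[:, j]
                    sw_direct += np.outer(d, d)
        np.testing.assert_allclose(s_w, sw_direct, atol=1e-10 * np.abs(sw_direct).max())
        np.testing.assert_allclose(s_d, sd_direct, atol=1e-10 * np.abs(sd_direct).max())


class TestOptimizeProjection:
    def test_rank_deficient_constraint_succeeds_with_ridge(self, rng):
        a = rng.normal(size=(10, 2))
        k = a @ a.T  # rank 2 -> S_D heavily rank-deficient
        ks = KernelSet([k], sample_ids=[f"S{i}" for i in range(10)])
        g = build_neighbor_graph(ks, 3)
        A = optimize_projection(ks, g, KernelWeights(np.ones(1)), n_components=9)
        s_w, s_d = projected_scatter(ks, g, KernelWeights(np.ones(1)))
        r = _relative_ridge(s_d, 1e-3)
        gram = A.T @ (s_d + r * np.eye(10)) @ A
        np.testing.assert_allclose(gram, np.eye(9), atol=1e-6)

    def test_trace_equals_sum_of_bottom_eigenvalues(self, rng):
        ks = random_kernel_set(rng, n=20, m=2)
        g = build_neighbor_graph(ks, 5)
        w = KernelWeights.uniform(2)
        s_w, s_d = projected_scatter(ks, g, w)
        r = _relative_ridge(s_d, 1e-3)
        a, vals = _solve_projection(s_w, s_d, 4, r)
        assert np.trace(a.T @ s_w @ a) == pytest.approx(vals.sum(), abs=1e-8)

    def test_deterministic_sign_convention(self, rng):
        ks = random_kernel_set(rng, n=20, m=2)
        g = build_neighbor_graph(ks, 5)
        a1 = optimize_projection(ks, g, KernelWeights.uniform(2), 3)
        a2 = optimize_projection(ks, g, KernelWeights.uniform(2), 3)
        np.testing.assert_array_equal(a1, a2)
        for j in range(3):
            assert a1[np.argmax(np.abs(a1[:, j])), j] > 0


class TestOptimizeWeights:
    def test_single_kernel_weight_is_one(self, rng):
        ks = random_kernel_set(rng, n=15, m=1)
        g = build_neighbor_graph(ks, 4)
        a = optimize_projection(ks, g, KernelWeights(np.ones(1)), 3)
        w = optimize_weights(ks, g, a)
        np.testing.assert_array_equal(w.beta, [1.0])

    def test_identical_kernels_objective_invariant_to_split(self, rng):
        base = random_kernel_set(rng, n=15, m=1)
        k = base.kernels[0]
        ks = KernelSet([k, k], sample_ids=base.sample_ids)
        g = build_neighbor_graph(ks, 4)
        a = optimize_projection(ks, g, KernelWeights.uniform(2), 3)
        s_w, s_d = _weight_step_matrices(ks, g, a)

        def ratio(b):
            return (b @ s_w @ b) / (b @ s_d @ b)

        w = optimize_weights(ks, g, a)
        for t in (0.0, 0.25, 0.5, 1.0):
            assert ratio(np.array([t, 1 - t])) == pytest.approx(ratio(w.beta), rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_two_kernel_weights_match_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        ks = random_kernel_set(rng, n=30, m=2)
        g = build_neighbor_graph(ks, 5)
        a = optimize_projection(ks, g, KernelWeights.uniform(2), 3)
        s_w, s_d = _weight_step_matrices(ks, g, a)
        t = np.linspace(0, 1, 1001)
        grid = np.column_stack([t, 1 - t])
        vals = np.einsum("gi,ij,gj->g", grid, s_w, grid) / np.einsum(
            "gi,ij,gj->g", grid, s_d, grid
        )
        w = optimize_weights(ks, g, a)
        achieved = (w.beta @ s_w @ w.beta) / (w.beta @ s_d @ w.beta)
        assert achieved <= vals.min() + 1e-4


class TestFit:
    def test_single_kernel_equals_direct_eigensolve(self, rng):
        ks = random_kernel_set(rng, n=40, m=1)
        g = build_neighbor_graph(ks, 9)
        model = fit_mkl_lpp(ks, g, n_components=4)
        s_w, s_d = projected_scatter(ks, g, KernelWeights(np.ones(1)))
        a, _ = _solve_projection(s_w, s_d, 4, _relative_ridge(s_d, 1e-3))
        np.testing.assert_allclose(model.A, a, atol=1e-10)

    def test_duplicated_kernel_matches_single_kernel_embedding(self, rng):
        base = random_kernel_set(rng, n=30, m=1)
        k = base.kernels[0]
        m1 = MKLLPP(n_components=3, k_neighbors=5).fit(base)
        m2 = MKLLPP(n_components=3, k_neighbors=5).fit(
            KernelSet([k, k], sample_ids=base.sample_ids)
        )
        np.testing.assert_allclose(
            np.abs(m1.embedding_), np.abs(m2.embedding_), atol=1e-8
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_objective_trace_non_increasing(self, seed):
        rng = np.random.default_rng(100 + seed)
        ks = random_kernel_set(rng, n=40, m=3)
        est = MKLLPP(n_components=4, k_neighbors=7).fit(ks)
        tr = est.objective_trace_
        rel = np.diff(tr) / np.maximum(np.abs(tr[:-1]), 1e-300)
        assert (rel <= 1e-8).all()

    def test_deterministic_for_fixed_inputs(self, rng):
        ks = random_kernel_set(rng, n=30, m=3)
        e1 = MKLLPP(n_components=3).fit(ks).embedding_
        e2 = MKLLPP(n_components=3).fit(ks).embedding_
        np.testing.assert_array_equal(e1, e2)

    def test_beta_first_initialization_runs(self, rng):
        ks = random_kernel_set(rng, n=30, m=3)
        est = MKLLPP(n_components=3, init="beta_first").fit(ks)
        assert est.kernel_weights_.sum() == pytest.approx(1.0)
        assert (np.diff(est.objective_trace_) <= 1e-8).all()

    def test_permutation_equivariance(self, rng):
        ks = random_kernel_set(rng, n=25, m=2)
        perm = rng.permutation(25)
        ks_perm = KernelSet(
            [k[np.ix_(perm, perm)] for k in ks.kernels],
            sample_ids=np.asarray(ks.sample_ids)[perm],
        )
        e = MKLLPP(n_components=3, k_neighbors=5).fit(ks).embedding_
        e_perm = MKLLPP(n_components=3, k_neighbors=5).fit(ks_perm).embedding_
        np.testing.assert_allclose(e_perm, e[perm], atol=1e-6)

    def test_informative_kernel_gets_more_weight_than_permuted_noise(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(7000 + seed)
            labels = np.repeat([0, 1, 2], 20)
            # each subtype shifts its own block of 6 features by 2.5 sd
            x = rng.normal(size=(60, 18))
            for s in range(3):
                x[labels == s, 6 * s : 6 * (s + 1)] += 2.5
            d2 = ((x[:, None] - x[None]) ** 2).sum(-1)
            k_inf = np.exp(-d2 / (2 * np.median(d2)))
            # destroy the planted structure: permute samples per feature
            x_noise = np.column_stack([rng.permutation(col) for col in x.T])
            d2n = ((x_noise[:, None] - x_noise[None]) ** 2).sum(-1)
            k_noise = np.exp(-d2n / (2 * np.median(d2n)))
            ks = KernelSet([k_inf, k_noise], sample_ids=[f"S{i}" for i in range(60)])
            est = MKLLPP(n_components=3, k_neighbors=9).fit(ks)
            wins += est.kernel_weights_[0] > est.kernel_weights_[1]
        assert wins >= 9


class TestProject:
    def test_basis_vector_reads_kernel_row(self, rng):
        ks = random_kernel_set(rng, n=10, m=1)
        k = ks.kernels[0]
        from rmkllpp.mkl_lpp import ProjectionModel

        a = np.zeros((10, 1))
        a[0, 0] = 1.0
        model = ProjectionModel(
            A=a, beta=KernelWeights(np.ones(1)), n_components=1,
            objective_trace=np.array([0.0]), n_iter=1, converged=True,
            graph=build_neighbor_graph(ks, 3), sample_ids=ks.sample_ids,
        )
        coords = project(model, ks)
        np.testing.assert_allclose(coords[:, 0], k[0, :], atol=1e-12)

    def test_training_coordinates_equal_fit_embedding(self, rng):
        ks = random_kernel_set(rng, n=20, m=2)
        est = MKLLPP(n_components=3, k_neighbors=5).fit(ks)
        np.testing.assert_allclose(est.transform(ks), est.embedding_, atol=1e-12)

    def test_coordinates_linear_in_kernels(self, rng):
        ks = random_kernel_set(rng, n=15, m=2)
        est = MKLLPP(n_components=2, k_neighbors=4).fit(ks)
        scaled = KernelSet([2 * k for k in ks.kernels], sample_ids=ks.sample_ids)
        np.testing.assert_allclose(
            est.transform(scaled), 2 * est.transform(ks), atol=1e-10
        )

    def test_dimension_mismatch_rejected(self, rng):
        ks = random_kernel_set(rng, n=20, m=2)
        est = MKLLPP(n_components=2, k_neighbors=4).fit(ks)
        other = random_kernel_set(rng, n=10, m=2)
        with pytest.raises(ValueError):
            est.transform(other)
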