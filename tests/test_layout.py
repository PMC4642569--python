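"""Gaussian layout: overlaps, objective, gradients, optimizer, ordering."""

import math

import numpy as np
import pytest

import netkl
from netkl import (
    Embedding,
    as_matrix,
    init_product_state,
    layout_objective,
    mutual_information,
    optimize_layout,
    ordering_from_embedding,
    overlap,
    overlap_matrix,
    relative_entropy,
)
from netkl.layout import GaussianEmbedding, _LayoutState, disc_overlap, gradient
from .conftest import random_symmetric


def random_embedding(rng, n, d):
    return Embedding(
        d,
        rng.standard_normal((n, d)),
        rng.random(n) + 0.5,
        rng.random(n) + 0.2,
    )


class TestOverlap:
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_zero_distance_closed_form(self, d):
        emb = Embedding(d, np.zeros((2, d)), np.array([0.7, 0.7]), np.ones(2))
        assert overlap(emb, 0, 1) == pytest.approx(
            (4 * math.pi * 0.7**2) ** (-d / 2), rel=1e-12
        )

    def test_monotone_decay_with_distance(self):
        vals = []
        for dist in np.linspace(0, 10, 30):
            emb = Embedding(
                2, np.array([[0.0, 0], [dist, 0]]), np.ones(2), np.ones(2)
            )
            vals.append(overlap(emb, 0, 1))
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-9

    def test_against_numeric_quadrature_1d(self):
        # b_ij must equal the explicit integral of the two Gaussian densities
        from scipy.integrate import quad

        emb = Embedding(1, np.array([[0.0], [2.0]]), np.array([1.0, 1.0]), np.ones(2))
        expect = (4 * math.pi) ** -0.5 * math.exp(-1.0)
        assert overlap(emb, 0, 1) == pytest.approx(expect, rel=1e-12)

        def rho(x, mu, s):
            return (2 * math.pi * s**2) ** -0.5 * math.exp(-((x - mu) ** 2) / (2 * s**2))

        num, _ = quad(lambda x: rho(x, 0, 1) * rho(x, 2, 1), -30, 30)
        assert overlap(emb, 0, 1) == pytest.approx(num, abs=1e-8)

    def test_disc_coordinate_search_separates_triangle_pair(self):
        # finite-support discs can represent a sparse graph perfectly:
        # coordinate search drives D toward 0 by removing spurious overlaps
        from netkl.layout import disc_layout_objective, optimize_disc_layout

        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        rng = np.random.default_rng(0)
        emb0 = Embedding(2, 0.3 * rng.standard_normal((4, 2)), np.full(4, 1.0),
                         np.ones(4))
        emb, D = optimize_disc_layout(A, emb0, n_rounds=60)
        assert np.isfinite(D)
        assert D <= disc_layout_objective(A, emb0) + 1e-12
        assert D < 0.05  # two disjoint dumbbells are almost perfectly drawn

    def test_disc_overlap_limits(self):
        emb = Embedding(2, np.array([[0.0, 0], [0.0, 0]]), np.array([1.0, 2.0]), np.ones(2))
        # full containment: integral of the smaller disc's density over itself
        assert disc_overlap(emb, 0, 1) == pytest.approx(
            1.0 / (math.pi * 2.0**2), rel=1e-12
        )
        emb.positions[1] = [5.0, 0]
        assert disc_overlap(emb, 0, 1) == 0.0


class TestOverlapMatrix:
    def test_two_node_normalization(self):
        emb = Embedding(1, np.array([[0.0], [1.0]]), np.ones(2), np.ones(2))
        B, btot = overlap_matrix(emb)
        assert btot == pytest.approx(2 * B[0, 1], rel=1e-12)
        _, btot_self = overlap_matrix(emb, include_self=True)
        assert btot_self == pytest.approx(2 * B[0, 1] + B[0, 0] + B[1, 1], rel=1e-12)

    def test_incremental_total_matches_full_recomputation(self, rng):
        A = as_matrix(random_symmetric(rng, 10))
        emb = random_embedding(rng, 10, 2)
        state = _LayoutState(A, emb)
        for _ in range(40):
            k = int(rng.integers(10))
            x_k = rng.standard_normal(2)
            sigma_k = float(rng.random() + 0.3)
            h_k = float(rng.random() + 0.1)
            D, lnrow, row, btot, cross = state.trial(
                k, x_k=x_k, sigma_k=sigma_k, h_k=h_k
            )
            state.commit(k, x_k, sigma_k, h_k, lnrow, row, btot, cross)
        fresh = _LayoutState(A, state.emb)
        # totals are stored re-centered; compare on the absolute scale
        assert state.btot * np.exp(state.offset) == pytest.approx(
            fresh.btot * np.exp(fresh.offset), rel=1e-10
        )
        assert state.D == pytest.approx(fresh.D, rel=1e-9)

    def test_support_masking(self, rng):
        emb = random_embedding(rng, 5, 2)
        support = np.zeros((5, 5), bool)
        support[0, 1] = support[1, 0] = True
        B, btot = overlap_matrix(emb, support=support)
        assert np.count_nonzero(B) == 2
        _, btot_full = overlap_matrix(emb)
        assert btot == btot_full  # normalization always over all pairs


class TestObjective:
    def test_matches_naive_double_loop(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            A = as_matrix(random_symmetric(rng, n))
            emb = random_embedding(rng, n, 2)
            D, _ = layout_objective(A, emb)
            B = np.array([[overlap(emb, i, j) for j in range(n)] for i in range(n)])
            np.fill_diagonal(B, 0.0)  # simple graph: self-overlap not counted
            assert D == pytest.approx(relative_entropy(A, B), rel=1e-12)

    def test_rank_one_coincident_is_perfect(self):
        # complete graph with product weights: all nodes at one point, D = 0
        marg = np.array([1.0, 2.0, 3.0, 4.0])
        A = np.outer(marg, marg)
        np.fill_diagonal(A, 0.0)
        # restore exact product structure including diagonal
        A_full = np.outer(marg, marg)
        emb = Embedding(2, np.zeros((4, 2)), np.ones(4), marg / marg.sum())
        D, _ = layout_objective(as_matrix(A_full), emb)
        assert D == pytest.approx(0.0, abs=1e-12)

    def test_invariance_under_rigid_motions(self, rng):
        A = as_matrix(random_symmetric(rng, 6))
        emb = random_embedding(rng, 6, 2)
        D0, _ = layout_objective(A, emb)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        for T in (R, -np.eye(2), np.eye(2)):
            emb2 = emb.copy()
            emb2.positions = emb.positions @ T.T + np.array([3.0, -2.0])
            D1, _ = layout_objective(A, emb2)
            assert D1 == pytest.approx(D0, rel=1e-10)

    def test_proportional_rows_shared_distribution(self, rng):
        # rows i, j proportional: co-locating them costs nothing vs merging
        from netkl import partition_divergence

        A = random_symmetric(rng, 5)
        A[3] = 2.0 * A[4]
        A[:, 3] = A[3]
        A[3, 4] = A[4, 3] = 0.0
        A[3, 3] = A[4, 4] = 0.0
        labels = np.array([0, 1, 2, 3, 3])
        assert partition_divergence(as_matrix(A), labels) == pytest.approx(
            0.0, abs=1e-10
        )


class TestGradients:
    def test_against_finite_differences(self, rng):
        # 50 seeded configurations, all three parameter blocks
        for trial in range(50):
            n = int(rng.integers(3, 7))
            d = int(rng.integers(1, 4))
            A = as_matrix(random_symmetric(rng, n))
            emb = random_embedding(rng, n, d)
            k = int(rng.integers(n))
            gx, gs, gh = gradient(A, emb, k)
            eps = 1e-6
            for a in range(d):
                e2 = emb.copy(); e2.positions[k, a] += eps
                Dp = layout_objective(A, e2)[0]
                e2 = emb.copy(); e2.positions[k, a] -= eps
                Dm = layout_objective(A, e2)[0]
                assert gx[a] == pytest.approx((Dp - Dm) / (2 * eps), abs=2e-6)
            for arr, g in (("sigma", gs), ("h", gh)):
                e2 = emb.copy(); getattr(e2, arr)[k] *= math.exp(eps)
                Dp = layout_objective(A, e2)[0]
                e2 = emb.copy(); getattr(e2, arr)[k] *= math.exp(-eps)
                Dm = layout_objective(A, e2)[0]
                assert g == pytest.approx((Dp - Dm) / (2 * eps), abs=2e-6)

    def test_stationary_when_overlaps_match(self):
        # perfect representation: p = q everywhere -> zero gradient
        marg = np.array([1.0, 1.0, 1.0])
        A = np.outer(marg, marg)
        emb = Embedding(2, np.zeros((3, 2)), np.ones(3), marg / marg.sum())
        gx, gs, gh = gradient(as_matrix(A), emb, 0)
        assert np.allclose(gx, 0, atol=1e-12)
        assert abs(gh) < 1e-12

    def test_distant_connected_node_attracts(self):
        # path 0-1-2 with node 0 far out: its underweighted overlap with
        # node 1 exerts a net attractive force back toward the chain
        A = as_matrix(np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]]))
        emb = Embedding(
            1, np.array([[-10.0], [0.0], [1.0]]), np.ones(3), np.ones(3)
        )
        gx, _, _ = gradient(A, emb, 0)
        # D falls as x_0 increases toward the others
        assert gx[0] < 0


class TestInit:
    def test_product_state_divergence_closed_form(self, karate):
        # coincident start with h ∝ a_i*: D0 = I(A) + ln(1 - sum (a_i*/a_**)^2)
        emb = init_product_state(karate, 2, seed=0, jitter=0.0)
        D, _ = layout_objective(karate, emb)
        s = np.sum((karate.row_marginals / karate.total) ** 2)
        expect = mutual_information(karate) + np.log(1 - s)
        assert D == pytest.approx(expect, rel=1e-10)

    def test_product_state_exact_for_diagonal_inputs(self, rng):
        # when the input carries its diagonal, the coincident start is exactly
        # the product state: D0 = I(A)
        A = as_matrix(rng.random((6, 6)) + 0.1, symmetric=False)
        emb = init_product_state(A, 2, jitter=0.0)
        # symmetrize for the layout
        v = 0.5 * (A.values + A.values.T)
        A2 = as_matrix(v)
        emb = init_product_state(A2, 2, jitter=0.0)
        D, _ = layout_objective(A2, emb)
        assert D == pytest.approx(mutual_information(A2), rel=1e-10)

    def test_determinism_and_jitter(self, karate):
        e1 = init_product_state(karate, 2, seed=42)
        e2 = init_product_state(karate, 2, seed=42)
        np.testing.assert_array_equal(e1.positions, e2.positions)
        assert np.abs(e1.positions).max() < 1e-4


class TestOptimizer:
    def test_path_graph_ordering(self):
        A = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
        res = optimize_layout(A, 1, seed=0, jitter=0.3, n_restarts=3)
        x = res.embedding.positions[:, 0]
        assert (x[0] < x[1] < x[2]) or (x[2] < x[1] < x[0])

    def test_divergence_decreases_and_is_consistent(self, rng):
        A = random_symmetric(rng, 8, density=0.6)
        emb0 = init_product_state(A, 2, seed=1)
        D0, _ = layout_objective(as_matrix(A), emb0)
        res = optimize_layout(A, 2, seed=1, max_iter=400)
        assert res.divergence < D0
        D_re, _ = layout_objective(as_matrix(A), res.embedding)
        assert res.divergence == pytest.approx(D_re, rel=1e-9)

    def test_disconnected_triangles_drift_apart(self):
        A = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i != j:
                        A[i, j] = 1.0
        res = optimize_layout(A, 2, seed=3, jitter=0.2, n_restarts=3)
        X = res.embedding.positions
        intra = max(
            np.linalg.norm(X[i] - X[j])
            for blk in (range(3), range(3, 6))
            for i in blk
            for j in blk
        )
        inter = min(
            np.linalg.norm(X[i] - X[j]) for i in range(3) for j in range(3, 6)
        )
        assert inter > intra

    def test_determinism_under_seed(self, rng):
        A = random_symmetric(rng, 6, density=0.8)
        r1 = optimize_layout(A, 2, seed=9, max_iter=150)
        r2 = optimize_layout(A, 2, seed=9, max_iter=150)
        np.testing.assert_array_equal(r1.embedding.positions, r2.embedding.positions)
        assert r1.divergence == r2.divergence

    def test_cross_entropy_linearity_in_input(self, rng):
        # H(alpha A1 + (1-alpha) A2, B) = alpha H(A1,B) + (1-alpha) H(A2,B)
        from netkl import cross_entropy

        A1 = random_symmetric(rng, 6)
        A2 = random_symmetric(rng, 6)
        A2 *= A1.sum() / A2.sum()  # equal totals
        B = random_symmetric(rng, 6, zero_diagonal=False) + 0.1
        for alpha in (0.25, 0.5, 0.9):
            mix = alpha * A1 + (1 - alpha) * A2
            assert cross_entropy(mix, B) == pytest.approx(
                alpha * cross_entropy(A1, B) + (1 - alpha) * cross_entropy(A2, B),
                rel=1e-12,
            )


class TestOrdering:
    def test_identity_and_reversal(self):
        emb = Embedding(1, np.array([[0.0], [1.0], [2.0]]), np.ones(3), np.ones(3))
        np.testing.assert_array_equal(ordering_from_embedding(emb), [0, 1, 2])
        emb.positions = -emb.positions
        # reflection-canonicalized: first listed index below last
        np.testing.assert_array_equal(ordering_from_embedding(emb), [0, 1, 2])

    def test_is_permutation_with_ties(self, rng):
        x = rng.integers(0, 3, size=10).astype(float)[:, None]
        emb = Embedding(1, x, np.ones(10), np.ones(10))
        perm = ordering_from_embedding(emb)
        assert sorted(perm) == list(range(10))

    def test_requires_one_dimension(self, rng):
        emb = random_embedding(rng, 4, 2)
        with pytest.raises(ValueError, match="1-D"):
            ordering_from_embedding(emb)


class TestEstimator:
    def test_sklearn_protocol_and_attributes(self, rng):
        from sklearn.base import clone

        A = random_symmetric(rng, 7, density=0.8)
        est = GaussianEmbedding(n_components=2, max_iter=200, random_state=0)
        clone(est)
        X = est.fit_transform(A)
        assert X.shape == (7, 2)
        assert est.sigma_.shape == (7,)
        assert est.divergence_ >= 0
        assert 0 <= est.eta_

    def test_one_dimensional_exposes_ordering(self, rng):
        A = random_symmetric(rng, 6, density=0.9)
        est = GaussianEmbedding(n_components=1, max_iter=150, random_state=0).fit(A)
        assert sorted(est.ordering_) == list(range(6))
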