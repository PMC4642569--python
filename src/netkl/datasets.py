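"""Synthetic benchmark generators and bundled fixtures.

The planted-partition generator mirrors the degree-corrected Poisson block
structure that the coarse-graining objective scores exactly: expected edge
weight ``a_ij = theta_i theta_j omega_{g(i)g(j)}`` with per-group-normalized
node propensities theta and a symmetric block affinity matrix omega.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import WeightedMatrix, cross_entropy

__all__ = [
    "PlantedModel",
    "generate_planted",
    "karate_fixture",
    "karate_faction_labels",
    "noisy_ensemble",
]

# Weighted friendship network of the 34-member karate club (Zachary 1977,
# public domain); edge weights are the number of shared social contexts.
# Frozen here so the fixture needs no downloads; a test cross-checks it
# against networkx's copy.
_KARATE_EDGES: list[tuple[int, int, int]] = [
    (0, 1, 4), (0, 2, 5), (0, 3, 3), (0, 4, 3), (0, 5, 3), (0, 6, 3),
    (0, 7, 2), (0, 8, 2), (0, 10, 2), (0, 11, 3), (0, 12, 1), (0, 13, 3),
    (0, 17, 2), (0, 19, 2), (0, 21, 2), (0, 31, 2), (1, 2, 6), (1, 3, 3),
    (1, 7, 4), (1, 13, 5), (1, 17, 1), (1, 19, 2), (1, 21, 2), (1, 30, 2),
    (2, 3, 3), (2, 7, 4), (2, 8, 5), (2, 9, 1), (2, 13, 3), (2, 27, 2),
    (2, 28, 2), (2, 32, 2), (3, 7, 3), (3, 12, 3), (3, 13, 3), (4, 6, 2),
    (4, 10, 3), (5, 6, 5), (5, 10, 3), (5, 16, 3), (6, 16, 3), (8, 30, 3),
    (8, 32, 3), (8, 33, 4), (9, 33, 2), (13, 33, 3), (14, 32, 3), (14, 33, 2),
    (15, 32, 3), (15, 33, 4), (18, 32, 1), (18, 33, 2), (19, 33, 1),
    (20, 32, 3), (20, 33, 1), (22, 32, 2), (22, 33, 3), (23, 25, 5),
    (23, 27, 4), (23, 29, 3), (23, 32, 5), (23, 33, 4), (24, 25, 2),
    (24, 27, 3), (24, 31, 2), (25, 31, 7), (26, 29, 4), (26, 33, 2),
    (27, 33, 4), (28, 31, 2), (28, 33, 2), (29, 32, 4), (29, 33, 2),
    (30, 32, 3), (30, 33, 3), (31, 32, 4), (31, 33, 4), (32, 33, 5),
]

# 0 = Mr. Hi's faction, 1 = the officers' faction after the split.
_KARATE_FACTION = [
    0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1,
    1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1,
]


def karate_fixture() -> WeightedMatrix:
    """The weighted 34-node Zachary karate club network (78 edges)."""
    A = np.zeros((34, 34))
    for i, j, w in _KARATE_EDGES:
        A[i, j] = w
        A[j, i] = w
    return WeightedMatrix(A, symmetric=True, zero_diagonal=True)


def karate_faction_labels() -> np.ndarray:
    """Ground-truth two-faction membership after the club's split."""
    return np.array(_KARATE_FACTION)


@dataclass
class PlantedModel:
    """Degree-corrected planted-partition model.

    Parameters
    ----------
    sizes : group sizes (sum = N).
    omega : (K, K) symmetric non-negative block affinities; omega_rs is the
        total expected weight between groups r and s (up to the theta
        weighting).
    theta : optional per-node propensities, normalized to sum to 1 within
        each group; uniform within groups by default.
    mode : "expected" returns the expectation matrix itself; "poisson"
        draws symmetric Poisson edge counts around it.
    self_loops : include the diagonal expectation theta_i^2 omega_rr.  With
        self-loops the expected matrix has exactly proportional rows within
        each block, so coarse-graining the true partition loses nothing.
    """

    sizes: tuple[int, ...]
    omega: np.ndarray
    theta: np.ndarray | None = None
    mode: str = "poisson"
    self_loops: bool = True

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        if any(s <= 0 for s in self.sizes):
            raise ValueError("group sizes must be positive")
        self.omega = np.asarray(self.omega, dtype=float)
        K = len(self.sizes)
        if self.omega.shape != (K, K):
            raise ValueError("omega must be K x K")
        if not np.array_equal(self.omega, self.omega.T) or np.any(self.omega < 0):
            raise ValueError("omega must be symmetric and non-negative")
        if self.omega.sum() == 0:
            raise ValueError("omega is all zero")
        if self.mode not in ("expected", "poisson"):
            raise ValueError("mode must be 'expected' or 'poisson'")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape != (sum(self.sizes),):
                raise ValueError("theta must have one entry per node")
            if np.any(self.theta <= 0):
                raise ValueError("theta must be positive")

    @classmethod
    def two_block(
        cls,
        n: int = 40,
        *,
        ratio: float = 8.0,
        omega_in: float = 640.0,
        mode: str = "poisson",
        self_loops: bool = False,
    ) -> "PlantedModel":
        """Canonical two-block benchmark: equal halves, affinity contrast
        ``omega_in / omega_out = ratio``.

        The default density (mean weighted degree ≈ 34 at n = 40) puts the
        model deep in the exact-recovery regime: at ratio 8 the chance that
        any node's Poisson within-block degree is overtaken by its
        between-block degree is negligible.
        """
        half = n // 2
        omega = np.array(
            [[omega_in, omega_in / ratio], [omega_in / ratio, omega_in]]
        )
        return cls(sizes=(half, n - half), omega=omega, mode=mode,
                   self_loops=self_loops)

    @property
    def n_nodes(self) -> int:
        return sum(self.sizes)

    @property
    def labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.sizes)), self.sizes)

    def normalized_theta(self) -> np.ndarray:
        g = self.labels
        theta = (
            np.ones(self.n_nodes) if self.theta is None else self.theta.copy()
        )
        for r in range(len(self.sizes)):
            theta[g == r] /= theta[g == r].sum()
        return theta

    def expected_matrix(self) -> np.ndarray:
        g = self.labels
        theta = self.normalized_theta()
        lam = np.outer(theta, theta) * self.omega[np.ix_(g, g)]
        if not self.self_loops:
            np.fill_diagonal(lam, 0.0)
        return lam


def generate_planted(
    model: PlantedModel, seed: int | np.random.Generator | None = None
) -> tuple[WeightedMatrix, np.ndarray]:
    """Draw a weighted matrix from a planted block model.

    Returns the matrix and the planted group labels.  In "poisson" mode the
    upper triangle (and, with self-loops, the diagonal) is drawn
    independently and mirrored, so the result is exactly symmetric.
    """
    lam = model.expected_matrix()
    if model.mode == "expected":
        values = lam
    else:
        rng = np.random.default_rng(seed)
        upper = np.triu(rng.poisson(lam).astype(float), k=0 if model.self_loops else 1)
        values = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diag(upper))
        if values.sum() == 0:  # pathological draw on tiny sparse models
            values = lam
    return (
        WeightedMatrix(
            values, symmetric=True, zero_diagonal=not np.any(np.diag(values))
        ),
        model.labels,
    )


def noisy_ensemble(
    A, relative_noise: float, n: int, seed: int | np.random.Generator | None = None
) -> list[WeightedMatrix]:
    """Multiplicative-noise replicates of A, each rescaled to A's total.

    Each replicate multiplies every (upper-triangle, symmetric) entry by an
    independent Gamma factor of mean 1 and relative standard deviation
    ``relative_noise``, then rescales to the original total weight; the
    ensemble mean converges to A.  Because the layout cross-entropy is
    linear in the matrix entries at fixed total, the optimal representation
    of the ensemble mean is the optimizer of the ensemble-averaged
    objective.
    """
    from .core import as_matrix

    A = as_matrix(A)
    if relative_noise < 0:
        raise ValueError("relative_noise must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    v = A.values
    total = v.sum()
    for _ in range(n):
        if relative_noise == 0:
            out.append(WeightedMatrix(v.copy(), labels=list(A.labels),
                                      symmetric=A.symmetric,
                                      zero_diagonal=A.zero_diagonal))
            continue
        shape = 1.0 / relative_noise**2
        factors = rng.gamma(shape, 1.0 / shape, size=v.shape)
        if A.symmetric:
            factors = np.triu(factors) + np.triu(factors, 1).T
        noisy = v * factors
        noisy *= total / noisy.sum()
        out.append(WeightedMatrix(noisy, labels=list(A.labels),
                                  symmetric=A.symmetric,
                                  zero_diagonal=A.zero_diagonal))
    return out


def ensemble_cross_entropy_gap(replicates, B) -> float:
    """|mean_k H(A_k, B) - H(mean_k A_k, B)|; zero for equal-total replicates."""
    vals = [cross_entropy(A, B) for A in replicates]
    mean_matrix = np.mean([r.values for r in replicates], axis=0)
    return abs(float(np.mean(vals)) - cross_entropy(mean_matrix, B))
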