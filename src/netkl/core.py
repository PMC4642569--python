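"""Information-theoretic quantities for non-negative weighted matrices.

A weighted network is a symmetric non-negative matrix ``A`` whose entries
``a_ij`` are interpreted as unnormalized probabilities of observing the
(i, j) index pair.  All quantities below follow the unnormalized
convention: sums run over the raw entries divided by the total weight
``a_** = sum_ij a_ij``, so matrices never need to be normalized by the
caller and every measure is invariant under a global rescaling of A.

Representation matrices ``B`` (product states, block inflations, Gaussian
overlap matrices) may carry positive diagonal entries even when the input
graph has none; their normalization ``b_**`` always includes every entry of
the matrix.  Entries with ``a_ij = 0`` never contribute to a sum
(``0 ln 0 := 0``), and all logarithms are natural (results in nats).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightedMatrix",
    "InfoSummary",
    "as_matrix",
    "summarize",
    "entropy",
    "mutual_information",
    "product_representation",
    "relative_entropy",
    "cross_entropy",
    "eta",
    "total_variation_check",
    "incidence_to_adjacency",
]


@dataclass
class WeightedMatrix:
    """A non-negative weight matrix with labels and structural flags.

    Parameters
    ----------
    values : ndarray of shape (n, n) or (n, m)
        Non-negative finite weights; need not be normalized.
    labels : list of str, optional
        Node labels; defaults to stringified indices.
    symmetric : bool
        Whether the matrix is (and must remain) exactly symmetric.
    zero_diagonal : bool
        True for simple-graph inputs whose diagonal is structurally zero.
        Representation matrices built by this package (product states,
        inflations, overlap matrices) generally carry a positive diagonal
        and set this flag False.
    """

    values: np.ndarray
    labels: list[str] | None = None
    symmetric: bool = True
    zero_diagonal: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix entries must be finite")
        if np.any(self.values < 0):
            raise ValueError("matrix entries must be non-negative")
        if self.values.sum() <= 0:
            raise ValueError("empty distribution: total weight must be positive")
        if self.symmetric:
            if self.values.shape[0] != self.values.shape[1]:
                raise ValueError("symmetric flag requires a square matrix")
            if not np.array_equal(self.values, self.values.T):
                raise ValueError("matrix is not symmetric")
        if self.zero_diagonal:
            if self.values.shape[0] == self.values.shape[1] and np.any(
                np.diag(self.values) != 0
            ):
                raise ValueError("zero_diagonal flag set but diagonal has weight")
        if self.labels is None:
            self.labels = [str(i) for i in range(self.values.shape[0])]
        elif len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match matrix size")

    # -- convenience views ------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def total(self) -> float:
        """Total weight a_**."""
        return float(self.values.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        """a_i* = sum_j a_ij."""
        return self.values.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.values.sum(axis=0)


@dataclass
class InfoSummary:
    """Entropy/mutual-information summary of a weight matrix (nats)."""

    total: float
    row_marginals: np.ndarray = field(repr=False)
    col_marginals: np.ndarray = field(repr=False)
    entropy: float
    mutual_information: float


def as_matrix(A, **kwargs) -> WeightedMatrix:
    """Coerce an ndarray (or WeightedMatrix) into a WeightedMatrix.

    Symmetry and diagonal flags are inferred from the values when not
    supplied explicitly.
    """
    if isinstance(A, WeightedMatrix):
        return A
    A = np.asarray(A, dtype=float)
    if "symmetric" not in kwargs:
        kwargs["symmetric"] = A.ndim == 2 and A.shape[0] == A.shape[1] and np.array_equal(A, A.T)
    if "zero_diagonal" not in kwargs:
        kwargs["zero_diagonal"] = (
            A.ndim == 2 and A.shape[0] == A.shape[1] and not np.any(np.diag(A))
        )
    return WeightedMatrix(A, **kwargs)


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x ln x with the 0 ln 0 := 0 convention, elementwise."""
    out = np.zeros_like(x, dtype=float)
    mask = x > 0
    out[mask] = x[mask] * np.log(x[mask])
    return out


def summarize(A) -> InfoSummary:
    """Compute totals, marginals, entropy S(A) and mutual information I(A).

    ``S(A) = -sum_ij p_ij ln p_ij`` and
    ``I(A) = sum_ij p_ij ln( a_ij a_** / (a_i* a_*j) )``
    with ``p_ij = a_ij / a_**``; both in nats.
    """
    A = as_matrix(A)
    v = A.values
    total = v.sum()
    if total <= 0:
        raise ValueError("empty distribution")
    r = v.sum(axis=1)
    c = v.sum(axis=0)
    # S = ln a_** - (1/a_**) sum a ln a
    sum_alna = _xlogx(v).sum()
    S = np.log(total) - sum_alna / total
    # I = (1/a_**)[ sum a ln a - sum_i a_i* ln a_i* - sum_j a_*j ln a_*j ] + ln a_**
    I = (sum_alna - _xlogx(r).sum() - _xlogx(c).sum()) / total + np.log(total)
    I = max(I, 0.0)  # clip -0.0 / roundoff on structureless inputs
    return InfoSummary(
        total=float(total),
        row_marginals=r,
        col_marginals=c,
        entropy=float(S),
        mutual_information=float(I),
    )


def entropy(A) -> float:
    """Shannon entropy S(A) of the normalized matrix, in nats."""
    return summarize(A).entropy


def mutual_information(A) -> float:
    """Mutual information I(A) between rows and columns, in nats."""
    return summarize(A).mutual_information


def product_representation(A) -> WeightedMatrix:
    """The product (rank-1) state B0 with b0_ij = a_i* a_*j / a_**.

    B0 is the structureless baseline: D(A‖B0) = I(A).  Its diagonal is
    generally positive even for simple-graph inputs, and counts toward its
    own normalization b_** = a_**.
    """
    A = as_matrix(A)
    s = summarize(A)
    b0 = np.outer(s.row_marginals, s.col_marginals) / s.total
    return WeightedMatrix(
        b0, labels=list(A.labels), symmetric=A.symmetric, zero_diagonal=False
    )


def relative_entropy(A, B) -> float:
    """Kullback–Leibler divergence D(A‖B) in nats.

    ``D = sum_{a_ij>0} (a_ij/a_**) ln[ (a_ij/a_**) / (b_ij/b_**) ]``
    where ``b_**`` sums over every entry of B, including pairs with
    ``a_ij = 0`` and including B's diagonal.  Returns ``inf`` if B lacks
    support somewhere A has weight.
    """
    A = as_matrix(A)
    B = as_matrix(B)
    a = A.values
    b = B.values
    if a.shape != b.shape:
        raise ValueError("A and B must have the same shape")
    atot = a.sum()
    btot = b.sum()
    mask = a > 0
    if np.any(b[mask] <= 0):
        return float("inf")
    p = a[mask] / atot
    q = b[mask] / btot
    return float(np.sum(p * np.log(p / q)))


def cross_entropy(A, B) -> float:
    """Unnormalized cross-entropy H(A, B) = -sum (a_ij/a_**) ln(b_ij/b_**).

    Linear in the entries of A at fixed total weight, which is what makes
    the layout objective robust against noise in A.
    """
    A = as_matrix(A)
    B = as_matrix(B)
    a, b = A.values, B.values
    atot, btot = a.sum(), b.sum()
    mask = a > 0
    if np.any(b[mask] <= 0):
        return float("inf")
    return float(-np.sum((a[mask] / atot) * np.log(b[mask] / btot)))


def eta(A, B=None, *, divergence: float | None = None, norm: str = "mutual") -> float:
    """Quality ratio η = D(A‖B) / I(A) (or D/S(A) with norm="entropy").

    η is 1 at the trivial product-state representation and 0 at a perfect
    one; returned as a plain ratio (user-facing output formats it as a
    percentage).  Pass either ``B`` or a precomputed ``divergence``.
    """
    s = summarize(A)
    if norm == "mutual":
        denom = s.mutual_information
        if denom <= 0:
            raise ValueError("structureless input: I(A) = 0")
    elif norm == "entropy":
        denom = s.entropy
        if denom <= 0:
            raise ValueError("S(A) = 0")
    else:
        raise ValueError("norm must be 'mutual' or 'entropy'")
    if divergence is None:
        if B is None:
            raise ValueError("provide B or divergence")
        divergence = relative_entropy(A, B)
    return float(divergence / denom)


def total_variation_check(A, B) -> tuple[float, float, bool]:
    """Total variation of the normalized matrices and its Pinsker bound.

    Returns ``(TV, sqrt(D/2), TV <= bound)`` with
    ``TV = 0.5 * sum |a_ij/a_** - b_ij/b_**|``; the bound guarantees that a
    low-divergence representation has few spurious connections.
    """
    A = as_matrix(A)
    B = as_matrix(B)
    a, b = A.values, B.values
    tv = 0.5 * float(np.abs(a / a.sum() - b / b.sum()).sum())
    D = relative_entropy(A, B)
    bound = float(np.sqrt(D / 2.0)) if np.isfinite(D) else float("inf")
    # tiny slack for roundoff when TV == bound == 0
    return tv, bound, tv <= bound + 1e-12


def incidence_to_adjacency(
    H, *, normalize_edges: bool = False, prune_isolated: bool = False
) -> WeightedMatrix:
    """Node co-occurrence adjacency A ~ HᵀH from an edge×node incidence matrix.

    ``a_ij = sum_e h_ei h_ej`` (or divided by the edge totals ``h_e*`` when
    ``normalize_edges`` is set).  Hypergraphs and bipartite data are covered
    by general non-negative H.  The result has a non-zero diagonal.

    Nodes with zero incidence weight are an error unless ``prune_isolated``
    removes them.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.size == 0:
        raise ValueError("incidence matrix must be non-empty and 2-D")
    if np.any(H < 0) or not np.all(np.isfinite(H)):
        raise ValueError("incidence entries must be finite and non-negative")
    edge_tot = H.sum(axis=1)
    if np.any(edge_tot == 0):
        raise ValueError("incidence matrix has an all-zero edge row")
    W = H / edge_tot[:, None] if normalize_edges else H
    A = H.T @ W if normalize_edges else H.T @ H
    labels = [str(i) for i in range(H.shape[1])]
    deg = A.sum(axis=1)
    if np.any(deg == 0):
        if not prune_isolated:
            raise ValueError("zero-degree node in incidence input (enable pruning)")
        keep = deg > 0
        A = A[np.ix_(keep, keep)]
        labels = [l for l, k in zip(labels, keep) if k]
    A = 0.5 * (A + A.T)  # exact symmetry against float noise
    return WeightedMatrix(A, labels=labels, symmetric=True, zero_diagonal=False)
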