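"""Degree-preserving agglomerative coarse-graining.

Fusing a group of nodes replaces their rows (and columns) by a common,
degree-proportional profile while every node keeps its original marginal
weight.  The Kullback–Leibler divergence between the input matrix and this
inflated block representation equals exactly the mutual information lost by
the reduction, ``D = I(A) - I(M)``, which makes the greedy merge objective
identical to maximizing the Karrer–Newman degree-corrected block-model
likelihood kernel at each group count.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .core import WeightedMatrix, as_matrix, mutual_information, summarize

__all__ = [
    "Partition",
    "MergeStep",
    "Dendrogram",
    "reduced_matrix",
    "inflate",
    "partition_divergence",
    "delta_divergence",
    "greedy_agglomerate",
    "dcsbm_objective",
    "refine_partition",
    "KLCoarseGraining",
]


def _xlogx(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    np.log(x, out=out, where=x > 0)
    out *= x
    return out


# ---------------------------------------------------------------------------
# partitions and block representations


@dataclass
class Partition:
    """Node-to-group assignment with the group degree totals kappa_r."""

    labels: np.ndarray
    kappa: np.ndarray = field(default=None)

    @classmethod
    def from_labels(cls, labels, A=None) -> "Partition":
        labels = np.asarray(labels)
        _, labels = np.unique(labels, return_inverse=True)
        kappa = None
        if A is not None:
            A = as_matrix(A)
            kappa = np.bincount(labels, weights=A.row_marginals)
            if np.any(kappa <= 0):
                raise ValueError("every group must have positive total degree")
        return cls(labels=labels, kappa=kappa)

    @property
    def n_groups(self) -> int:
        return int(self.labels.max()) + 1


def _labels_of(P) -> np.ndarray:
    if isinstance(P, Partition):
        return P.labels
    labels = np.asarray(P)
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def reduced_matrix(A, partition) -> WeightedMatrix:
    """Sum rows and columns within groups: m_rs = sum_{i in r, j in s} a_ij.

    Within-group blocks land on the diagonal of the reduced matrix, so the
    result generally has positive diagonal entries even for simple-graph
    input; the total weight is preserved.
    """
    A = as_matrix(A)
    g = _labels_of(partition)
    if g.shape[0] != A.n:
        raise ValueError("partition does not cover the matrix")
    G = int(g.max()) + 1
    ind = np.zeros((A.n, G))
    ind[np.arange(A.n), g] = 1.0
    M = ind.T @ A.values @ ind
    M = 0.5 * (M + M.T)
    return WeightedMatrix(M, symmetric=True, zero_diagonal=False)


def inflate(M, partition, degrees) -> WeightedMatrix:
    """Expand a reduced matrix back to full size at fixed node degrees.

    ``b_ij = a_i* a_j* m_{g(i)g(j)} / (kappa_{g(i)} kappa_{g(j)})``, which
    is the unique degree-proportional expansion preserving symmetry and
    every row sum: ``b_i* = a_i*`` exactly and ``b_** = a_**``.  Within a
    group the same formula redistributes the block weight over all pairs
    including the diagonal.
    """
    M = as_matrix(M)
    g = _labels_of(partition)
    degrees = np.asarray(degrees, dtype=float)
    kappa = np.bincount(g, weights=degrees, minlength=M.n)
    if np.any(kappa <= 0):
        raise ValueError("zero total degree in a group")
    ratio = degrees / kappa[g]
    B = np.outer(ratio, ratio) * M.values[np.ix_(g, g)]
    return WeightedMatrix(
        0.5 * (B + B.T), symmetric=True, zero_diagonal=False
    )


def partition_divergence(A, partition, *, route: str = "info") -> float:
    """Information lost by coarse-graining A with a partition, in nats.

    ``route="info"`` evaluates ``I(A) - I(reduced)``; ``route="kl"``
    evaluates ``D(A‖inflate(reduced))`` directly.  The two agree to
    numerical precision.
    """
    from .core import relative_entropy

    A = as_matrix(A)
    if route == "info":
        d = mutual_information(A) - mutual_information(reduced_matrix(A, partition))
        return max(float(d), 0.0)
    if route == "kl":
        M = reduced_matrix(A, partition)
        B = inflate(M, partition, A.row_marginals)
        return relative_entropy(A, B)
    raise ValueError("route must be 'info' or 'kl'")


def dcsbm_objective(A, partition) -> float:
    """Karrer–Newman degree-corrected block-model log-likelihood kernel.

    ``score = sum_rs m_rs ln( m_rs / (kappa_r kappa_s) )``.  At any fixed
    number of groups, ranking partitions by ascending coarse-graining
    divergence is identical to ranking by descending score, through the
    identity ``partition_divergence = I(A) - (score/a_** + ln a_**)``.
    """
    A = as_matrix(A)
    M = reduced_matrix(A, partition).values
    kappa = M.sum(axis=1)
    mask = M > 0
    return float(
        np.sum(M[mask] * (np.log(M[mask]) - np.log(np.outer(kappa, kappa)[mask])))
    )


# ---------------------------------------------------------------------------
# pairwise merge deltas


def delta_divergence(M, r, s, *, total: float | None = None) -> float:
    """Divergence increase from merging groups r and s of a reduced matrix.

    Computed locally from rows r and s: ``Delta D = I(M) - I(M')`` where M'
    merges the two rows and columns.  Always >= 0 (merging never recovers
    information).
    """
    M = as_matrix(M)
    v = M.values
    if r == s:
        raise ValueError("r and s must differ")
    if total is None:
        total = v.sum()
    kappa = v.sum(axis=1)
    row_r, row_s = v[r], v[s]
    merged = row_r + row_s
    off = (
        _xlogx(row_r).sum()
        + _xlogx(row_s).sum()
        - _xlogx(merged).sum()
    )
    # remove the u in {r, s} columns from the off-group sum, handle the
    # 2x2 diagonal block explicitly
    for u in (r, s):
        off -= _xlogx(v[r, u]) + _xlogx(v[s, u]) - _xlogx(v[r, u] + v[s, u])
    mtt = v[r, r] + v[s, s] + 2.0 * v[r, s]
    diag = (
        _xlogx(v[r, r]) + _xlogx(v[s, s]) + 2.0 * _xlogx(v[r, s]) - _xlogx(mtt)
    )
    kap = 2.0 * (
        _xlogx(kappa[r]) + _xlogx(kappa[s]) - _xlogx(kappa[r] + kappa[s])
    )
    return float(max((2.0 * off + diag - kap) / total, 0.0))


def _all_pair_deltas(v: np.ndarray, total: float) -> np.ndarray:
    """Vectorized merge deltas for every group pair of a reduced matrix."""
    G = v.shape[0]
    X = _xlogx(v)
    S1 = X.sum(axis=1)
    # F[r, s] = sum_u xlogx(m_ru + m_su); G^3 broadcast, fine for G <= ~300
    F = _xlogx(v[:, None, :] + v[None, :, :]).sum(axis=-1)
    off = S1[:, None] + S1[None, :] - F
    # subtract the u = r and u = s columns
    diag_X = np.diag(X)
    off -= diag_X[:, None] + X.T - _xlogx(np.diag(v)[:, None] + v.T)
    off -= X + diag_X[None, :] - _xlogx(v + np.diag(v)[None, :])
    mtt = np.diag(v)[:, None] + np.diag(v)[None, :] + 2.0 * v
    blk = diag_X[:, None] + diag_X[None, :] + 2.0 * X - _xlogx(mtt)
    kappa = v.sum(axis=1)
    xk = _xlogx(kappa)
    kap = 2.0 * (xk[:, None] + xk[None, :] - _xlogx(kappa[:, None] + kappa[None, :]))
    deltas = (2.0 * off + blk - kap) / total
    np.fill_diagonal(deltas, np.inf)
    return np.maximum(deltas, 0.0) + np.where(np.isfinite(deltas), 0.0, np.inf)


# ---------------------------------------------------------------------------
# dendrogram


@dataclass
class MergeStep:
    """One fusion: groups (a, b) -> new_id at cumulative divergence height."""

    a: int
    b: int
    new_id: int
    height: float
    delta: float


@dataclass
class Dendrogram:
    """Ordered merge list from N leaves down to one group.

    Group ids follow the scipy convention: leaves are 0..N-1 and the merge
    at step t creates id N+t.  Heights are cumulative divergences (nats)
    and are non-decreasing; the final height equals I(A).
    """

    merges: list[MergeStep]
    n_leaves: int
    leaf_labels: list[str]

    def cut(self, n_groups: int) -> Partition:
        """Partition obtained by undoing the last ``n_groups - 1`` merges."""
        if not 1 <= n_groups <= self.n_leaves:
            raise ValueError("n_groups out of range")
        parent = np.arange(self.n_leaves + len(self.merges))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for step in self.merges[: self.n_leaves - n_groups]:
            parent[find(step.a)] = step.new_id
            parent[find(step.b)] = step.new_id
        roots = [find(i) for i in range(self.n_leaves)]
        _, labels = np.unique(roots, return_inverse=True)
        # renumber by first appearance for determinism
        order = {}
        out = np.empty(self.n_leaves, dtype=int)
        for i, r in enumerate(labels):
            out[i] = order.setdefault(r, len(order))
        return Partition(labels=out)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def to_linkage(self) -> np.ndarray:
        """scipy.cluster.hierarchy linkage array (heights in nats)."""
        counts = {i: 1 for i in range(self.n_leaves)}
        Z = np.zeros((len(self.merges), 4))
        for t, m in enumerate(self.merges):
            counts[m.new_id] = counts[m.a] + counts[m.b]
            Z[t] = [m.a, m.b, m.height, counts[m.new_id]]
        return Z

    def to_table(self) -> str:
        """TSV merge table: step, groupA, groupB, newgroup, height, delta."""
        lines = ["step\tgroupA\tgroupB\tnewgroup\theight_nats\tdelta_nats"]
        for t, m in enumerate(self.merges):
            lines.append(
                f"{t}\t{m.a}\t{m.b}\t{m.new_id}\t{m.height:.9g}\t{m.delta:.9g}"
            )
        return "\n".join(lines) + "\n"

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences (nats)."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        node = {i: self.leaf_labels[i] for i in range(self.n_leaves)}
        for m in self.merges:
            bl_a = m.height - height[m.a]
            bl_b = m.height - height[m.b]
            node[m.new_id] = f"({node[m.a]}:{bl_a:.9g},{node[m.b]}:{bl_b:.9g})"
            height[m.new_id] = m.height
        return node[self.merges[-1].new_id] + ";" if self.merges else node[0] + ";"


# ---------------------------------------------------------------------------
# greedy agglomeration


def _candidate_pairs(v: np.ndarray) -> set[tuple[int, int]]:
    """Connected pairs plus pairs sharing at least one neighbor."""
    adj = v > 0
    two_step = (adj.astype(np.int64) @ adj.astype(np.int64)) > 0
    cand = adj | two_step
    out = set()
    idx = np.argwhere(np.triu(cand, 1))
    for r, s in idx:
        out.add((int(r), int(s)))
    return out


def greedy_agglomerate(
    A,
    *,
    candidates: str = "auto",
    batch_fraction: float | None = None,
    all_pairs_limit: int = 200,
) -> Dendrogram:
    """Greedy pairwise agglomeration into a full dendrogram.

    At every step the pair of current groups whose fusion costs the least
    divergence is merged (ties broken by the lexicographically smallest
    group-id pair).  ``candidates="all"`` evaluates every pair each step
    (exact greedy, the default up to ``all_pairs_limit`` nodes);
    ``candidates="neighbors"`` restricts to connected or
    neighbor-sharing pairs via a lazily invalidated priority queue, which
    approaches quadratic running time on sparse networks.  With
    ``batch_fraction`` set, each round merges the best
    ``ceil(fraction * G)`` disjoint pairs instead of a single one.
    """
    A = as_matrix(A)
    if not A.symmetric:
        raise ValueError("agglomeration requires a symmetric matrix")
    N = A.n
    if candidates == "auto":
        candidates = "all" if N <= all_pairs_limit else "neighbors"
    total = A.total

    # working reduced matrix in a (2N-1) frame; leaves 0..N-1
    size = 2 * N - 1
    M = np.zeros((size, size))
    M[:N, :N] = A.values
    active = list(range(N))
    merges: list[MergeStep] = []
    height = 0.0
    next_id = N

    def merge_pair(r, s, delta):
        nonlocal height, next_id
        t = next_id
        next_id += 1
        act = np.array(active)
        M[t, act] = M[r, act] + M[s, act]
        M[act, t] = M[t, act]
        M[t, t] = M[r, r] + M[s, s] + 2.0 * M[r, s]
        active.remove(r)
        active.remove(s)
        active.append(t)
        height += delta
        merges.append(MergeStep(a=r, b=s, new_id=t, height=height, delta=delta))
        return t

    if candidates == "all" and batch_fraction is None:
        while len(active) > 1:
            act = np.array(sorted(active))
            sub = M[np.ix_(act, act)]
            deltas = _all_pair_deltas(sub, total)
            k = int(np.argmin(deltas))
            i, j = divmod(k, len(act))
            if i > j:
                i, j = j, i
            merge_pair(int(act[i]), int(act[j]), float(deltas[i, j]))
    elif batch_fraction is not None:
        while len(active) > 1:
            act = np.array(sorted(active))
            sub = M[np.ix_(act, act)]
            deltas = _all_pair_deltas(sub, total)
            n_merge = max(1, int(np.ceil(batch_fraction * len(act))))
            order = np.argsort(deltas, axis=None, kind="stable")
            used: set[int] = set()
            chosen = []
            for k in order:
                i, j = divmod(int(k), len(act))
                if i >= j or i in used or j in used:
                    continue
                chosen.append((int(act[i]), int(act[j])))
                used.update((i, j))
                if len(chosen) >= n_merge:
                    break
            for r, s in chosen:
                # recompute the actual delta at merge time for exact heights
                act_now = sorted(active)
                sub_now = M[np.ix_(act_now, act_now)]
                ir, is_ = act_now.index(r), act_now.index(s)
                d = delta_divergence(sub_now, ir, is_, total=total)
                merge_pair(r, s, d)
    else:
        # neighbor-restricted candidates with a lazily invalidated heap
        is_active = np.zeros(size, dtype=bool)
        is_active[:N] = True
        pairs = _candidate_pairs(A.values)
        heap: list[tuple[float, int, int]] = []
        stamp = 0  # global merge counter; entries older than the last merge
        entries: list[tuple[float, int, int, int]] = []
        act_arr = np.array(active)

        def pair_delta(r, s):
            act_now = sorted(i for i in active)
            sub = M[np.ix_(act_now, act_now)]
            return delta_divergence(sub, act_now.index(r), act_now.index(s), total=total)

        for r, s in sorted(pairs):
            heapq.heappush(heap, (pair_delta(r, s), stamp, r, s))
        while len(active) > 1:
            while heap:
                d, st, r, s = heapq.heappop(heap)
                if not (is_active[r] and is_active[s]):
                    continue
                if st < stamp:
                    # stale: third-party merges may have shifted the delta
                    heapq.heappush(heap, (pair_delta(r, s), stamp, r, s))
                    continue
                break
            else:
                # disconnected remainder: fall back to the cheapest pair
                act_now = sorted(active)
                sub = M[np.ix_(act_now, act_now)]
                deltas = _all_pair_deltas(sub, total)
                k = int(np.argmin(deltas))
                i, j = divmod(k, len(act_now))
                r, s, d = act_now[min(i, j)], act_now[max(i, j)], float(deltas[min(i, j), max(i, j)])
            t = merge_pair(r, s, d)
            is_active[r] = is_active[s] = False
            is_active[t] = True
            stamp += 1
            neigh = [u for u in active if u != t and M[t, u] > 0]
            # distance-2 closure around the new group
            two = set()
            for u in neigh:
                two.update(w for w in active if w not in (t, u) and M[u, w] > 0)
            for u in sorted(set(neigh) | two):
                heapq.heappush(heap, (pair_delta(t, u), stamp, min(t, u), max(t, u)))
    return Dendrogram(merges=merges, n_leaves=N, leaf_labels=list(A.labels))


# ---------------------------------------------------------------------------
# fixed-G refinement


def refine_partition(A, labels, *, max_sweeps: int = 20) -> np.ndarray:
    """Kernighan–Lin-style single-node reassignment sweeps.

    Greedily moves nodes between the existing groups whenever the move
    lowers the coarse-graining divergence (equivalently, raises the
    block-model score); stops at a sweep with no accepted move.
    """
    A = as_matrix(A)
    g = _labels_of(labels).copy()
    G = int(g.max()) + 1
    if G == 1:
        return g
    v = A.values
    best = -partition_divergence(A, g)
    for _ in range(max_sweeps):
        improved = False
        for i in range(A.n):
            current = g[i]
            if np.sum(g == current) == 1:
                continue  # keep every group non-empty
            best_move, best_val = current, best
            for s in range(G):
                if s == current:
                    continue
                g[i] = s
                val = -partition_divergence(A, g)
                if val > best_val + 1e-13:
                    best_move, best_val = s, val
            g[i] = best_move
            if best_move != current:
                best = best_val
                improved = True
        if not improved:
            break
    _, g = np.unique(g, return_inverse=True)
    return g


# ---------------------------------------------------------------------------
# estimator


class KLCoarseGraining(ClusterMixin, BaseEstimator):
    """Agglomerative clustering by relative-entropy (lost-information) cost.

    Builds the full degree-preserving merge dendrogram of a symmetric
    non-negative affinity matrix and optionally cuts it at ``n_clusters``.
    Equivalent, at fixed group count, to maximizing the degree-corrected
    stochastic block-model likelihood kernel.

    Parameters
    ----------
    n_clusters : int or None
        Where to cut the dendrogram for ``labels_``; None keeps only the
        dendrogram.
    candidates : {"auto", "all", "neighbors"}
        Merge-candidate policy; "all" is exact greedy, "neighbors"
        restricts to graph-distance <= 2 pairs (near-quadratic time).
    batch_fraction : float or None
        Merge the best ``ceil(fraction * G)`` disjoint pairs per round
        instead of one pair.
    refine : bool
        Run node-reassignment sweeps on the cut partition.

    Attributes
    ----------
    dendrogram_ : Dendrogram
    heights_ : ndarray of cumulative divergences (nats); last = I(A).
    labels_ : group labels (only when ``n_clusters`` is set).
    divergence_ : partition divergence of ``labels_`` in nats.
    mutual_information_ : I(A) of the input, nats.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        *,
        candidates: str = "auto",
        batch_fraction: float | None = None,
        refine: bool = False,
    ):
        self.n_clusters = n_clusters
        self.candidates = candidates
        self.batch_fraction = batch_fraction
        self.refine = refine

    def fit(self, X, y=None):
        A = as_matrix(X)
        self.n_leaves_ = A.n
        self.mutual_information_ = mutual_information(A)
        self.dendrogram_ = greedy_agglomerate(
            A, candidates=self.candidates, batch_fraction=self.batch_fraction
        )
        self.heights_ = self.dendrogram_.heights
        if self.n_clusters is not None:
            labels = self.dendrogram_.cut(self.n_clusters).labels
            if self.refine:
                labels = refine_partition(A, labels)
            self.labels_ = labels
            self.divergence_ = partition_divergence(A, labels)
        return self

    def fit_predict(self, X, y=None):
        if self.n_clusters is None:
            raise ValueError("fit_predict requires n_clusters")
        return self.fit(X).labels_
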