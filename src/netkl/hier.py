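"""Hierarchical layout: coarse-graining-guided top-down visualization.

The greedy merge dendrogram is replayed in reverse: the layout starts from a
single Gaussian holding the whole network, and fusion steps are undone one
batch at a time.  At every intermediate scale the current groups are laid
out as nodes of the reduced matrix (norms pinned proportionally to the
group degree totals), so the large-scale arrangement is settled before the
fine structure is released.  At a scale with G groups the coarse-graining
divergence is a hard lower bound for the achievable layout divergence: the
full-size representation induced by group Gaussians satisfies

    D(A‖B_full) = D_coarse(G) + D(M_G‖B_G) >= D_coarse(G),

where M_G is the reduced matrix and B_G the group overlap matrix.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator

from .coarse import Dendrogram, MergeStep, greedy_agglomerate
from .core import as_matrix, summarize
from .layout import Embedding, LayoutResult, _LayoutState, optimize_layout

__all__ = ["expand_step", "hierarchical_layout", "HierarchicalEmbedding"]


def _write_snapshot(snapshot_dir, n_groups, M, emb, group_ids) -> None:
    """Per-stage coordinates and reduced-matrix TSVs."""
    import os

    from .core import WeightedMatrix
    from .io import write_coordinates, write_matrix

    os.makedirs(snapshot_dir, exist_ok=True)
    labels = [f"g{gid}" for gid in group_ids]
    write_coordinates(
        emb, os.path.join(snapshot_dir, f"coordinates_{n_groups:04d}.tsv"),
        labels=labels,
    )
    write_matrix(
        WeightedMatrix(M, labels=labels, symmetric=True, zero_diagonal=False),
        os.path.join(snapshot_dir, f"reduced_{n_groups:04d}.tsv"),
    )


def expand_step(
    emb: Embedding,
    group_ids: list[int],
    merge: MergeStep,
    child_degrees: tuple[float, float],
    jitter: float = 0.1,
    seed=None,
) -> tuple[Embedding, list[int]]:
    """Undo one fusion: replace the merged group by its two children.

    The children inherit the parent's width and position, displaced by
    ``±jitter * sigma_parent`` along a seeded random unit vector, and split
    the parent's norm in proportion to their degree totals.  At jitter = 0
    the children exactly superpose the parent, so the divergence is
    unchanged (proportional rows are represented optimally by a shared
    distribution).
    """
    if merge.new_id not in group_ids:
        raise ValueError("merge product not present in the embedding")
    idx = group_ids.index(merge.new_id)
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(emb.d)
    norm = np.linalg.norm(u)
    u = u / norm if norm > 0 else np.eye(emb.d)[0]
    x_p = emb.positions[idx]
    s_p = emb.sigma[idx]
    h_p = emb.h[idx]
    ka, kb = child_degrees
    offset = jitter * s_p * u
    keep = [i for i in range(emb.n) if i != idx]
    positions = np.vstack(
        [emb.positions[keep], x_p + offset, x_p - offset]
    )
    sigma = np.concatenate([emb.sigma[keep], [s_p, s_p]])
    h = np.concatenate(
        [emb.h[keep], [h_p * ka / (ka + kb), h_p * kb / (ka + kb)]]
    )
    new_ids = [group_ids[i] for i in keep] + [merge.a, merge.b]
    return Embedding(emb.d, positions, sigma, h), new_ids


def hierarchical_layout(
    A,
    d: int = 2,
    *,
    expand_batch: int | None = None,
    optimize_iters: int | None = None,
    jitter: float = 0.1,
    seed=None,
    freeze_h: bool = True,
    fine_tune: bool = False,
    max_iter: int | None = None,
    dendrogram: Dendrogram | None = None,
    snapshot_dir: str | None = None,
) -> LayoutResult:
    """Full top-down hierarchical layout of a symmetric weighted network.

    Builds (or reuses) the merge dendrogram, then alternates
    ``expand_batch`` undo steps with layout optimization of the current
    reduced matrix.  Group norms stay proportional to the group degree
    totals throughout; ``fine_tune`` additionally releases widths and norms
    in the final full-size stage.  Returns the final embedding together
    with a per-stage trace of (n_groups, layout divergence, coarse-graining
    divergence).
    """
    A = as_matrix(A)
    N = A.n
    info = summarize(A)
    if info.mutual_information <= 1e-14:
        emb = Embedding(d, np.zeros((N, d)), np.ones(N), A.row_marginals / A.total)
        return LayoutResult(emb, 0.0, 0.0, 0, "rank-1 input", [(1, 0.0, 0.0)])
    if dendrogram is None:
        dendrogram = greedy_agglomerate(A)
    if expand_batch is None:
        expand_batch = 1 if N <= 100 else max(1, int(math.ceil(0.05 * N)))
    ss = np.random.SeedSequence(seed)

    # (2N-1)-frame reduced matrix bookkeeping, scipy-style ids
    size = 2 * N - 1
    Mbig = np.zeros((size, size))
    Mbig[:N, :N] = A.values
    for m in dendrogram.merges:
        Mbig[m.new_id, : m.new_id] = Mbig[m.a, : m.new_id] + Mbig[m.b, : m.new_id]
        Mbig[: m.new_id, m.new_id] = Mbig[m.new_id, : m.new_id]
        Mbig[m.new_id, m.new_id] = (
            Mbig[m.a, m.a] + Mbig[m.b, m.b] + 2.0 * Mbig[m.a, m.b]
        )
    degrees = Mbig.sum(axis=1) - np.diag(Mbig)  # kappa per frame id
    # within-frame degree: row sum of its own scale; recompute properly below
    kappa = np.zeros(size)
    kappa[:N] = A.values.sum(axis=1)
    for m in dendrogram.merges:
        kappa[m.new_id] = kappa[m.a] + kappa[m.b]

    atot = A.total
    root = dendrogram.merges[-1].new_id
    group_ids = [root]
    emb = Embedding(d, np.zeros((1, d)), np.ones(1), np.ones(1))
    stage_trace: list[tuple[int, float, float]] = []
    total_iters = 0
    pending = list(reversed(dendrogram.merges))

    def coarse_D(n_groups: int) -> float:
        if n_groups >= N:
            return 0.0
        return dendrogram.merges[N - n_groups - 1].height

    def stage_optimize(final: bool) -> None:
        nonlocal emb, total_iters
        ids = list(group_ids)
        M = Mbig[np.ix_(ids, ids)]
        # pin norms to the group degree totals at this scale
        emb.h[:] = kappa[ids] / atot
        G = len(ids)
        iters = optimize_iters if optimize_iters is not None else 60 * G
        if final and max_iter is not None:
            iters = max_iter
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        res = optimize_layout(
            M,
            d,
            init=emb,
            seed=sub_seed,
            max_iter=iters,
            freeze_h=True if not final else freeze_h,
            freeze_sigma=False,
            fine_tune=fine_tune if final else False,
        )
        emb = res.embedding
        total_iters += res.n_iter
        cD = coarse_D(G)
        layout_D = cD + res.divergence  # induced full-size divergence
        slack = 1e-9 * max(1.0, abs(cD))
        if layout_D < cD - slack:
            raise RuntimeError(
                "scale-bound violation: layout divergence fell below the "
                "coarse-graining lower bound"
            )
        stage_trace.append((G, layout_D, cD))
        if snapshot_dir is not None:
            _write_snapshot(snapshot_dir, G, M, emb, ids)

    stage_optimize(final=(len(pending) == 0))
    while pending:
        for _ in range(min(expand_batch, len(pending))):
            merge = pending.pop(0)
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            emb, group_ids = expand_step(
                emb,
                group_ids,
                merge,
                (kappa[merge.a], kappa[merge.b]),
                jitter=jitter,
                seed=sub_seed,
            )
        stage_optimize(final=(len(pending) == 0))

    # reorder rows into leaf index order
    order = np.argsort(group_ids)
    final_emb = Embedding(
        d,
        emb.positions[order],
        emb.sigma[order],
        emb.h[order],
        freeze_h=freeze_h,
    )
    state = _LayoutState(A, final_emb)
    D = state.D
    return LayoutResult(
        final_emb,
        float(D),
        float(D / info.mutual_information),
        total_iters,
        "hierarchical",
        stage_trace,
    )


class HierarchicalEmbedding(BaseEstimator):
    """Coarse-graining-guided hierarchical Gaussian layout estimator.

    Like :class:`~netkl.layout.GaussianEmbedding` but the optimization is
    driven top-down along the merge dendrogram, which settles the
    large-scale arrangement first and in practice reaches lower divergence
    than cold starts.

    Attributes include the stage trace ``stage_trace_`` of
    (n_groups, layout D, coarse-graining D) triples; the layout value never
    falls below the coarse-graining lower bound at any scale.
    """

    def __init__(
        self,
        n_components: int = 2,
        *,
        expand_batch: int | None = None,
        optimize_iters: int | None = None,
        jitter: float = 0.1,
        freeze_h: bool = True,
        fine_tune: bool = False,
        max_iter: int | None = None,
        random_state=None,
    ):
        self.n_components = n_components
        self.expand_batch = expand_batch
        self.optimize_iters = optimize_iters
        self.jitter = jitter
        self.freeze_h = freeze_h
        self.fine_tune = fine_tune
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        A = as_matrix(X)
        result = hierarchical_layout(
            A,
            self.n_components,
            expand_batch=self.expand_batch,
            optimize_iters=self.optimize_iters,
            jitter=self.jitter,
            seed=self.random_state,
            freeze_h=self.freeze_h,
            fine_tune=self.fine_tune,
            max_iter=self.max_iter,
        )
        self.result_ = result
        self.embedding_ = result.embedding.positions
        self.sigma_ = result.embedding.sigma
        self.h_ = result.embedding.h
        self.divergence_ = result.divergence
        self.eta_ = result.eta
        self.n_iter_ = result.n_iter
        self.stage_trace_ = result.stage_trace
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_
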