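"""Gaussian-node network layout by relative-entropy minimization.

Each node i is a d-dimensional isotropic Gaussian with position ``x_i``,
width ``sigma_i`` and norm ``h_i`` (the distribution integrates to h_i).
The representation matrix entry is the overlap integral

    b_ij = h_i h_j [2 pi (sigma_i^2 + sigma_j^2)]^(-d/2)
           exp( -|x_i - x_j|^2 / (2 (sigma_i^2 + sigma_j^2)) ),

and the layout quality is D(A‖B).  Minimizing D acts as a force-directed
scheme: wherever the normalized overlap b_ij/b_** falls short of the
normalized edge weight a_ij/a_** the pair attracts, the opposite mismatch
repels, and unconnected pairs only repel (they enter D solely through the
b_** normalization, so B never needs to be stored more densely than A).

Optimization follows a Kamada–Kawai-style scheme: repeatedly pick the node
with the largest position-gradient norm and move it by a damped Newton step
on its own d x d Hessian (backtracking gradient descent when the Newton
step fails), interleaving full sweeps with one-dimensional log-space
updates of the widths and norms unless frozen.  Steps are only accepted
when D decreases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .core import WeightedMatrix, as_matrix, relative_entropy, summarize

__all__ = [
    "Embedding",
    "LayoutResult",
    "overlap",
    "disc_overlap",
    "disc_layout_objective",
    "optimize_disc_layout",
    "overlap_matrix",
    "layout_objective",
    "gradient",
    "init_product_state",
    "optimize_layout",
    "ordering_from_embedding",
    "GaussianEmbedding",
]


@dataclass
class Embedding:
    """Positions, widths and norms of the per-node Gaussians."""

    d: int
    positions: np.ndarray  # (n, d)
    sigma: np.ndarray  # (n,)
    h: np.ndarray  # (n,)
    freeze_h: bool = False
    freeze_sigma: bool = False

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.positions.shape[1] != self.d:
            raise ValueError("positions do not match dimension d")
        if np.any(self.sigma <= 0) or np.any(self.h <= 0):
            raise ValueError("sigma and h must be positive")
        if not (
            np.all(np.isfinite(self.positions))
            and np.all(np.isfinite(self.sigma))
            and np.all(np.isfinite(self.h))
        ):
            raise ValueError("embedding parameters must be finite")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Embedding":
        return Embedding(
            self.d,
            self.positions.copy(),
            self.sigma.copy(),
            self.h.copy(),
            self.freeze_h,
            self.freeze_sigma,
        )


@dataclass
class LayoutResult:
    embedding: Embedding
    divergence: float
    eta: float
    n_iter: int
    converged: str
    stage_trace: list = field(default_factory=list)


def overlap(emb: Embedding, i: int, j: int) -> float:
    """Closed-form Gaussian product integral b_ij = ∫ rho_i rho_j dx."""
    s2 = emb.sigma[i] ** 2 + emb.sigma[j] ** 2
    r2 = float(np.sum((emb.positions[i] - emb.positions[j]) ** 2))
    return float(
        emb.h[i]
        * emb.h[j]
        * (2.0 * math.pi * s2) ** (-emb.d / 2.0)
        * math.exp(-r2 / (2.0 * s2))
    )


def disc_overlap(emb: Embedding, i: int, j: int) -> float:
    """Overlap of two homogeneous discs (d = 2 only): lens area kernel.

    rho_i is uniform with mass h_i on a disc of radius sigma_i; the overlap
    is h_i h_j * lens_area / (pi^2 sigma_i^2 sigma_j^2).  Non-differentiable
    at tangency; optimized by coordinate search rather than Newton steps.
    """
    if emb.d != 2:
        raise ValueError("the disc kernel is defined for d = 2")
    R, r = max(emb.sigma[i], emb.sigma[j]), min(emb.sigma[i], emb.sigma[j])
    dist = float(np.linalg.norm(emb.positions[i] - emb.positions[j]))
    if dist >= R + r:
        area = 0.0
    elif dist <= R - r:
        area = math.pi * r**2
    else:
        d2 = dist**2
        a1 = r**2 * math.acos((d2 + r**2 - R**2) / (2 * dist * r))
        a2 = R**2 * math.acos((d2 + R**2 - r**2) / (2 * dist * R))
        a3 = 0.5 * math.sqrt(
            max((-dist + r + R) * (dist + r - R) * (dist - r + R) * (dist + r + R), 0.0)
        )
        area = a1 + a2 - a3
    return float(
        emb.h[i] * emb.h[j] * area / (math.pi**2 * emb.sigma[i] ** 2 * emb.sigma[j] ** 2)
    )


def _log_overlap_full(emb: Embedding) -> np.ndarray:
    """ln b_ij for all pairs including the self-overlap diagonal."""
    s2 = emb.sigma[:, None] ** 2 + emb.sigma[None, :] ** 2
    diff = emb.positions[:, None, :] - emb.positions[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    lnh = np.log(emb.h)
    return (
        lnh[:, None]
        + lnh[None, :]
        - (emb.d / 2.0) * np.log(2.0 * math.pi * s2)
        - r2 / (2.0 * s2)
    )


def overlap_matrix(
    emb: Embedding, support=None, *, include_self: bool = False
) -> tuple[np.ndarray, float]:
    """Overlap matrix restricted to a support mask, and the exact b_**.

    ``b_**`` is summed over every admissible pair (a full N x N pass)
    regardless of which entries are materialized, so a representation can
    stay as sparse as A itself.  For simple-graph inputs the self-overlaps
    b_ii are not part of the representation and are excluded from b_**;
    ``include_self`` keeps them, which is the convention for inputs with
    weight on the diagonal (incidence-derived or coarse-grained matrices).
    """
    B = np.exp(_log_overlap_full(emb))
    btot = float(B.sum()) if include_self else float(B.sum() - np.trace(B))
    if support is not None:
        B = np.where(np.asarray(support, dtype=bool), B, 0.0)
    return B, btot


def disc_layout_objective(A, emb: Embedding) -> float:
    """D(A‖B) for the homogeneous-disc kernel (d = 2); may be infinite
    when connected discs do not overlap."""
    A = as_matrix(A)
    n = emb.n
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            B[i, j] = B[j, i] = disc_overlap(emb, i, j)
    if B.sum() == 0:
        return math.inf
    from .core import relative_entropy

    return relative_entropy(A, B)


def optimize_disc_layout(
    A,
    emb: Embedding,
    *,
    n_rounds: int = 40,
    initial_step: float = 0.5,
    shrink: float = 0.7,
) -> tuple[Embedding, float]:
    """Greedy coordinate search for the non-differentiable disc kernel.

    Axis-aligned position moves (and multiplicative width moves) are tried
    per node with a shrinking step schedule; a move is kept only if it
    lowers D.  Coarse but adequate for the small demonstrations the kernel
    is meant for; Newton steps do not apply at the kernel's kinks.
    """
    A = as_matrix(A)
    emb = emb.copy()
    best = disc_layout_objective(A, emb)
    step = initial_step
    for _ in range(n_rounds):
        improved = False
        for k in range(emb.n):
            for delta in (
                np.array([step, 0.0]),
                np.array([-step, 0.0]),
                np.array([0.0, step]),
                np.array([0.0, -step]),
            ):
                emb.positions[k] += delta
                D = disc_layout_objective(A, emb)
                if D < best - 1e-15:
                    best = D
                    improved = True
                else:
                    emb.positions[k] -= delta
            for factor in (1.0 + step, 1.0 / (1.0 + step)):
                old = emb.sigma[k]
                emb.sigma[k] = old * factor
                D = disc_layout_objective(A, emb)
                if D < best - 1e-15:
                    best = D
                    improved = True
                else:
                    emb.sigma[k] = old
        if not improved:
            step *= shrink
            if step < 1e-6:
                break
    return emb, float(best)


# ---------------------------------------------------------------------------
# incremental objective state


class _LayoutState:
    """Dense objective bookkeeping with O(n) single-node updates.

    Maintains lnB, B, the normalization b_** and the cross term
    sum_ij p_ij ln b_ij, each refreshed incrementally when one node's
    parameters change (a node only touches its own row and column).
    """

    def __init__(self, A: WeightedMatrix, emb: Embedding):
        self.A = A
        self.emb = emb
        # self-overlaps belong to the representation only when the input
        # itself carries diagonal weight (incidence-derived / coarse-grained)
        self.include_self = not A.zero_diagonal
        v = A.values
        self.atot = v.sum()
        self.P = v / self.atot
        mask = self.P > 0
        self.plogp = float(np.sum(self.P[mask] * np.log(self.P[mask])))
        self._full_refresh()

    def _full_refresh(self):
        self.lnB = _log_overlap_full(self.emb)
        # center on the largest admissible log-overlap so exp() never
        # underflows globally (D only depends on lnB - ln b_**)
        if self.include_self:
            self.offset = float(self.lnB.max())
        else:
            off = self.lnB.copy()
            np.fill_diagonal(off, -np.inf)
            self.offset = float(off.max())
        if not np.isfinite(self.offset):
            self.offset = 0.0
        self.B = np.exp(self.lnB - self.offset)
        if not self.include_self:
            # excluded self-overlaps can dwarf the admissible mass (tiny
            # sigma); keep them out of B entirely so sums never cancel
            np.fill_diagonal(self.B, 0.0)
        self.btot = float(self.B.sum())
        self.cross = float(np.sum(self.P * self.lnB))

    @property
    def D(self) -> float:
        if self.btot <= 0 or not np.isfinite(self.btot):
            return math.inf
        return self.plogp - self.cross + math.log(self.btot) + self.offset

    # -- single-node row computation ------------------------------------
    def _row(self, k, x_k, sigma_k, h_k):
        emb = self.emb
        s2 = emb.sigma**2 + sigma_k**2
        s2[k] = 2.0 * sigma_k**2
        diff = emb.positions - x_k
        diff[k] = 0.0
        r2 = np.einsum("ij,ij->i", diff, diff)
        lnrow = (
            math.log(h_k)
            + np.log(emb.h)
            - (emb.d / 2.0) * np.log(2.0 * math.pi * s2)
            - r2 / (2.0 * s2)
        )
        lnrow[k] = 2.0 * math.log(h_k) - (emb.d / 2.0) * math.log(
            4.0 * math.pi * sigma_k**2
        )
        return lnrow

    def trial(self, k, x_k=None, sigma_k=None, h_k=None):
        """Objective value if node k moved to the given parameters."""
        emb = self.emb
        x_k = emb.positions[k] if x_k is None else x_k
        sigma_k = emb.sigma[k] if sigma_k is None else sigma_k
        h_k = emb.h[k] if h_k is None else h_k
        lnrow = self._row(k, x_k, sigma_k, h_k)
        row = np.exp(lnrow - self.offset)
        if not self.include_self:
            row[k] = 0.0
        old_row = self.B[k]
        ddiag = row[k] - old_row[k]
        btot = self.btot + 2.0 * (row.sum() - old_row.sum()) - ddiag
        dln = lnrow - self.lnB[k]
        cross = self.cross + 2.0 * float(np.dot(self.P[k], dln)) - float(
            self.P[k, k] * dln[k]
        )
        if btot <= 0 or not np.isfinite(btot):
            # catastrophic cancellation in the incremental total: the move
            # shrank the overlap mass below float resolution; reject it
            return math.inf, lnrow, row, btot, cross
        D = self.plogp - cross + math.log(btot) + self.offset
        return D, lnrow, row, btot, cross

    def commit(self, k, x_k, sigma_k, h_k, lnrow, row, btot, cross):
        emb = self.emb
        emb.positions[k] = x_k
        emb.sigma[k] = sigma_k
        emb.h[k] = h_k
        self.lnB[k] = lnrow
        self.lnB[:, k] = lnrow
        self.B[k] = row
        self.B[:, k] = row
        self.btot = btot
        self.cross = cross
        # incremental totals accumulate roundoff; resync periodically and
        # whenever the centered total leaves its safe dynamic range
        self._commits = getattr(self, "_commits", 0) + 1
        # a refresh re-centers so btot >= 1; decay far below that signals
        # heavy cancellation in the running sums
        if (
            self._commits % 1000 == 0
            or self.btot < 1e-6
            or self.btot > 1e12
            or not np.isfinite(self.btot)
        ):
            self._full_refresh()

    # -- derivatives ------------------------------------------------------
    def all_position_gradients(self) -> np.ndarray:
        emb = self.emb
        Q = self.B / self.btot
        s2 = emb.sigma[:, None] ** 2 + emb.sigma[None, :] ** 2
        W = 2.0 * (self.P - Q) / s2
        np.fill_diagonal(W, 0.0)
        return W.sum(axis=1)[:, None] * emb.positions - W @ emb.positions

    def position_gradient_hessian(self, k):
        emb = self.emb
        q = self.B[k] / self.btot
        p = self.P[k]
        c = 1.0 / (emb.sigma**2 + emb.sigma[k] ** 2)
        diff = emb.positions[k] - emb.positions  # r_j = x_k - x_j
        w = (p - q) * c
        w[k] = 0.0
        grad = 2.0 * (w @ diff)
        qc = q * c
        qc[k] = 0.0
        pc = p * c
        pc[k] = 0.0
        d = emb.d
        eye = np.eye(d)
        H = 2.0 * (pc.sum() - qc.sum()) * eye
        scaled = (qc * c)[:, None] * diff
        H += 2.0 * diff.T @ scaled
        u = qc @ diff
        H -= 4.0 * np.outer(u, u)
        return grad, H

    def scale_gradients(self, k):
        """(dD/d ln sigma_k, dD/d ln h_k), self-overlap terms included."""
        emb = self.emb
        q = self.B[k] / self.btot
        p = self.P[k]
        s2 = emb.sigma**2 + emb.sigma[k] ** 2
        diff = emb.positions[k] - emb.positions
        r2 = np.einsum("ij,ij->i", diff, diff)
        dln_sigma = (emb.sigma[k] ** 2 / s2) * (r2 / s2 - emb.d)
        qmp = q - p
        if self.include_self:
            dln_sigma[k] = -emb.d
            g_sigma = 2.0 * float(np.dot(qmp, dln_sigma)) - float(
                qmp[k] * dln_sigma[k]
            )
            # d ln b_kj / d ln h_k = 1 off-diagonal, 2 on the diagonal
            g_h = 2.0 * float(qmp.sum())
        else:
            dln_sigma[k] = 0.0
            g_sigma = 2.0 * float(np.dot(qmp, dln_sigma))
            g_h = 2.0 * float(qmp.sum() - qmp[k])
        return g_sigma, g_h


# ---------------------------------------------------------------------------
# public objective / gradient wrappers


def layout_objective(A, emb: Embedding) -> tuple[float, float]:
    """(D, eta) of a Gaussian embedding; always finite."""
    A = as_matrix(A)
    state = _LayoutState(A, emb)
    D = state.D
    I = summarize(A).mutual_information
    return float(D), float(D / I) if I > 0 else 0.0


def gradient(A, emb: Embedding, k: int):
    """Analytic derivatives for node k: (dD/dx_k, dD/dln sigma_k, dD/dln h_k)."""
    A = as_matrix(A)
    state = _LayoutState(A, emb)
    g, _ = state.position_gradient_hessian(k)
    gs, gh = state.scale_gradients(k)
    return g, gs, gh


def init_product_state(A, d: int, seed=None, jitter: float = 1e-6) -> Embedding:
    """All nodes coincident with h_i ∝ a_i*: the product-state start.

    A seeded jitter of relative magnitude ``jitter`` breaks the exact
    permutation degeneracy; at jitter = 0 the representation is exactly B0
    and D = I(A) whatever distribution shape is used.
    """
    A = as_matrix(A)
    rng = np.random.default_rng(seed)
    sigma0 = 1.0
    n = A.n
    positions = jitter * sigma0 * rng.standard_normal((n, d))
    h = A.row_marginals / A.total
    return Embedding(d, positions, np.full(n, sigma0), h.copy())


def ordering_from_embedding(emb: Embedding, tie_order=None) -> np.ndarray:
    """Node permutation from a one-dimensional layout.

    Sorts by coordinate; exact ties fall back to ``tie_order`` (for
    example a dendrogram leaf order) or the input index.  The global
    reflection is canonicalized so the first node's index precedes the
    last node's.
    """
    if emb.d != 1:
        raise ValueError("ordering requires a 1-D embedding")
    x = emb.positions[:, 0]
    tie = np.asarray(tie_order) if tie_order is not None else np.arange(emb.n)
    perm = np.lexsort((tie, x))
    if perm[0] > perm[-1]:
        perm = perm[::-1]
    return perm


# ---------------------------------------------------------------------------
# optimizer


def _update_position(state: _LayoutState, k: int, sigma_min: float) -> bool:
    """Newton (or backtracking gradient) step on node k's position."""
    emb = state.emb
    grad, H = state.position_gradient_hessian(k)
    gnorm = float(np.linalg.norm(grad))
    if gnorm == 0.0:
        return False
    D0 = state.D
    step = None
    try:
        L = np.linalg.cholesky(H)
        step = -np.linalg.solve(H, grad)
    except np.linalg.LinAlgError:
        step = None
    candidates = []
    if step is not None and np.all(np.isfinite(step)):
        candidates.append(step)
    # gradient direction with a curvature-informed initial scale
    scale = np.trace(H) / emb.d if np.trace(H) > 0 else None
    alpha = 1.0 / scale if scale else 1.0 / (gnorm + 1.0)
    candidates.append(-alpha * grad)
    for base in candidates:
        s = base
        for _ in range(30):
            trial_x = emb.positions[k] + s
            D, lnrow, row, btot, cross = state.trial(k, x_k=trial_x)
            if D < D0 - 1e-15:
                state.commit(k, trial_x, emb.sigma[k], emb.h[k], lnrow, row, btot, cross)
                return True
            s = 0.5 * s
    return False


def _update_scalar(state: _LayoutState, k: int, which: str, sigma_min: float) -> bool:
    """One-dimensional Newton step in log-space on sigma_k or h_k."""
    emb = state.emb
    gs, gh = state.scale_gradients(k)
    g = gs if which == "sigma" else gh
    if g == 0.0:
        return False
    D0 = state.D
    # curvature by symmetric difference of the analytic first derivative
    eps = 1e-4
    saved = emb.sigma[k] if which == "sigma" else emb.h[k]

    def grad_at(logval):
        if which == "sigma":
            emb.sigma[k] = math.exp(logval)
        else:
            emb.h[k] = math.exp(logval)
        lnrow = state._row(k, emb.positions[k], emb.sigma[k], emb.h[k])
        row = np.exp(lnrow - state.offset)
        if not state.include_self:
            row[k] = 0.0
        # local gradient with the trial row in place of the stored one
        old_lnB_k, old_B_k = state.lnB[k].copy(), state.B[k].copy()
        old_btot, old_cross = state.btot, state.cross
        state.lnB[k] = lnrow
        state.lnB[:, k] = lnrow
        state.B[k] = row
        state.B[:, k] = row
        ddiag = row[k] - old_B_k[k]
        state.btot = old_btot + 2.0 * (row.sum() - old_B_k.sum()) - ddiag
        if state.btot <= 0 or not np.isfinite(state.btot):
            state.btot = max(float(state.B.sum()), 1e-300)
        gs2, gh2 = state.scale_gradients(k)
        state.lnB[k] = old_lnB_k
        state.lnB[:, k] = old_lnB_k
        state.B[k] = old_B_k
        state.B[:, k] = old_B_k
        state.btot = old_btot
        state.cross = old_cross
        if which == "sigma":
            emb.sigma[k] = saved
        else:
            emb.h[k] = saved
        return gs2 if which == "sigma" else gh2

    logv = math.log(saved)
    curv = (grad_at(logv + eps) - grad_at(logv - eps)) / (2.0 * eps)
    if curv > 0 and np.isfinite(curv):
        step = -g / curv
    else:
        step = -math.copysign(0.2, g)
    step = float(np.clip(step, -2.0, 2.0))
    for _ in range(25):
        newval = math.exp(logv + step)
        if which == "sigma":
            newval = max(newval, sigma_min)
            D, lnrow, row, btot, cross = state.trial(k, sigma_k=newval)
            if D < D0 - 1e-15:
                state.commit(
                    k, emb.positions[k], newval, emb.h[k], lnrow, row, btot, cross
                )
                return True
        else:
            D, lnrow, row, btot, cross = state.trial(k, h_k=newval)
            if D < D0 - 1e-15:
                state.commit(
                    k, emb.positions[k], emb.sigma[k], newval, lnrow, row, btot, cross
                )
                return True
        step = 0.5 * step
    return False


def _run_optimizer(
    A: WeightedMatrix,
    emb: Embedding,
    *,
    max_iter: int,
    gtol: float,
    dtol: float,
    freeze_h: bool,
    freeze_sigma: bool,
) -> tuple[_LayoutState, int, str]:
    state = _LayoutState(A, emb)
    n = emb.n
    reason = "max_iter"
    sweep_D = state.D
    it = 0
    while it < max_iter:
        if not np.isfinite(state.D):
            state._full_refresh()
            if not np.isfinite(state.D):
                raise FloatingPointError(
                    "layout diverged: overlap mass vanished (all pairwise "
                    "overlaps underflowed)"
                )
        grads = state.all_position_gradients()
        norms = np.linalg.norm(grads, axis=1)
        if not np.all(np.isfinite(norms)):
            state._full_refresh()
            grads = state.all_position_gradients()
            norms = np.nan_to_num(np.linalg.norm(grads, axis=1))
        k = int(np.argmax(norms))
        if norms[k] < gtol:
            reason = "gtol"
            break
        _update_position(state, k, _sigma_floor(state))
        it += 1
        if it % n == 0:
            # full sweep: every node's position, then widths and norms
            floor = _sigma_floor(state)
            for j in range(n):
                _update_position(state, j, floor)
            if not freeze_sigma:
                for j in range(n):
                    _update_scalar(state, j, "sigma", floor)
            if not freeze_h:
                for j in range(n):
                    _update_scalar(state, j, "h", floor)
            it += n
            D = state.D
            if abs(sweep_D - D) < dtol * max(abs(D), 1e-30):
                reason = "dtol"
                break
            sweep_D = D
    if not np.all(np.isfinite(state.emb.positions)):
        raise FloatingPointError("layout diverged: non-finite coordinates")
    return state, it, reason


def _sigma_floor(state: _LayoutState) -> float:
    spread = float(np.ptp(state.emb.positions)) if state.emb.n > 1 else 1.0
    return max(1e-6 * max(spread, 1e-6), 1e-12)


def optimize_layout(
    A,
    d: int = 2,
    *,
    max_iter: int | None = None,
    gtol: float = 1e-8,
    dtol: float = 1e-9,
    seed=None,
    n_restarts: int = 1,
    freeze_h: bool = True,
    freeze_sigma: bool = False,
    fine_tune: bool = True,
    init: Embedding | None = None,
    jitter: float = 1e-6,
) -> LayoutResult:
    """Minimize D(A‖B) over a Gaussian embedding of dimension d.

    Starts from the product state (all nodes coincident, h_i ∝ a_i*, so
    D_0 = I(A)) unless an explicit ``init`` embedding is given.  The norms
    h_i stay pinned at a_i*/a_** during the main phase; with ``fine_tune``
    a second phase releases both widths and norms.  With restarts, the
    lowest-divergence run wins; all randomness derives from ``seed``.
    """
    A = as_matrix(A)
    if max_iter is None:
        max_iter = 100 * A.n
    info = summarize(A)
    if info.mutual_information <= 1e-14:
        # structureless input: the product state is already perfect
        emb = init_product_state(A, d, seed=seed, jitter=0.0)
        return LayoutResult(emb, 0.0, 0.0, 0, "rank-1 input")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(n_restarts, 1))
    best: LayoutResult | None = None
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        emb = (
            init.copy()
            if init is not None
            else init_product_state(A, d, seed=sub_seed, jitter=jitter)
        )
        state, iters, reason = _run_optimizer(
            A,
            emb,
            max_iter=max_iter,
            gtol=gtol,
            dtol=dtol,
            freeze_h=freeze_h,
            freeze_sigma=freeze_sigma,
        )
        if fine_tune and (freeze_h or freeze_sigma):
            state, extra, reason = _run_optimizer(
                A,
                state.emb,
                max_iter=max_iter,
                gtol=gtol,
                dtol=dtol,
                freeze_h=False,
                freeze_sigma=False,
            )
            iters += extra
        D = state.D
        result = LayoutResult(
            state.emb, float(D), float(D / info.mutual_information), iters, reason
        )
        if best is None or result.divergence < best.divergence:
            best = result
        if init is not None:
            break  # deterministic start: restarts would repeat it
    return best


# ---------------------------------------------------------------------------
# one-dimensional (seriation) refinement moves
#
# Gradient steps cannot reorder nodes along a line: permutations are
# separated by high-divergence barriers.  Two combinatorial move classes fix
# this — reinsertion (teleport one node into any inter-node gap) and segment
# reversal (mirror a contiguous run, the classic 2-opt move of seriation) —
# each followed by local continuous re-optimization and accepted only when D
# decreases.


def _sweeps(
    state: _LayoutState, n_sweeps: int, *, freeze_h: bool, freeze_sigma: bool
) -> None:
    """Cheap refinement: fixed node-order sweeps without gradient ranking."""
    floor = _sigma_floor(state)
    for _ in range(n_sweeps):
        for j in range(state.emb.n):
            _update_position(state, j, floor)
            if not freeze_sigma:
                _update_scalar(state, j, "sigma", floor)
            if not freeze_h:
                _update_scalar(state, j, "h", floor)


def _reinsert_pass(state: _LayoutState) -> bool:
    n = state.emb.n
    improved = False
    floor = _sigma_floor(state)
    for k in range(n):
        xs = np.sort(state.emb.positions[:, 0])
        gaps = np.concatenate(
            [[xs[0] - 1.0], 0.5 * (xs[:-1] + xs[1:]), [xs[-1] + 1.0]]
        )
        best_D, payload = state.D, None
        for gx in gaps:
            D, lnrow, row, btot, cross = state.trial(k, x_k=np.array([gx]))
            if D < best_D - 1e-12:
                best_D, payload = D, (gx, lnrow, row, btot, cross)
        if payload is not None:
            gx, lnrow, row, btot, cross = payload
            state.commit(
                k, np.array([gx]), state.emb.sigma[k], state.emb.h[k],
                lnrow, row, btot, cross,
            )
            for _ in range(5):
                _update_position(state, k, floor)
                _update_scalar(state, k, "sigma", floor)
                _update_scalar(state, k, "h", floor)
            improved = True
    return improved


def _reversal_pass(
    state: _LayoutState, *, freeze_h: bool, freeze_sigma: bool
) -> tuple[_LayoutState, bool]:
    n = state.emb.n
    improved = False
    windows = [w for w in (3, 4, 5, 7, 10, max(3, n // 3), max(4, n // 2)) if w <= n]
    stride = 1 if n <= 60 else 2
    for w in sorted(set(windows)):
        for start in range(0, n - w + 1, stride):
            x = state.emb.positions[:, 0]
            order = np.argsort(x)
            seg = order[start : start + w]
            lo, hi = x[seg].min(), x[seg].max()
            emb2 = state.emb.copy()
            emb2.positions = x[:, None].copy()
            emb2.positions[seg, 0] = lo + hi - x[seg]
            st2 = _LayoutState(state.A, emb2)
            # screen with a short optimizer run to settle the mirrored run
            st2, _, _ = _run_optimizer(
                state.A, st2.emb, max_iter=150 if n <= 60 else 40,
                gtol=1e-8, dtol=1e-9,
                freeze_h=freeze_h, freeze_sigma=freeze_sigma,
            )
            if st2.D < state.D - 1e-10:
                state = st2
                improved = True
    return state, improved


def seriation_polish(
    A,
    emb: Embedding,
    *,
    max_cycles: int = 6,
    freeze_h: bool = False,
    freeze_sigma: bool = False,
    max_iter: int | None = None,
) -> LayoutResult:
    """Refine a 1-D layout with reinsertion and segment-reversal moves.

    Alternates combinatorial passes with continuous re-optimization until
    neither move class improves D (or the cycle cap is reached).
    """
    A = as_matrix(A)
    if emb.d != 1:
        raise ValueError("seriation polish applies to 1-D layouts")
    if max_iter is None:
        max_iter = 100 * A.n
    state = _LayoutState(A, emb.copy())
    iters = 0
    for _ in range(max_cycles):
        imp1 = _reinsert_pass(state)
        state, it, _ = _run_optimizer(
            A, state.emb, max_iter=max_iter, gtol=1e-8, dtol=1e-9,
            freeze_h=freeze_h, freeze_sigma=freeze_sigma,
        )
        iters += it
        state, imp2 = _reversal_pass(
            state, freeze_h=freeze_h, freeze_sigma=freeze_sigma
        )
        if not (imp1 or imp2):
            break
    info = summarize(A)
    D = state.D
    eta_val = D / info.mutual_information if info.mutual_information > 0 else 0.0
    return LayoutResult(state.emb, float(D), float(eta_val), iters, "polished")


# ---------------------------------------------------------------------------
# estimator


class GaussianEmbedding(BaseEstimator):
    """Embed a weighted network as d-dimensional Gaussian distributions.

    scikit-learn style estimator over a precomputed symmetric non-negative
    affinity matrix.  ``fit_transform`` returns the (n, d) positions; the
    widths express the residual positional uncertainty of each node and
    the divergence/eta attributes quantify layout quality.

    Parameters
    ----------
    n_components : embedding dimension d (1 gives a seriation ordering).
    init : "product" (cold start) or "hierarchical" (coarse-graining-guided
        top-down start, usually markedly better).
    n_restarts : independent seeded starts; the lowest divergence wins.
    freeze_h, freeze_sigma : pin norms/widths during the main phase.
    fine_tune : release widths and norms for a final refinement phase.
    random_state : master seed for all randomness.

    Attributes
    ----------
    embedding_ : (n, d) positions.
    sigma_, h_ : widths and norms.
    divergence_ : final D(A‖B) in nats.
    eta_ : D / I(A), the residual-information ratio.
    ordering_ : node permutation (only when n_components == 1).
    """

    def __init__(
        self,
        n_components: int = 2,
        *,
        init: str = "product",
        n_restarts: int = 1,
        max_iter: int | None = None,
        gtol: float = 1e-8,
        dtol: float = 1e-9,
        freeze_h: bool = True,
        freeze_sigma: bool = False,
        fine_tune: bool = True,
        polish: bool = True,
        jitter: float = 1e-6,
        random_state=None,
    ):
        self.n_components = n_components
        self.init = init
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.gtol = gtol
        self.dtol = dtol
        self.freeze_h = freeze_h
        self.freeze_sigma = freeze_sigma
        self.fine_tune = fine_tune
        self.polish = polish
        self.jitter = jitter
        self.random_state = random_state

    def fit(self, X, y=None):
        A = as_matrix(X)
        if self.init == "hierarchical":
            from .hier import hierarchical_layout

            ss = np.random.SeedSequence(self.random_state)
            best = None
            for child in ss.spawn(max(self.n_restarts, 1)):
                sub = int(child.generate_state(1)[0] % (2**31))
                res = hierarchical_layout(
                    A,
                    self.n_components,
                    seed=sub,
                    freeze_h=self.freeze_h,
                    fine_tune=self.fine_tune,
                    max_iter=self.max_iter,
                )
                if self.n_components == 1 and self.polish and res.divergence > 0:
                    # combinatorial refinement is basin-dependent: polish
                    # every restart, not only the best one
                    pol = seriation_polish(
                        A,
                        res.embedding,
                        freeze_h=self.freeze_h and not self.fine_tune,
                        freeze_sigma=self.freeze_sigma and not self.fine_tune,
                        max_iter=self.max_iter,
                    )
                    if pol.divergence < res.divergence:
                        res = pol
                if best is None or res.divergence < best.divergence:
                    best = res
            result = best
        elif self.init == "product":
            result = optimize_layout(
                A,
                self.n_components,
                max_iter=self.max_iter,
                gtol=self.gtol,
                dtol=self.dtol,
                seed=self.random_state,
                n_restarts=self.n_restarts,
                freeze_h=self.freeze_h,
                freeze_sigma=self.freeze_sigma,
                fine_tune=self.fine_tune,
                jitter=self.jitter,
            )
        else:
            raise ValueError("init must be 'product' or 'hierarchical'")
        if (
            self.n_components == 1
            and self.polish
            and self.init != "hierarchical"  # hierarchical restarts are
            and result.divergence > 0        # polished individually above
        ):
            polished = seriation_polish(
                A,
                result.embedding,
                freeze_h=self.freeze_h and not self.fine_tune,
                freeze_sigma=self.freeze_sigma and not self.fine_tune,
                max_iter=self.max_iter,
            )
            if polished.divergence < result.divergence:
                result = polished
        self.result_ = result
        self.embedding_ = result.embedding.positions
        self.sigma_ = result.embedding.sigma
        self.h_ = result.embedding.h
        self.divergence_ = result.divergence
        self.eta_ = result.eta
        self.n_iter_ = result.n_iter
        if self.n_components == 1:
            self.ordering_ = ordering_from_embedding(result.embedding)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_
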