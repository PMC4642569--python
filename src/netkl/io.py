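"""Readers and writers for networks, embeddings and partitions.

All text formats are TSV with UTF-8 and LF line endings: dense matrices
(optional label header), undirected 3-column edge lists (duplicates
summed), edge-by-node incidence matrices, per-node coordinates, orderings
and partitions, plus an SVG rendering in the circles-of-radius-sigma style.
"""

from __future__ import annotations

import numpy as np

from .core import WeightedMatrix, as_matrix, incidence_to_adjacency
from .layout import Embedding

__all__ = [
    "read_network",
    "read_edgelist",
    "read_matrix",
    "read_incidence",
    "write_matrix",
    "write_edgelist",
    "write_coordinates",
    "read_coordinates",
    "write_ordering",
    "write_partition",
    "render_svg",
]

_FMT = "%.9g"


def _split(line: str) -> list[str]:
    return line.replace("\t", " ").split()


def read_edgelist(path, *, allow_self_loops: bool = True) -> WeightedMatrix:
    """Undirected weighted edge list: ``source<TAB>target<TAB>weight``.

    Duplicate edges (in either orientation) are summed.  Node labels are
    kept in first-appearance order.
    """
    labels: dict[str, int] = {}
    triples: list[tuple[int, int, float]] = []
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, 1):
            parts = _split(raw)
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{ln}: expected 2 or 3 columns")
            try:
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError:
                raise ValueError(f"{path}:{ln}: bad weight {parts[2]!r}") from None
            if w < 0:
                raise ValueError(f"{path}:{ln}: negative weight")
            i = labels.setdefault(parts[0], len(labels))
            j = labels.setdefault(parts[1], len(labels))
            if i == j and not allow_self_loops:
                raise ValueError(f"{path}:{ln}: self-loop not allowed")
            triples.append((i, j, w))
    if not triples:
        raise ValueError(f"{path}: no edges")
    n = len(labels)
    A = np.zeros((n, n))
    for i, j, w in triples:
        if i == j:
            A[i, i] += w
        else:
            A[i, j] += w
            A[j, i] += w
    return WeightedMatrix(
        A,
        labels=list(labels),
        symmetric=True,
        zero_diagonal=not np.any(np.diag(A)),
    )


def read_matrix(path, *, as_incidence: bool = False, **kwargs) -> WeightedMatrix:
    """Dense whitespace/TSV numeric matrix with an optional label header."""
    labels_from_comment = None
    with open(path, encoding="utf-8") as fh:
        lines = []
        for l in (l.strip() for l in fh):
            if l.startswith("# labels:"):
                labels_from_comment = l[len("# labels:"):].split()
            elif l and not l.startswith("#"):
                lines.append(l)
    if not lines:
        raise ValueError(f"{path}: empty file")
    first = _split(lines[0])

    def _numeric(tokens):
        try:
            return [float(t) for t in tokens]
        except ValueError:
            return None

    labels = labels_from_comment
    start = 0
    if labels is None and _numeric(first) is None:
        labels = first
        start = 1
    rows = []
    for ln, line in enumerate(lines[start:], start + 1):
        tokens = _split(line)
        vals = _numeric(tokens)
        if vals is None:
            # allow a leading row label
            vals = _numeric(tokens[1:])
            if vals is None:
                raise ValueError(f"{path}:{ln}: non-numeric entry")
        rows.append(vals)
    A = np.array(rows)
    if np.any(A < 0):
        raise ValueError(f"{path}: negative weight")
    if as_incidence:
        return incidence_to_adjacency(A, **kwargs)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValueError(
            f"{path}: matrix is not symmetric; pass it as an incidence "
            "matrix if it is edge-by-node data"
        )
    A = 0.5 * (A + A.T)
    return WeightedMatrix(
        A,
        labels=labels,
        symmetric=True,
        zero_diagonal=not np.any(np.diag(A)),
    )


def read_incidence(path, *, triplets: bool = False, **kwargs) -> WeightedMatrix:
    """Edge-by-node incidence input, dense rows or sparse triplets.

    Triplet rows are ``edge<TAB>node<TAB>weight`` with arbitrary labels.
    """
    if not triplets:
        return read_matrix(path, as_incidence=True, **kwargs)
    edges: dict[str, int] = {}
    nodes: dict[str, int] = {}
    entries = []
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, 1):
            parts = _split(raw)
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            w = float(parts[2])
            if w < 0:
                raise ValueError(f"{path}:{ln}: negative weight")
            e = edges.setdefault(parts[0], len(edges))
            v = nodes.setdefault(parts[1], len(nodes))
            entries.append((e, v, w))
    if not entries:
        raise ValueError(f"{path}: empty incidence data")
    H = np.zeros((len(edges), len(nodes)))
    for e, v, w in entries:
        H[e, v] += w
    out = incidence_to_adjacency(H, **kwargs)
    out.labels = list(nodes)[: out.n]
    return out


def read_network(path, format: str = "auto", **kwargs) -> WeightedMatrix:
    """Dispatching reader: edgelist, matrix, incidence or triplet incidence."""
    if format == "auto":
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                parts = _split(raw)
                if parts and not parts[0].startswith("#"):
                    format = "edgelist" if len(parts) <= 3 else "matrix"
                    break
            else:
                raise ValueError(f"{path}: empty file")
    if format == "edgelist":
        return read_edgelist(path, **kwargs)
    if format == "matrix":
        return read_matrix(path, **kwargs)
    if format == "incidence":
        return read_incidence(path, **kwargs)
    if format == "incidence-triplets":
        return read_incidence(path, triplets=True, **kwargs)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(A, path) -> None:
    # labels go in a comment so purely numeric label sets stay unambiguous
    A = as_matrix(A)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# labels: " + " ".join(A.labels) + "\n")
        for row in A.values:
            fh.write("\t".join(_FMT % v for v in row) + "\n")


def write_edgelist(A, path) -> None:
    """Upper-triangle (plus diagonal) non-zero entries as a TSV edge list."""
    A = as_matrix(A)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i in range(A.n):
            for j in range(i, A.n):
                if A.values[i, j] > 0:
                    fh.write(
                        f"{A.labels[i]}\t{A.labels[j]}\t{_FMT % A.values[i, j]}\n"
                    )


def write_coordinates(emb: Embedding, path, labels=None) -> None:
    """TSV ``node<TAB>x1..xd<TAB>sigma<TAB>h`` with 9 significant digits."""
    labels = labels or [str(i) for i in range(emb.n)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["node"] + [f"x{k+1}" for k in range(emb.d)] + ["sigma", "h"]
        fh.write("\t".join(header) + "\n")
        for i in range(emb.n):
            row = [labels[i]]
            row += [_FMT % v for v in emb.positions[i]]
            row += [_FMT % emb.sigma[i], _FMT % emb.h[i]]
            fh.write("\t".join(row) + "\n")


def read_coordinates(path) -> tuple[Embedding, list[str]]:
    with open(path, encoding="utf-8") as fh:
        header = _split(fh.readline())
        d = sum(1 for c in header if c.startswith("x"))
        labels, X, sigma, h = [], [], [], []
        for raw in fh:
            parts = _split(raw)
            if not parts:
                continue
            labels.append(parts[0])
            X.append([float(v) for v in parts[1 : 1 + d]])
            sigma.append(float(parts[1 + d]))
            h.append(float(parts[2 + d]))
    return Embedding(d, np.array(X), np.array(sigma), np.array(h)), labels


def write_ordering(labels_in_order, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for label in labels_in_order:
            fh.write(f"{label}\n")


def write_partition(labels, groups, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\tgroup\n")
        for label, g in zip(labels, groups):
            fh.write(f"{label}\t{int(g)}\n")


def render_svg(A, emb: Embedding, path, *, figsize: float = 7.0) -> None:
    """Draw the layout as circles of radius sigma_i with weight-scaled edges.

    d = 1 layouts are drawn on a line; d >= 3 layouts are projected onto
    their first two coordinates.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    A = as_matrix(A)
    X = emb.positions
    if emb.d == 1:
        X = np.column_stack([X[:, 0], np.zeros(emb.n)])
    else:
        X = X[:, :2]
    fig, ax = plt.subplots(figsize=(figsize, figsize))
    wmax = A.values.max()
    for i in range(A.n):
        for j in range(i + 1, A.n):
            w = A.values[i, j]
            if w > 0:
                ax.plot(
                    [X[i, 0], X[j, 0]],
                    [X[i, 1], X[j, 1]],
                    color="0.55",
                    linewidth=2.5 * w / wmax,
                    zorder=1,
                )
    for i in range(A.n):
        ax.add_patch(
            Circle(
                X[i],
                radius=emb.sigma[i],
                facecolor="tab:blue",
                edgecolor="k",
                alpha=0.45,
                zorder=2,
            )
        )
    ax.set_aspect("equal")
    ax.autoscale_view()
    ax.set_axis_off()
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
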