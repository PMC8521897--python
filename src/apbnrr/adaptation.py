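"""Registration-point-driven mesh adaptation metrics.

The goal is to equidistribute registration points (block centers) among
mesh vertex cell complexes. Two metric constructions are provided:

* isotropic — local spacing at a vertex equals the distance to its k-th
  nearest registration point, i.e. ``M = I / d_k^2``;
* anisotropic — the minimum-volume ellipsoid centered at the vertex that
  encloses its k nearest registration points, computed by the Khachiyan
  algorithm on the centrally symmetrized point set, optionally inflated
  by a constant factor ``a`` (every axis scaled by ``a``).

A metric tensor M (mm^-2, symmetric positive definite) encodes the
ellipsoid ``{x : (x - v)^T M (x - v) <= 1}``. The mesh is then refined by
longest-metric-edge bisection until no edge exceeds metric length sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesher import TetLocator, TetMesh


@dataclass
class AdaptationConfig:
    """k-NN count, inflation constant and metric mode.

    The clinical default is k = 500 registration points per vertex cell;
    desk-scale phantoms yield fewer points, so callers typically pass
    ``min(500, n_points // 2)``.
    """

    k: int = 500
    a: float = 1.0
    mode: str = "isotropic"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.a < 1:
            raise ValueError("inflation constant a must be >= 1")
        if self.mode not in ("isotropic", "anisotropic"):
            raise ValueError(f"unknown mode {self.mode!r}")


def knn_distance(vertices: np.ndarray, points: np.ndarray, k: int) -> np.ndarray:
    """Distance from each vertex to its k-th nearest registration point."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    if k > len(points):
        raise ValueError(f"k={k} exceeds the number of registration points {len(points)}")
    d, _ = cKDTree(points).query(vertices, k=k)
    return d[:, -1] if k > 1 else np.asarray(d).reshape(-1)


def centered_mvee(center: np.ndarray, points: np.ndarray, eps: float = 1e-3,
                  max_iter: int = 10000, min_axis: float = 1e-6) -> np.ndarray:
    """Minimum-volume enclosing ellipsoid centered at ``center``.

    Khachiyan iteration on the centrally symmetrized set {p - c, -(p - c)}
    (the centered problem reduces exactly to the classical MVEE of a
    symmetric set): maximize log det of X = sum_i u_i q_i q_i^T subject to
    the simplex constraint on u; the metric is M = X^{-1} / d with d = 3.
    Every point then satisfies (p - c)^T M (p - c) <= 1 + eps.

    Degenerate (coplanar/collinear about the center) inputs are
    regularized with a minimum axis length ``min_axis`` (mm).
    """
    center = np.asarray(center, dtype=float).reshape(3)
    q = np.asarray(points, dtype=float).reshape(-1, 3) - center
    n, d = q.shape
    if n == 0:
        raise ValueError("no points")
    u = np.full(n, 1.0 / n)
    reg = min_axis**2
    for _ in range(max_iter):
        X = (q * u[:, None]).T @ q + reg * np.eye(3)
        Xinv = np.linalg.inv(X)
        m = np.einsum("ij,jk,ik->i", q, Xinv, q)
        j = int(np.argmax(m))
        if m[j] <= d * (1.0 + eps):
            break
        step = (m[j] - d) / (d * (m[j] - 1.0))
        u = (1.0 - step) * u
        u[j] += step
    X = (q * u[:, None]).T @ q + reg * np.eye(3)
    M = np.linalg.inv(X) / d
    M = 0.5 * (M + M.T)
    # Cap eigenvalues so degenerate directions get the minimum axis length.
    w, V = np.linalg.eigh(M)
    w = np.minimum(w, 1.0 / reg)
    return (V * w) @ V.T


@dataclass
class MetricField:
    """Per-vertex SPD tensors (mm^-2) driving anisotropic adaptation."""

    tensors: np.ndarray  # (n, 3, 3)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float).reshape(-1, 3, 3)
        w = np.linalg.eigvalsh(self.tensors)
        if np.any(w <= 0):
            raise ValueError("metric tensors must be positive definite")

    def __len__(self) -> int:
        return len(self.tensors)


def build_metric(mesh: TetMesh, points: np.ndarray, cfg: AdaptationConfig) -> MetricField:
    """Metric field on the mesh vertices from the registration points.

    Isotropic: ``M_v = I / d_k(v)^2``. Anisotropic: the centered MVEE of
    the k nearest points, with every ellipsoid axis scaled by the
    inflation constant ``a`` (i.e. ``M / a^2``).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    k = min(cfg.k, len(points))
    if k < 1:
        raise ValueError("no registration points")
    verts = mesh.vertices
    if cfg.mode == "isotropic":
        d_k = knn_distance(verts, points, k)
        d_k = np.maximum(d_k, 1e-6)
        tensors = np.eye(3)[None] / (cfg.a * d_k[:, None, None]) ** 2
        return MetricField(tensors)
    tree = cKDTree(points)
    _, idx = tree.query(verts, k=k)
    idx = np.atleast_2d(idx)
    if idx.shape[0] != len(verts):
        idx = idx.reshape(len(verts), -1)
    tensors = np.empty((len(verts), 3, 3))
    for v in range(len(verts)):
        tensors[v] = centered_mvee(verts[v], points[idx[v]]) / cfg.a**2
    return MetricField(tensors)


def metric_edge_lengths(vertices: np.ndarray, tensors: np.ndarray,
                        edges: np.ndarray) -> np.ndarray:
    """Metric length of each edge under the averaged endpoint metric."""
    e = vertices[edges[:, 1]] - vertices[edges[:, 0]]
    M = 0.5 * (tensors[edges[:, 0]] + tensors[edges[:, 1]])
    return np.sqrt(np.einsum("ei,eij,ej->e", e, M, e))


def adapt_mesh(mesh: TetMesh, metric: MetricField, max_factor: int = 10,
               max_passes: int = 60) -> tuple[TetMesh, MetricField]:
    """Refine by longest-metric-edge bisection until all edges are short.

    Any edge of metric length > sqrt(2) is split at its midpoint (all tets
    sharing the edge bisect simultaneously, keeping the mesh conforming);
    midpoint metrics are interpolated (the average of two SPD tensors is
    SPD). Stops when no edge exceeds the bound, or at a ``max_factor`` x
    input size cap (partial result, flagged by a warning).
    """
    import warnings

    if len(metric) != mesh.n_vertices:
        raise ValueError("metric must be defined on every mesh vertex")
    verts = list(map(np.asarray, mesh.vertices))
    tensors = list(map(np.asarray, metric.tensors))
    tets = mesh.tets.copy()
    tissue = mesh.tissue.copy()
    cap = max_factor * max(mesh.n_tets, 1)
    bound = np.sqrt(2.0)

    for _ in range(max_passes):
        V = np.asarray(verts)
        T = np.asarray(tensors)
        pairs = tets[:, [0, 1, 0, 2, 0, 3, 1, 2, 1, 3, 2, 3]].reshape(-1, 2)
        pairs = np.sort(pairs, axis=1)
        edges, inv = np.unique(pairs, axis=0, return_inverse=True)
        lengths = metric_edge_lengths(V, T, edges)
        long_ids = np.where(lengths > bound)[0]
        if len(long_ids) == 0 or len(tets) >= cap:
            if len(tets) >= cap and len(long_ids):
                warnings.warn("adaptation size cap reached; partial refinement returned")
            break
        # Independent set: at most one split edge per tet, longest first.
        order = long_ids[np.argsort(-lengths[long_ids], kind="stable")]
        edge_of_tet = inv.reshape(-1, 6)
        tet_blocked = np.zeros(len(tets), dtype=bool)
        tets_of_edge: dict[int, list[int]] = {}
        for t in range(len(tets)):
            for e in edge_of_tet[t]:
                tets_of_edge.setdefault(int(e), []).append(t)
        chosen = []
        for e in order:
            owners = tets_of_edge[int(e)]
            if any(tet_blocked[t] for t in owners):
                continue
            chosen.append(int(e))
            for t in owners:
                tet_blocked[t] = True
            if len(tets) + sum(len(tets_of_edge[c]) for c in chosen) >= cap:
                break
        if not chosen:
            break
        midpoint_of = {}
        for e in chosen:
            a, b = edges[e]
            midpoint_of[(int(a), int(b))] = len(verts)
            verts.append(0.5 * (V[a] + V[b]))
            tensors.append(0.5 * (T[a] + T[b]))
        new_tets, new_tissue = [], []
        for t in range(len(tets)):
            split = None
            for i, j in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)):
                key = tuple(sorted((int(tets[t, i]), int(tets[t, j]))))
                if key in midpoint_of:
                    split = (i, j, midpoint_of[key])
                    break
            if split is None:
                new_tets.append(tets[t])
                new_tissue.append(tissue[t])
            else:
                i, j, mid = split
                for repl in (i, j):
                    child = tets[t].copy()
                    child[repl] = mid
                    new_tets.append(child)
                    new_tissue.append(tissue[t])
        tets = np.asarray(new_tets, dtype=np.int64)
        tissue = np.asarray(new_tissue, dtype=np.int64)

    out = TetMesh(np.asarray(verts), tets, tissue).oriented()
    return out, MetricField(np.asarray(tensors))


def points_per_vertex_cell(mesh: TetMesh, points: np.ndarray,
                           locator: TetLocator | None = None) -> np.ndarray:
    """Registration points per vertex cell complex (elements touching a vertex).

    Each point inside the mesh contributes to the four vertices of its
    containing tet; the returned array has one count per mesh vertex.
    """
    if locator is None:
        locator = TetLocator(mesh)
    tet_idx, _ = locator.locate(np.asarray(points, dtype=float).reshape(-1, 3))
    counts = np.zeros(mesh.n_vertices, dtype=int)
    for t in tet_idx[tet_idx >= 0]:
        for v in mesh.tets[t]:
            counts[v] += 1
    return counts
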