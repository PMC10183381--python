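"""Exact point-to-surface distances for triangle meshes.

Vectorised closest-point-on-triangle projection with k-d tree pruning on
triangle centroids.  Distances are unsigned; a point lying on the surface
reports (numerically) zero.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``triangles[i]`` to ``points[i]``, elementwise.

    ``points``: (n, 3); ``triangles``: (n, 3, 3).  Standard region-based
    projection (Eberly's algorithm, vectorised).
    """
    p = np.asarray(points, float)
    a = triangles[:, 0]
    ab = triangles[:, 1] - a
    ac = triangles[:, 2] - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - triangles[:, 1]
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - triangles[:, 2]
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    # vertex regions
    settle((d1 <= 0) & (d2 <= 0), a)
    settle((d3 >= 0) & (d4 <= d3), triangles[:, 1])
    settle((d6 >= 0) & (d5 <= d6), triangles[:, 2])

    # edge AB
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)

    # edge AC
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)

    # edge BC
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           triangles[:, 1] + w_bc[:, None] * (triangles[:, 2] - triangles[:, 1]))

    # interior
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    settle(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


class SurfaceDistance:
    """Nearest-point query object for one triangle mesh."""

    def __init__(self, mesh, leafsize: int = 16):
        self.triangles = np.asarray(mesh.triangles, float)
        self.face_normals = np.asarray(mesh.face_normals, float)
        centroids = self.triangles.mean(axis=1)
        # prune radius: candidate set must contain the true nearest triangle
        self._half_diag = 0.5 * np.linalg.norm(
            self.triangles.max(axis=1) - self.triangles.min(axis=1), axis=1
        ).max()
        self._tree = cKDTree(centroids, leafsize=leafsize)

    def query(self, points: np.ndarray, k: int = 16):
        """Return (closest_points, distances, face_indices) for each query point."""
        pts = np.atleast_2d(np.asarray(points, float))
        k = min(k, len(self.triangles))
        _, idx = self._tree.query(pts, k=k)
        idx = np.atleast_2d(idx)
        n, kk = idx.shape
        flat_idx = idx.ravel()
        rep_pts = np.repeat(pts, kk, axis=0)
        cand = closest_point_on_triangles(rep_pts, self.triangles[flat_idx])
        d2 = np.einsum("ij,ij->i", rep_pts - cand, rep_pts - cand).reshape(n, kk)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        closest = cand.reshape(n, kk, 3)[rows, best]
        faces = idx[rows, best]
        return closest, np.sqrt(d2[rows, best]), faces


def _any_vertex_inside_convex(vertices: np.ndarray, mesh, margin: float = 0.0) -> bool:
    """True if any vertex lies inside the CONVEX mesh (face half-space test)."""
    lo, hi = mesh.bounds
    cand = vertices[np.all((vertices > lo - margin) & (vertices < hi + margin), axis=1)]
    if len(cand) == 0:
        return False
    origins = mesh.triangles[:, 0]
    normals = mesh.face_normals
    # v inside iff n_f . (v - p_f) <= 0 for every face f
    d = np.einsum("fj,vfj->vf", normals, cand[:, None, :] - origins[None, :, :])
    return bool(np.any(np.all(d <= 1e-9, axis=1)))


def signed_gap_convex(mesh_a, mesh_b, k: int = 16) -> float:
    """Signed separation of two convex meshes: the minimum surface distance,
    negated when the bodies interpenetrate."""
    d = min_surface_distance(mesh_a, mesh_b, k=k)
    if (_any_vertex_inside_convex(mesh_a.vertices, mesh_b)
            or _any_vertex_inside_convex(mesh_b.vertices, mesh_a)):
        return -d
    return d


def min_surface_distance(mesh_a, mesh_b, k: int = 16) -> float:
    """Minimum unsigned surface-to-surface distance between two meshes.

    Queries each mesh's vertices against the other's triangles (both
    directions), which is exact to within the sampling of the meshes
    themselves and symmetric.
    """
    da = SurfaceDistance(mesh_b).query(mesh_a.vertices, k=k)[1].min()
    db = SurfaceDistance(mesh_a).query(mesh_b.vertices, k=k)[1].min()
    return float(min(da, db))
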