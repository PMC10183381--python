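"""Watertight parametric solids used as stand-ins for tooth anatomy.

Crowns are superellipsoids (boxy-rounded closed surfaces), single roots are
tapered cones, multirooted bodies are a root trunk plus two diverging root
cones that share an explicit furcation level.  All dimensions in mm.
"""
from __future__ import annotations

import numpy as np
import trimesh


def _grid_surface(points: np.ndarray) -> trimesh.Trimesh:
    """Triangulate an (nu, nv) closed-in-v grid of 3D points.

    Rows ``u`` run pole-to-pole; the first and last rows may be degenerate
    (poles).  Columns ``v`` wrap around.  Duplicate vertices are merged,
    which closes the poles and the seam.
    """
    nu, nv, _ = points.shape
    verts = points.reshape(-1, 3)
    faces = []
    for i in range(nu - 1):
        for j in range(nv):
            j2 = (j + 1) % nv
            a = i * nv + j
            b = i * nv + j2
            c = (i + 1) * nv + j
            d = (i + 1) * nv + j2
            faces.append([a, b, d])
            faces.append([a, d, c])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    mesh.merge_vertices(merge_tex=True, merge_norm=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    mesh.fix_normals()
    return mesh


def _superellipse_cs(c: np.ndarray, s: np.ndarray, e: float):
    return np.sign(c) * np.abs(c) ** e, np.sign(s) * np.abs(s) ** e


def superellipsoid(a: float, b: float, c: float, e_we: float = 0.8,
                   e_ns: float = 0.8, n_u: int = 17, n_v: int = 24) -> trimesh.Trimesh:
    """Closed superellipsoid with semi-axes (a, b, c).

    ``e_ns`` is the north-south (latitudinal) exponent, ``e_we`` the
    equatorial one; exponents < 1 give a boxy, rounded-corner solid.
    """
    u = np.linspace(-np.pi / 2, np.pi / 2, n_u)
    v = np.linspace(-np.pi, np.pi, n_v, endpoint=False)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    cu, su = _superellipse_cs(np.cos(uu), np.sin(uu), e_ns)
    cv, sv = _superellipse_cs(np.cos(vv), np.sin(vv), e_we)
    x = a * cu * cv
    y = b * cu * sv
    z = c * su
    return _grid_surface(np.stack([x, y, z], axis=-1))


def tapered_cone(r_top_x: float, r_top_y: float, length: float,
                 apex_offset=(0.0, 0.0), tip_fraction: float = 0.02,
                 n_u: int = 9, n_v: int = 20) -> trimesh.Trimesh:
    """Closed tapered cone: elliptical top rim at z = 0, apex at z = -length.

    The top is capped with a fan; the radius tapers linearly to
    ``tip_fraction`` of the top radius before collapsing to the apex point,
    which keeps near-tip triangles well shaped.  ``apex_offset`` tilts the
    axis (apex displaced in x/y), used for curved/diverging roots.
    """
    frac = np.linspace(0.0, 1.0, n_u)  # 0 = top rim, 1 = apex
    v = np.linspace(-np.pi, np.pi, n_v, endpoint=False)
    rows = []
    # cap: collapse a degenerate first row at the rim centre
    rows.append(np.tile(np.array([0.0, 0.0, 0.0]), (n_v, 1)))
    for f in frac:
        r = (1.0 - f) + tip_fraction * f
        cx = apex_offset[0] * f
        cy = apex_offset[1] * f
        ring = np.stack([cx + r_top_x * r * np.cos(v),
                         cy + r_top_y * r * np.sin(v),
                         np.full(n_v, -length * f)], axis=-1)
        rows.append(ring)
    apex = np.array([apex_offset[0], apex_offset[1], -length])
    rows.append(np.tile(apex, (n_v, 1)))
    return _grid_surface(np.stack(rows, axis=0))


def frustum(r_top_x: float, r_top_y: float, r_bot_scale: float, depth: float,
            n_v: int = 20) -> trimesh.Trimesh:
    """Closed elliptical frustum from z = 0 down to z = -depth, capped both ends."""
    v = np.linspace(-np.pi, np.pi, n_v, endpoint=False)
    rows = [np.tile(np.array([0.0, 0.0, 0.0]), (n_v, 1))]
    for z, s in ((0.0, 1.0), (-depth, r_bot_scale)):
        rows.append(np.stack([r_top_x * s * np.cos(v),
                              r_top_y * s * np.sin(v),
                              np.full(n_v, z)], axis=-1))
    rows.append(np.tile(np.array([0.0, 0.0, -depth]), (n_v, 1)))
    return _grid_surface(np.stack(rows, axis=0))


def box(extents, center=(0.0, 0.0, 0.0)) -> trimesh.Trimesh:
    mesh = trimesh.creation.box(extents=extents)
    mesh.apply_translation(center)
    return mesh


def resolution_counts(circumference: float, height: float, edge_length: float,
                      min_u: int = 9, min_v: int = 12):
    """Grid counts for a target mesh edge length (mm)."""
    n_v = max(min_v, int(np.ceil(circumference / edge_length)))
    n_u = max(min_u, int(np.ceil(height / edge_length)) + 1)
    return n_u, n_v
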