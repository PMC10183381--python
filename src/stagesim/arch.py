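"""Synthetic parametric maxillary half-arch (FDI 11-17).

Stand-in for patient imaging: crowns are superellipsoids, single roots are
tapered cones, molar roots are a trunk plus two diverging root cones with an
explicit furcation level.  Teeth are placed along an elliptical arch form
and slid along it until every interproximal gap sits strictly inside
(0, max_gap) mm.  The contralateral half is represented by mirroring
landmarks across the midsagittal plane rather than by meshing it.

Local tooth frame: x = mesiodistal (distal positive), y = buccolingual
(lingual positive), z = occlusal; the cervical margin is at local z = 0,
crowns occupy z in [0, crown_height], roots z < 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import trimesh
from scipy.optimize import brentq

from . import shapes
from .config import ArchConfig, AttachmentPlacement, ToothSpecConfig
from .errors import FrameError, GeometryError, LandmarkError, PlacementError
from .mechanics import MaterialLawBilinear, PDLFoundation
from .meshdist import SurfaceDistance, min_surface_distance, signed_gap_convex
from .transforms import RigidTransform, unit


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToothSpec:
    """Realised (jittered) per-tooth geometry parameters, mm."""

    fdi_id: int
    crown_height: float
    crown_md_width: float
    crown_bl_width: float
    root_length: float
    root_count: int = 1
    furcation_depth: Optional[float] = None
    arch_position: float = 0.0      # arc-length coordinate, mm

    def __post_init__(self):
        for name in ("crown_height", "crown_md_width", "crown_bl_width", "root_length"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"tooth {self.fdi_id}: {name} must be positive")
        if self.root_count < 1:
            raise GeometryError(f"tooth {self.fdi_id}: root_count must be >= 1")


@dataclass
class Landmarks:
    crown_point: np.ndarray
    root_point: np.ndarray
    CR: np.ndarray
    LA: np.ndarray                       # unit vector, crown_point -> CR
    cusp_points: Dict[str, np.ndarray] = field(default_factory=dict)

    def transformed(self, pose: RigidTransform) -> "Landmarks":
        return Landmarks(pose.apply(self.crown_point), pose.apply(self.root_point),
                         pose.apply(self.CR), pose.apply_vector(self.LA),
                         {k: pose.apply(v) for k, v in self.cusp_points.items()})


@dataclass
class ToothModel:
    spec: ToothSpec
    crown_mesh: trimesh.Trimesh          # local frame
    root_mesh: trimesh.Trimesh           # local frame
    pose: RigidTransform
    landmarks: Landmarks                 # local frame
    furcation_point: Optional[np.ndarray] = None     # local frame
    attachments: List[trimesh.Trimesh] = field(default_factory=list)
    distal_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    @property
    def fdi_id(self) -> int:
        return self.spec.fdi_id

    def world_landmarks(self) -> Landmarks:
        return self.landmarks.transformed(self.pose)

    def crown_world(self) -> trimesh.Trimesh:
        return _transformed_mesh(self.crown_mesh, self.pose)

    def root_world(self) -> trimesh.Trimesh:
        return _transformed_mesh(self.root_mesh, self.pose)

    def contact_mesh(self) -> Tuple[trimesh.Trimesh, np.ndarray]:
        """Crown plus attachments in the LOCAL frame and a per-face
        attachment mask."""
        meshes = [self.crown_mesh] + self.attachments
        combined = trimesh.util.concatenate(meshes) if self.attachments else self.crown_mesh
        mask = np.zeros(len(combined.faces), dtype=bool)
        mask[len(self.crown_mesh.faces):] = True
        return combined, mask

    def distal_dir_world(self) -> np.ndarray:
        return self.pose.apply_vector(self.distal_dir)


@dataclass
class FrameDefinition:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    occlusal_plane: Tuple[np.ndarray, np.ndarray]   # (point, normal)

    def to_frame(self, vectors: np.ndarray) -> np.ndarray:
        """Express world vectors in frame components."""
        R = np.stack([self.x_axis, self.y_axis, self.z_axis])
        return np.asarray(vectors, float) @ R.T


@dataclass
class ArchModel:
    teeth: List[ToothModel]              # ordered mesial -> distal (11 .. 17)
    midsagittal_plane: Tuple[np.ndarray, np.ndarray]   # (point, normal)
    frame: Optional[FrameDefinition] = None
    config: Optional[ArchConfig] = None

    def tooth(self, fdi_id: int) -> ToothModel:
        for t in self.teeth:
            if t.fdi_id == fdi_id:
                return t
        raise KeyError(f"no tooth {fdi_id} in arch")

    def apply_transform(self, T: RigidTransform) -> "ArchModel":
        """Rigidly move the whole scene (poses and the midsagittal plane)."""
        teeth = [replace(t, pose=T.compose(t.pose)) for t in self.teeth]
        p0, nm = self.midsagittal_plane
        moved = ArchModel(teeth, (T.apply(p0), T.apply_vector(nm)), None, self.config)
        moved.frame = define_frame(moved)
        return moved

    def interproximal_gaps(self) -> List[float]:
        gaps = []
        for a, b in zip(self.teeth[:-1], self.teeth[1:]):
            gaps.append(min_surface_distance(a.crown_world(), b.crown_world()))
        return gaps


def _transformed_mesh(mesh: trimesh.Trimesh, pose: RigidTransform) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=pose.apply(mesh.vertices),
                           faces=mesh.faces.copy(), process=False)


def mirror_point(point: np.ndarray, plane: Tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    p0, nm = plane
    nm = unit(nm)
    return point - 2.0 * np.dot(point - p0, nm) * nm


# --------------------------------------------------------------------------
# arch curve
# --------------------------------------------------------------------------

class ArchCurve:
    """Arc-length parameterised elliptical arch form in the z = 0 plane.

    x = A sin(theta), y = B (1 - cos(theta)); s = 0 at the midline, s grows
    distally along the right half-arch.
    """

    def __init__(self, half_width: float, depth: float, n: int = 2000):
        self.A = half_width
        self.B = depth
        theta = np.linspace(0.0, 0.75 * np.pi, n)
        dx = self.A * np.cos(theta)
        dy = self.B * np.sin(theta)
        ds = np.sqrt(dx ** 2 + dy ** 2)
        s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(theta))])
        self._theta = theta
        self._s = s

    def theta(self, s: float) -> float:
        return float(np.interp(s, self._s, self._theta))

    def point(self, s: float) -> np.ndarray:
        th = self.theta(s)
        return np.array([self.A * np.sin(th), self.B * (1.0 - np.cos(th)), 0.0])

    def tangent(self, s: float) -> np.ndarray:
        th = self.theta(s)
        return unit(np.array([self.A * np.cos(th), self.B * np.sin(th), 0.0]))

    def pose(self, s: float) -> RigidTransform:
        """Tooth placement pose: local x -> distal tangent, y -> lingual, z -> up."""
        t = self.tangent(s)
        lingual = np.array([-t[1], t[0], 0.0])
        R = np.stack([t, lingual, np.array([0.0, 0.0, 1.0])], axis=1)
        return RigidTransform(R, self.point(s))


# --------------------------------------------------------------------------
# per-tooth solid construction
# --------------------------------------------------------------------------

def _crown_mesh(spec: ToothSpec, exponent: float, mesh_size: float) -> trimesh.Trimesh:
    a = spec.crown_md_width / 2.0
    b = spec.crown_bl_width / 2.0
    c = spec.crown_height / 2.0
    circ = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    n_u, n_v = shapes.resolution_counts(circ, spec.crown_height, mesh_size)
    mesh = shapes.superellipsoid(a, b, c, e_we=exponent, e_ns=exponent,
                                 n_u=n_u, n_v=n_v)
    mesh.apply_translation([0.0, 0.0, c])
    return mesh

def _root_mesh(spec: ToothSpec, mesh_size: float):
    rx = 0.42 * spec.crown_md_width
    ry = 0.42 * spec.crown_bl_width
    circ = 2 * np.pi * max(rx, ry)
    if spec.root_count == 1:
        n_u, n_v = shapes.resolution_counts(circ, spec.root_length, mesh_size)
        mesh = shapes.tapered_cone(rx, ry, spec.root_length, n_u=n_u, n_v=n_v)
        return mesh, None
    f = spec.furcation_depth
    if f is None or f >= spec.root_length:
        raise GeometryError(f"tooth {spec.fdi_id}: invalid furcation depth")
    n_u, n_v = shapes.resolution_counts(circ, spec.root_length, mesh_size)
    trunk = shapes.frustum(rx, ry, 0.85, f, n_v=n_v)
    cone_len = spec.root_length - f
    parts = [trunk]
    for side, x0 in (("mesial", -0.22 * spec.crown_md_width),
                     ("distal", +0.22 * spec.crown_md_width)):
        cone = shapes.tapered_cone(0.45 * rx, 0.75 * ry, cone_len,
                                   apex_offset=(np.sign(x0) * 0.06 * spec.crown_md_width, 0.0),
                                   n_u=max(5, n_u // 2), n_v=max(12, n_v // 2))
        cone.apply_translation([x0, 0.0, -f])
        parts.append(cone)
    mesh = trimesh.util.concatenate(parts)
    furcation = np.array([0.0, 0.0, -f])
    return mesh, furcation


def _section_centroid(mesh: trimesh.Trimesh, z_level: float) -> np.ndarray:
    """Area centroid of the planar cross-section at local height ``z_level``."""
    sec = mesh.section(plane_origin=[0.0, 0.0, z_level], plane_normal=[0.0, 0.0, 1.0])
    if sec is None or len(sec.entities) == 0:
        raise LandmarkError(f"empty cross-section at z = {z_level:.3f}")
    planar, to_3d = sec.to_2D()
    polys = planar.polygons_full
    if len(polys) == 0:
        raise LandmarkError(f"cross-section at z = {z_level:.3f} does not close")
    area = np.array([p.area for p in polys])
    cents = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    c2 = (cents * area[:, None]).sum(axis=0) / area.sum()
    c3 = to_3d @ np.array([c2[0], c2[1], 0.0, 1.0])
    return c3[:3]


def compute_landmarks(tooth: ToothModel) -> Landmarks:
    """Landmark battery in the tooth-local frame.

    Crown point: occlusal centre (incisal-edge midpoint for incisors, cusp
    for the canine, occlusal-surface midpoint for premolars/molars; the
    parametric crowns make these coincide with the occlusal pole).  Root
    point: apex (mesial apex for multirooted teeth).  CR: cross-section
    centroid at the cervical-third root level (single root) or 1 mm above
    the furcation (multirooted).  LA: unit crown_point -> CR.
    """
    spec = tooth.spec
    crown_point = np.array([0.0, 0.0, spec.crown_height])
    # snap to an actual crown vertex (the occlusal pole is meshed exactly)
    verts = tooth.crown_mesh.vertices
    crown_point = verts[np.argmin(np.linalg.norm(verts - crown_point, axis=1))].copy()

    if spec.root_count == 1:
        root_point = np.array([0.0, 0.0, -spec.root_length])
        rverts = tooth.root_mesh.vertices
        root_point = rverts[np.argmin(np.linalg.norm(rverts - root_point, axis=1))].copy()
        level = -spec.root_length / 3.0          # cervical-third level
    else:
        if tooth.furcation_point is None:
            raise LandmarkError(f"tooth {spec.fdi_id}: multirooted without furcation point")
        apex_target = np.array([-0.28 * spec.crown_md_width, 0.0, -spec.root_length])
        rverts = tooth.root_mesh.vertices
        root_point = rverts[np.argmin(np.linalg.norm(rverts - apex_target, axis=1))].copy()
        level = tooth.furcation_point[2] + 1.0   # 1 mm above the furcation

    CR = _section_centroid(tooth.root_mesh, level)
    LA = unit(CR - crown_point)

    cusps: Dict[str, np.ndarray] = {}
    if spec.fdi_id in (16, 17):
        sd = SurfaceDistance(tooth.crown_mesh)
        a = spec.crown_md_width / 2.0
        b = spec.crown_bl_width / 2.0
        targets = {
            "distobuccal": np.array([0.55 * a, -0.55 * b, spec.crown_height]),
            "distolingual": np.array([0.55 * a, 0.55 * b, spec.crown_height]),
            "mesiobuccal": np.array([-0.55 * a, -0.55 * b, spec.crown_height]),
        }
        for name, tgt in targets.items():
            cusps[name] = sd.query(tgt[None, :])[0][0]
    return Landmarks(crown_point, root_point, CR, LA, cusps)


# --------------------------------------------------------------------------
# arch assembly
# --------------------------------------------------------------------------

def _jittered_spec(cfg: ToothSpecConfig, rng: np.random.Generator,
                   fraction: float) -> ToothSpec:
    def j(x):
        return float(x * (1.0 + fraction * rng.uniform(-1.0, 1.0))) if fraction else float(x)
    return ToothSpec(cfg.fdi_id, j(cfg.crown_height), j(cfg.crown_md_width),
                     j(cfg.crown_bl_width), j(cfg.root_length), cfg.root_count,
                     None if cfg.furcation_depth is None else j(cfg.furcation_depth))


def _crown_gap(curve: ArchCurve, crown: trimesh.Trimesh, s: float,
               prev_world: trimesh.Trimesh) -> float:
    moved = _transformed_mesh(crown, curve.pose(s))
    return signed_gap_convex(moved, prev_world)


def build_arch(config: ArchConfig, seed: int = 0) -> ArchModel:
    """Generate the synthetic half-arch; deterministic for fixed (config, seed)."""
    rng = np.random.default_rng(seed)
    curve = ArchCurve(config.curve_half_width, config.curve_depth)
    teeth: List[ToothModel] = []
    specs = [_jittered_spec(t, rng, config.jitter_fraction)
             for t in sorted(config.teeth, key=lambda t: t.fdi_id)]

    prev_world: Optional[trimesh.Trimesh] = None
    prev_s = 0.0
    for k, spec in enumerate(specs):
        crown = _crown_mesh(spec, config.crown_exponent, config.mesh_size)
        root, furcation = _root_mesh(spec, config.mesh_size)
        if not crown.is_watertight or not root.is_watertight:
            raise GeometryError(f"tooth {spec.fdi_id}: generated mesh is not watertight")

        half_md = spec.crown_md_width / 2.0
        if k == 0:
            # mesial crown face sits target_gap/2 from the midsagittal plane
            def f0(s):
                moved = _transformed_mesh(crown, curve.pose(s))
                return float(moved.vertices[:, 0].min()) - config.target_gap / 2.0
            s = brentq(f0, 0.5 * half_md, 2.5 * half_md, xtol=1e-6)
        else:
            prev_half = specs[k - 1].crown_md_width / 2.0
            nominal = prev_s + prev_half + half_md

            def fg(s):
                return _crown_gap(curve, crown, s, prev_world) - config.target_gap
            lo, hi = nominal - 1.5, nominal + 2.0
            while fg(lo) > 0 and lo > prev_s:
                lo -= 0.5
            while fg(hi) < 0:
                hi += 0.5
            s = brentq(fg, lo, hi, xtol=1e-5)

        pose = curve.pose(s)
        spec = replace(spec, arch_position=float(s))
        tooth = ToothModel(spec, crown, root, pose, None, furcation,
                           distal_dir=np.array([1.0, 0.0, 0.0]))
        tooth.landmarks = compute_landmarks(tooth)
        teeth.append(tooth)
        prev_world = _transformed_mesh(crown, pose)
        prev_s = s

    arch = ArchModel(teeth, (np.zeros(3), np.array([1.0, 0.0, 0.0])), None,
                     config.model_copy(deep=True))
    for g in arch.interproximal_gaps():
        if not (0.0 < g < config.max_gap):
            raise GeometryError(f"interproximal gap {g:.4f} mm outside (0, {config.max_gap})")
    arch.frame = define_frame(arch)
    return arch


# --------------------------------------------------------------------------
# attachments
# --------------------------------------------------------------------------

def build_attachments(arch: ArchModel, plan: List[AttachmentPlacement]) -> ArchModel:
    """Add rectangular attachments to buccal crown faces (in place, returned).

    Long axis: occluso-gingival for ``vertical``, mesiodistal for
    ``horizontal``; the prism protrudes ``depth`` off the face, tangent to
    the crown at the face-centre point.
    """
    for placement in plan:
        tooth = arch.tooth(placement.tooth)
        spec = tooth.spec
        limit = spec.crown_height if placement.orientation == "vertical" else spec.crown_md_width
        if placement.length > 0.9 * limit:
            raise PlacementError(
                f"tooth {placement.tooth}: {placement.orientation} attachment of "
                f"length {placement.length} mm exceeds the crown face")
        # face-centre point on the buccal surface (local -y direction)
        target = np.array([0.0, -spec.crown_bl_width, placement.height_fraction * spec.crown_height])
        sd = SurfaceDistance(tooth.crown_mesh)
        closest, _, fidx = sd.query(target[None, :])
        p = closest[0]
        n = unit(tooth.crown_mesh.face_normals[fidx[0]])
        # rectangular attachments are milled square to the occlusal plane:
        # use the horizontal projection of the face normal
        n = unit(np.array([n[0], n[1], 0.0]))

        if placement.orientation == "vertical":
            long_axis = np.array([0.0, 0.0, 1.0])
        else:
            long_axis = np.array([1.0, 0.0, 0.0])
        long_axis = unit(long_axis - np.dot(long_axis, n) * n)
        short_axis = np.cross(n, long_axis)

        prism = shapes.box([placement.length, placement.width, placement.depth])
        R = np.stack([long_axis, short_axis, n], axis=1)
        prism.apply_transform(RigidTransform(R, p + n * placement.depth / 2.0).matrix())
        tooth.attachments.append(prism)
    return arch


# --------------------------------------------------------------------------
# coordinate frame
# --------------------------------------------------------------------------

def define_frame(arch: ArchModel) -> FrameDefinition:
    """Occlusal coordinate frame from mirrored landmarks.

    Origin: midpoint of the central incisors (incisal-edge midpoint of 11
    and its midsagittal mirror).  X: along the line of the two first-molar
    mesiobuccal cusps (mirrored pair), toward the modelled side.  Occlusal
    plane: through both cusps and the origin; Z its occlusally-directed
    normal; Y = Z x X (posterior).
    """
    incisor = arch.tooth(11).world_landmarks().crown_point
    molar = arch.tooth(16).world_landmarks()
    if "mesiobuccal" not in molar.cusp_points:
        raise FrameError("first molar lacks a mesiobuccal cusp landmark")
    cusp = molar.cusp_points["mesiobuccal"]
    origin = 0.5 * (incisor + mirror_point(incisor, arch.midsagittal_plane))
    cusp_m = mirror_point(cusp, arch.midsagittal_plane)

    v1 = cusp - origin
    v2 = cusp_m - origin
    normal = np.cross(v1, v2)
    if np.linalg.norm(normal) < 1e-9 or np.linalg.norm(cusp - cusp_m) < 1e-9:
        raise FrameError("degenerate (collinear) frame landmarks")
    z_axis = unit(normal)
    # orient occlusally: along the mean crown-ward direction of the dentition
    hint = np.zeros(3)
    for t in arch.teeth:
        lm = t.world_landmarks()
        hint += lm.crown_point - lm.CR
    if np.dot(z_axis, hint) < 0:
        z_axis = -z_axis
    x_axis = unit(cusp - cusp_m)
    x_axis = unit(x_axis - np.dot(x_axis, z_axis) * z_axis)
    y_axis = np.cross(z_axis, x_axis)
    return FrameDefinition(origin, x_axis, y_axis, z_axis, (origin, z_axis))


# --------------------------------------------------------------------------
# PDL foundation sampling
# --------------------------------------------------------------------------

def build_pdl_foundation(tooth: ToothModel, thickness: float = 0.30,
                         law: Optional[MaterialLawBilinear] = None,
                         shear_fraction: float = 0.5) -> PDLFoundation:
    """Sample the root surface into PDL support points (tooth-local frame).

    Support points are root-mesh face centroids with outward face normals
    and face areas as tributary areas; coronally-facing cap faces at the
    cervical margin are excluded (they face the crown, not the socket).
    """
    if thickness <= 0:
        raise GeometryError("PDL thickness must be positive")
    mesh = tooth.root_mesh
    normals = mesh.face_normals
    centroids = mesh.triangles.mean(axis=1)
    keep = normals[:, 2] <= 0.9
    if not np.any(keep):
        raise GeometryError("PDL sampling is empty")
    return PDLFoundation(centroids[keep], normals[keep],
                         mesh.area_faces[keep], thickness,
                         law or MaterialLawBilinear(), shear_fraction)
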