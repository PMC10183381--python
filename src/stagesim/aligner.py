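"""Clear-aligner shell model and the temperature-changing staging deformation.

The aligner is represented by its inner surface: the union of the crown
(plus attachment) surfaces above a gingival trim plane, so before any
activation the inner surface coincides with the crowns it covers.  The
0.7 mm shell thickness and the 1500 MPa modulus enter through the lumped
contact stiffness, not through a meshed shell volume.

Interdental staging uses the temperature-changing method (TCM): a band of
width d (2 mm, 1 mm mesial + 1 mm distal of the interdental centre point
P_c) expands along the crown-centre line C_i - C_j by a preset quantity
U = k (d + sum_delta) t per step, i.e. the equivalent thermal strain is
k t = U / (d + sum_delta).  The displacement ramps linearly across the
band; everything distal of the band is carried along rigidly, everything
mesial is untouched.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import trimesh
from shapely.geometry import LineString, MultiPoint, Point

from .arch import ArchModel, ToothModel
from .errors import AlignerBuildError, BandError, RefitError
from .transforms import RigidTransform, unit


@dataclass(frozen=True)
class TCMParams:
    """Preset deformation quantity per staging step (mm)."""

    U: float = 0.1

    def __post_init__(self):
        if self.U < 0:
            raise ValueError("U must be non-negative")


@dataclass
class BandDefinition:
    """Interdental deformation band between two adjacent teeth."""

    mesial_tooth: int
    distal_tooth: int
    C_i: np.ndarray
    C_j: np.ndarray
    P_i: np.ndarray
    P_j: np.ndarray
    P_c: np.ndarray
    direction: np.ndarray           # unit, along C_i -> C_j
    d: float = 2.0                  # band width, mm
    delta_sum: float = 0.0          # cumulative deformation of previous steps
    b_mesial: float = 0.0           # projection of the fixed mesial boundary
    kt_history: List[float] = field(default_factory=list)
    member_idx: np.ndarray = field(default_factory=lambda: np.array([], int))
    _witness_mesial: np.ndarray = field(default_factory=lambda: np.array([], int))
    _witness_distal: np.ndarray = field(default_factory=lambda: np.array([], int))
    _width0: float = 0.0

    @property
    def band_interval(self) -> Tuple[float, float]:
        """Current band interval along ``direction`` (widens with delta_sum)."""
        return self.b_mesial, self.b_mesial + self.d + self.delta_sum


class AlignerModel:
    """Aligner inner surface with per-vertex provenance for contact and refit.

    ``vertices`` are always in the current world frame; ``pose`` records the
    accumulated wear-in (refit) motion relative to the build frame.
    """

    def __init__(self, vertices, faces, vert_tooth, vert_local, face_tooth,
                 face_attachment, face_local_centroid, face_local_normal,
                 face_area, thickness: float = 0.7, elastic_modulus: float = 1500.0,
                 poisson: float = 0.30):
        self.vertices = np.asarray(vertices, float).copy()
        self.faces = np.asarray(faces, int)
        self.vert_tooth = np.asarray(vert_tooth, int)
        self.vert_local = np.asarray(vert_local, float)
        self.face_tooth = np.asarray(face_tooth, int)
        self.face_attachment = np.asarray(face_attachment, bool)
        self.face_local_centroid = np.asarray(face_local_centroid, float)
        self.face_local_normal = np.asarray(face_local_normal, float)
        self.face_area = np.asarray(face_area, float)
        self.thickness = float(thickness)
        self.elastic_modulus = float(elastic_modulus)
        self.poisson = float(poisson)
        self.bands: List[BandDefinition] = []
        self.pose = RigidTransform.identity()
        self.last_refit_residuals: List[float] = []

    # -- geometry ----------------------------------------------------------

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def as_mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.faces.copy(), process=False)

    @property
    def area(self) -> float:
        return float(self.face_area.sum())

    def covered_teeth(self) -> List[int]:
        return sorted(set(int(t) for t in np.unique(self.face_tooth)))

    # -- band bookkeeping ---------------------------------------------------

    def band_width(self, band: BandDefinition) -> float:
        p = self.vertices @ band.direction
        return float(p[band._witness_distal].min() - p[band._witness_mesial].max())

    def band_width_increase(self, band: BandDefinition) -> float:
        return self.band_width(band) - band._width0


def build_aligner(arch: ArchModel, thickness: float = 0.7,
                  elastic_modulus: float = 1500.0, poisson: float = 0.30,
                  trim_fraction: Optional[float] = None) -> AlignerModel:
    """Generate the aligner inner surface from the current crown geometry.

    Faces below the gingival trim plane (a per-tooth local height,
    ``trim_fraction`` x crown height) are dropped; face identity with the
    generating crown faces is preserved, which is what makes small-sliding
    contact pairing and the wear-in registration exact.
    """
    if thickness <= 0:
        raise AlignerBuildError("aligner thickness must be positive")
    if trim_fraction is None:
        trim_fraction = arch.config.gingival_trim_fraction if arch.config is not None else 0.35

    all_v, all_f = [], []
    vt, vl, ft, fa, flc, fln, far = [], [], [], [], [], [], []
    offset = 0
    for tooth in arch.teeth:
        local, att_mask = tooth.contact_mesh()
        z0 = trim_fraction * tooth.spec.crown_height
        centroids = local.triangles.mean(axis=1)
        keep = centroids[:, 2] >= z0
        if not np.any(keep):
            raise AlignerBuildError(f"tooth {tooth.fdi_id}: trim plane removes the whole crown")
        faces = local.faces[keep]
        used = np.unique(faces)
        remap = -np.ones(len(local.vertices), dtype=int)
        remap[used] = np.arange(len(used))
        v_local = local.vertices[used]
        all_v.append(tooth.pose.apply(v_local))
        all_f.append(remap[faces] + offset)
        offset += len(used)
        vt.append(np.full(len(used), tooth.fdi_id))
        vl.append(v_local)
        ft.append(np.full(keep.sum(), tooth.fdi_id))
        fa.append(att_mask[keep])
        flc.append(centroids[keep])
        fln.append(local.face_normals[keep])
        far.append(local.area_faces[keep])

    return AlignerModel(np.vstack(all_v), np.vstack(all_f), np.concatenate(vt),
                        np.vstack(vl), np.concatenate(ft), np.concatenate(fa),
                        np.vstack(flc), np.vstack(fln), np.concatenate(far),
                        thickness, elastic_modulus, poisson)


# --------------------------------------------------------------------------
# band definition
# --------------------------------------------------------------------------

def _project_to_plane(points: np.ndarray, origin: np.ndarray, ex: np.ndarray,
                      ey: np.ndarray) -> np.ndarray:
    rel = np.atleast_2d(points) - origin
    return np.stack([rel @ ex, rel @ ey], axis=1)


def define_band(aligner: AlignerModel, arch: ArchModel, mesial_tooth: int,
                distal_tooth: int, d: float = 2.0, delta_sum: float = 0.0,
                witness_window: float = 1.0) -> BandDefinition:
    """Construct the interdental TCM band between two adjacent teeth.

    Crown centre points C_i, C_j are crown centroids projected to the
    occlusal plane; P_i, P_j are the crown-outline intersections with the
    segment C_i-C_j (occlusal view, convex outline); P_c is their midpoint.
    Band membership: aligner vertices whose projection on the C_i -> C_j
    direction falls within +-(d + delta_sum)/2 of P_c, where ``delta_sum``
    is the accumulated expansion already present in the geometry the band
    is defined on (zero on a pristine shell, so the zone is +-d/2 of P_c).
    """
    ids = [t.fdi_id for t in arch.teeth]
    ia, ib = ids.index(mesial_tooth), ids.index(distal_tooth)
    if abs(ia - ib) != 1:
        raise BandError(f"teeth {mesial_tooth} and {distal_tooth} are not adjacent")
    frame = arch.frame
    origin, ez = frame.occlusal_plane
    ex, ey = frame.x_axis, frame.y_axis

    def occlusal(tooth: ToothModel):
        verts = tooth.pose.apply(tooth.crown_mesh.vertices)
        pts2 = _project_to_plane(verts, origin, ex, ey)
        hull = MultiPoint(pts2).convex_hull
        c2 = pts2.mean(axis=0)
        return c2, hull

    c_i2, hull_i = occlusal(arch.tooth(mesial_tooth))
    c_j2, hull_j = occlusal(arch.tooth(distal_tooth))
    seg = LineString([c_i2, c_j2])

    def margin(hull, towards):
        inter = seg.intersection(hull.exterior)
        if inter.is_empty:
            raise BandError("crown-centre segment misses the crown outline")
        pts = [inter] if isinstance(inter, Point) else list(inter.geoms)
        pts = [np.array([p.x, p.y]) for p in pts]
        return min(pts, key=lambda p: np.linalg.norm(p - towards))

    p_i2 = margin(hull_i, c_j2)
    p_j2 = margin(hull_j, c_i2)
    p_c2 = 0.5 * (p_i2 + p_j2)

    def lift(p2):
        return origin + p2[0] * ex + p2[1] * ey

    C_i, C_j = lift(c_i2), lift(c_j2)
    P_i, P_j, P_c = lift(p_i2), lift(p_j2), lift(p_c2)
    direction = unit(C_j - C_i)

    p = aligner.vertices @ direction
    c = float(P_c @ direction)
    width = d + delta_sum
    b_m, b_d = c - width / 2.0, c + width / 2.0
    member = (p >= b_m) & (p <= b_d)
    if not np.any(member):
        raise BandError("no aligner vertices fall inside the band")
    wit_m = np.flatnonzero((p < b_m) & (p >= b_m - witness_window))
    wit_d = np.flatnonzero((p > b_d) & (p <= b_d + witness_window))
    if len(wit_m) == 0 or len(wit_d) == 0:
        raise BandError("band has no flanking aligner material to measure against")

    band = BandDefinition(mesial_tooth, distal_tooth, C_i, C_j, P_i, P_j, P_c,
                          direction, d=d, delta_sum=delta_sum, b_mesial=float(b_m),
                          member_idx=np.flatnonzero(member),
                          _witness_mesial=wit_m, _witness_distal=wit_d)
    band._width0 = aligner.band_width(band)
    aligner.bands.append(band)
    return band


# --------------------------------------------------------------------------
# TCM step
# --------------------------------------------------------------------------

def apply_tcm_step(aligner: AlignerModel, band: BandDefinition,
                   params: TCMParams = TCMParams()) -> AlignerModel:
    """Apply one TCM expansion step of magnitude ``params.U`` to the band.

    Displacement is along ``band.direction`` only, ramping linearly from 0
    at the mesial band boundary to U at the distal one; the aligner distal
    of the band translates rigidly by U.  ``delta_sum`` accumulates and the
    equivalent thermal strain k t = U / (d + sum_delta) is recorded.
    """
    if params.U < 0:
        raise ValueError("TCM step U must be non-negative")
    if len(band.member_idx) == 0:
        raise BandError("band has no member vertices")
    if params.U == 0:
        return aligner
    width = band.d + band.delta_sum
    band.kt_history.append(params.U / width)

    p = aligner.vertices @ band.direction
    ramp = np.clip((p - band.b_mesial) / width, 0.0, 1.0)
    aligner.vertices += (params.U * ramp)[:, None] * band.direction
    band.delta_sum += params.U
    return aligner


# --------------------------------------------------------------------------
# wear-in (best-fit) registration
# --------------------------------------------------------------------------

def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tc - R @ sc)


def refit_aligner(aligner: AlignerModel, arch: ArchModel,
                  max_iterations: int = 3, tol: float = 1e-10) -> RigidTransform:
    """Rigid wear-in registration of the aligner to the current crowns.

    Least-squares over non-band vertex correspondences (each aligner vertex
    against its generating crown point at the tooth's current pose), with
    the midsagittal front end constrained against translation across the
    midsagittal plane.  Returns the total applied transform; the aligner's
    vertices and pose are updated.
    """
    poses = {t.fdi_id: t.pose for t in arch.teeth}
    in_band = np.zeros(len(aligner.vertices), dtype=bool)
    for band in aligner.bands:
        p = aligner.vertices @ band.direction
        lo, hi = band.band_interval
        in_band |= (p >= lo) & (p <= hi)
    free = ~in_band
    if free.sum() < 3:
        raise RefitError("too few non-band vertices for registration")

    target = np.empty_like(aligner.vertices)
    for fdi, pose in poses.items():
        m = aligner.vert_tooth == fdi
        target[m] = pose.apply(aligner.vert_local[m])

    p0, nm = arch.midsagittal_plane
    nm = unit(nm)
    front_idx = int(np.argmin(np.abs((aligner.vertices - p0) @ nm)))

    total = RigidTransform.identity()
    residuals = []
    src = aligner.vertices
    def rms(v):
        return float(np.sqrt(np.mean(np.linalg.norm(v, axis=1) ** 2)))

    residuals.append(rms(src[free] - target[free]))
    for _ in range(max_iterations):
        T = _kabsch(src[free], target[free])
        # suppress translation of the front end across the midsagittal plane
        pf = src[front_idx]
        slip = float((T.apply(pf) - pf) @ nm)
        T = RigidTransform(T.rotation, T.translation - slip * nm)
        src = T.apply(src)
        total = T.compose(total)
        res = rms(src[free] - target[free])
        residuals.append(res)
        if abs(residuals[-2] - res) < tol:
            break
    if residuals[-1] > residuals[0] + 1e-9:
        raise RefitError(f"registration residual increased: {residuals}")
    aligner.vertices = src
    aligner.pose = total.compose(aligner.pose)
    aligner.last_refit_residuals = residuals
    return total
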