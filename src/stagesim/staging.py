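"""The 4D staging driver.

Each staging step (stage) corresponds to one aligner in the series and two
weeks of wear: the previous aligner is deleted, a fresh shell is
regenerated from the current crown geometry, one new interdental TCM step
of the preset quantity U = 0.1 mm is applied over the accumulated
deformation zone (width d + Sigma-Delta, per the thermal-expansion
formula), and the shell is best-fit and elastically seated on the
dentition (wear-in).  Two bone-remodeling iterations then run, each
standing for one week of wear, with the wear-in repeated before each
iteration:

  phase 1  solve quasi-static equilibrium of every rigid tooth on its PDL
           foundation under aligner contact, and move the teeth by the
           resulting screw displacements (capped at the physiologic rate
           ceiling per week);
  phase 2  restore the PDL to its reference 0.30 mm configuration around
           the displaced roots (strains zeroed, poses untouched).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import kinematics as kin
from .aligner import AlignerModel, BandDefinition, TCMParams, apply_tcm_step, \
    build_aligner, define_band, refit_aligner
from .arch import ArchModel, build_arch, build_attachments, build_pdl_foundation
from .config import RunConfig, StagePlanConfig as StagePlan
from .errors import StageSimError
from .mechanics import ContactSet, EquilibriumSolution, ForceSystem, \
    MaterialLawBilinear, PDLFoundation, ToothSystem, WallContact, solve_equilibrium
from .transforms import RigidTransform, unit

__all__ = ["StagePlan", "SimulationState", "StageRecord", "Trajectory",
           "initialize_state", "make_contacts", "phase1_load_step",
           "phase2_pdl_reset", "run_stage", "run_plan"]


@dataclass
class StageRecord:
    stage: int
    elapsed_weeks: float
    delta_sum: float
    poses: Dict[int, RigidTransform]
    offtrack: Dict[str, float]
    residuals: Dict[int, float]
    iterations: Dict[int, int]
    peak_pdl_strain: Dict[int, float]
    forces: Dict[int, ForceSystem]
    aligner_reaction: Optional[ForceSystem] = None


@dataclass
class Trajectory:
    arch: ArchModel
    baseline_poses: Dict[int, RigidTransform]
    frame: object
    distal_dirs: Dict[int, np.ndarray]
    plan: StagePlan
    config: RunConfig
    records: List[StageRecord] = field(default_factory=list)

    def hash(self) -> str:
        h = hashlib.sha256()
        for rec in self.records:
            for fdi in sorted(rec.poses):
                h.update(rec.poses[fdi].rotation.tobytes())
                h.update(rec.poses[fdi].translation.tobytes())
        return h.hexdigest()


@dataclass
class SimulationState:
    config: RunConfig
    arch: ArchModel
    stage_index: int = 0
    iteration_index: int = 0
    elapsed_weeks: float = 0.0
    delta_sum: float = 0.0
    aligner: Optional[AlignerModel] = None
    band: Optional[BandDefinition] = None
    foundations: Dict[int, PDLFoundation] = field(default_factory=dict)
    offtrack_correspondence: Dict[str, int] = field(default_factory=dict)
    last_solution: Optional[EquilibriumSolution] = None
    trajectory: Optional[Trajectory] = None

    def pdl_law(self) -> MaterialLawBilinear:
        m = self.config.materials
        return MaterialLawBilinear(m.pdl_e1, m.pdl_e2, m.pdl_strain_threshold)


def initialize_state(config: RunConfig, seed: Optional[int] = None) -> SimulationState:
    """Build the arch (with attachments), PDL foundations and the baseline
    trajectory bookkeeping."""
    seed = config.seed if seed is None else seed
    arch = build_arch(config.arch, seed=seed)
    build_attachments(arch, config.attachments)
    state = SimulationState(config=config, arch=arch)
    phase2_pdl_reset(state)
    state.trajectory = Trajectory(
        arch=arch,
        baseline_poses={t.fdi_id: t.pose for t in arch.teeth},
        frame=arch.frame,
        distal_dirs={t.fdi_id: t.distal_dir_world() for t in arch.teeth},
        plan=config.plan, config=config)
    return state


# --------------------------------------------------------------------------
# contact assembly
# --------------------------------------------------------------------------

def make_contacts(aligner: AlignerModel, arch: ArchModel,
                  config: RunConfig) -> ContactSet:
    """Small-sliding contact pairs for the current stage.

    Each aligner inner-surface face centroid is paired with its generating
    crown face at the tooth's current pose; the signed gap is measured along
    the crown outward normal.  Attachment-region pairs carry the configured
    stiffness multiplier (attachments are rigid relative to the shell).
    """
    m = config.materials
    poses = {t.fdi_id: t.pose for t in arch.teeth}
    a = aligner.face_centroids()
    c = np.empty_like(a)
    n = np.empty_like(a)
    for fdi, pose in poses.items():
        msk = aligner.face_tooth == fdi
        c[msk] = pose.apply(aligner.face_local_centroid[msk])
        n[msk] = pose.apply_vector(aligner.face_local_normal[msk])
    stiff = np.where(aligner.face_attachment,
                     m.contact_stiffness * m.attachment_stiffness_multiplier,
                     m.contact_stiffness)
    return ContactSet(a, c, n, aligner.face_area, stiff, aligner.face_tooth,
                      mu=m.friction, clearance=m.contact_clearance)


def _midsagittal_wall(state: SimulationState) -> Optional[WallContact]:
    if not state.config.solver.midsagittal_wall:
        return None
    arch = state.arch
    tooth = arch.teeth[0]
    p0, nm = arch.midsagittal_plane
    nm = unit(nm)
    mesh = tooth.crown_mesh
    normals = tooth.pose.apply_vector(mesh.face_normals)
    centroids = tooth.pose.apply(mesh.triangles.mean(axis=1))
    sel = (normals @ (-nm) > 0.5)
    if not np.any(sel):
        return None
    return WallContact(points=centroids[sel], areas=mesh.area_faces[sel],
                       normal=nm, offset=float(nm @ p0),
                       stiffness=state.config.materials.contact_stiffness)


def seat_aligner(state: SimulationState, tol: float = 1e-10,
                 max_iterations: int = 60) -> RigidTransform:
    """Elastic seating: rigid 6-DOF equilibrium of the shell on its contact
    springs with the teeth held fixed.

    The geometric best fit leaves the shell where squared distances are
    minimal; seating moves it to where the contact forces balance, which is
    what distributes the interdental activation between the target molar
    and the anchorage unit.  Seating is frictionless (repeated insertion)
    and restricted to occlusal-plane motions (in-plane translation plus
    rotation about the occlusal normal): the vertical pose is imposed by
    the wearer pressing the appliance home (the geometric best fit), and
    without that restriction a trimmed shell on convergent crowns has its
    energy minimum at lift-off.  The front end is additionally constrained
    exactly against motion across the midsagittal plane.
    """
    aligner = state.aligner
    contacts = make_contacts(aligner, state.arch, state.config)
    G = aligner.vertices.mean(axis=0)
    r = contacts.aligner_points - G
    n = contacts.normals
    kA = contacts.stiffness * contacts.areas
    # gap(xi) = gap0 + A xi with xi = [u; theta] about G
    A = np.hstack([n, np.cross(r, n)])
    gap0 = contacts.gaps.copy() + contacts.clearance

    p0, nm = state.arch.midsagittal_plane
    nm = unit(nm)
    pf = aligner.vertices[int(np.argmin(np.abs((aligner.vertices - p0) @ nm)))]
    a_con = np.concatenate([nm, np.cross(pf - G, nm)])
    # admissible motions: occlusal-plane translations + rotation about the
    # occlusal normal, restricted to the midsagittal constraint's null space
    frame = state.arch.frame
    C = np.zeros((6, 3))
    C[:3, 0] = frame.x_axis
    C[:3, 1] = frame.y_axis
    C[3:, 2] = frame.z_axis
    a_red = a_con @ C
    _, _, Vt = np.linalg.svd(a_red[None, :])
    N = C @ Vt[1:].T                                     # (6, 2)

    xi = np.zeros(6)
    for _ in range(max_iterations):
        gap = gap0 + A @ xi
        pen = np.maximum(0.0, -gap)
        grad = -(A.T @ (kA * pen))                       # dE/dxi
        g_red = N.T @ grad
        if np.linalg.norm(g_red) < tol:
            break
        act = pen > 0
        H = (A[act] * (kA[act])[:, None]).T @ A[act]
        H_red = N.T @ H @ N + 1e-12 * np.eye(N.shape[1])
        try:
            step = N @ np.linalg.solve(H_red, -g_red)
        except np.linalg.LinAlgError:
            break
        # line search on the seating energy
        def energy(x):
            return 0.5 * float(kA @ np.maximum(0.0, -(gap0 + A @ x)) ** 2)
        e0, s = energy(xi), 1.0
        for _ in range(30):
            if energy(xi + s * step) <= e0 or s < 1e-8:
                break
            s *= 0.5
        if s < 1e-8:
            break
        xi = xi + s * step

    if np.allclose(xi, 0.0):
        return RigidTransform.identity()
    T = RigidTransform.about_point(xi[3:], G, xi[:3])
    aligner.vertices = T.apply(aligner.vertices)
    aligner.pose = T.compose(aligner.pose)
    return T


# --------------------------------------------------------------------------
# the two remodeling phases
# --------------------------------------------------------------------------

def phase1_load_step(state: SimulationState) -> SimulationState:
    """Load phase: solve equilibrium and move each tooth by its screw
    displacement, capped at the weekly rate ceiling."""
    if state.aligner is None:
        raise StageSimError("no aligner fitted; run a stage set-up first")
    cfg = state.config
    contacts = make_contacts(state.aligner, state.arch, cfg)
    wall = _midsagittal_wall(state)
    systems = []
    for tooth in state.arch.teeth:
        fdi = tooth.fdi_id
        systems.append(ToothSystem(
            tooth_id=fdi,
            CR=tooth.pose.apply(tooth.landmarks.CR),
            foundation=state.foundations[fdi],
            contacts=contacts.for_tooth(fdi),
            wall=wall if tooth is state.arch.teeth[0] else None))
    sol = solve_equilibrium(systems, cfg.solver.tol_force, cfg.solver.tol_moment,
                            cfg.solver.max_iterations)

    plan = cfg.plan
    cap = plan.displacement_cap
    for tooth in state.arch.teeth:
        fdi = tooth.fdi_id
        x = sol.displacements[fdi]
        if plan.strain_gating and sol.peak_pdl_strain[fdi] < plan.strain_gate:
            sol.displacements[fdi] = np.zeros(6)
            continue
        u_norm = np.linalg.norm(x[:3])
        if u_norm > cap:
            x = x * (cap / u_norm)
            sol.displacements[fdi] = x
        if u_norm == 0 and np.linalg.norm(x[3:]) == 0:
            continue
        CR = tooth.pose.apply(tooth.landmarks.CR)
        delta = RigidTransform.about_point(x[3:], CR, x[:3])
        tooth.pose = delta.compose(tooth.pose)
    state.last_solution = sol
    state.iteration_index += 1
    state.elapsed_weeks += plan.weeks_per_iteration
    return state


def phase2_pdl_reset(state: SimulationState) -> SimulationState:
    """Remodeling phase: rebuild every PDL foundation at its reference
    thickness around the displaced root; tooth poses untouched.  Idempotent."""
    m = state.config.materials
    law = state.pdl_law()
    for tooth in state.arch.teeth:
        pdl_local = build_pdl_foundation(tooth, m.pdl_thickness, law, m.shear_fraction)
        state.foundations[tooth.fdi_id] = pdl_local.transformed(tooth.pose)
    return state


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _mesial_neighbour(arch: ArchModel, fdi: int) -> int:
    ids = [t.fdi_id for t in arch.teeth]
    i = ids.index(fdi)
    if i == 0:
        raise StageSimError(f"tooth {fdi} has no mesial neighbour")
    return ids[i - 1]


def setup_stage(state: SimulationState) -> SimulationState:
    """Regenerate the aligner from the current dentition and wear it in.

    The previous shell is discarded; a fresh one is built as the offset of
    the current crowns.  The accumulated expansion of earlier steps,
    Sigma-Delta = (steps applied) x U, is already present in that geometry
    (the interdental span has widened by the expressed movement), so the
    new step applies the preset quantity U over the widened deformation
    zone of width d + Sigma-Delta, with equivalent thermal strain
    k t = U / (d + Sigma-Delta).  Activation a step fails to express is not
    replayed: the next shell starts from wherever the teeth actually are.
    """
    cfg = state.config
    plan = cfg.plan
    m = cfg.materials
    aligner = build_aligner(state.arch, thickness=m.aligner_thickness,
                            elastic_modulus=m.aligner_modulus, poisson=m.poisson)
    band = define_band(aligner, state.arch,
                       _mesial_neighbour(state.arch, plan.target_tooth),
                       plan.target_tooth, d=plan.band_width,
                       delta_sum=state.delta_sum)
    apply_tcm_step(aligner, band, TCMParams(plan.step_size))
    refit_aligner(aligner, state.arch)
    state.aligner = aligner
    state.band = band
    state.delta_sum = band.delta_sum
    seat_aligner(state)

    # freeze cusp <-> inner-surface correspondence for the off-track metric
    target = state.arch.tooth(plan.target_tooth)
    lm = target.world_landmarks()
    state.offtrack_correspondence = {}
    vert_sel = np.flatnonzero(aligner.vert_tooth == plan.target_tooth)
    for name in ("distobuccal", "distolingual"):
        if name not in lm.cusp_points:
            continue
        d = np.linalg.norm(aligner.vertices[vert_sel] - lm.cusp_points[name], axis=1)
        state.offtrack_correspondence[name] = int(vert_sel[np.argmin(d)])
    return state


def run_stage(state: SimulationState, plan: Optional[StagePlan] = None) -> SimulationState:
    """Execute one full staging step (aligner regeneration + TCM + wear-in +
    ``iterations_per_stage`` remodeling iterations) and record it."""
    plan = plan or state.config.plan
    if state.stage_index >= plan.n_stages:
        raise StageSimError(f"plan exhausted after {plan.n_stages} stages")
    setup_stage(state)
    for k in range(plan.iterations_per_stage):
        if k > 0:
            refit_aligner(state.aligner, state.arch)   # wear-in before each iteration
            seat_aligner(state)
        phase1_load_step(state)
        phase2_pdl_reset(state)
    state.stage_index += 1

    sol = state.last_solution
    record = StageRecord(
        stage=state.stage_index,
        elapsed_weeks=state.elapsed_weeks,
        delta_sum=state.delta_sum,
        poses={t.fdi_id: t.pose for t in state.arch.teeth},
        offtrack=kin.offtrack_gap(state) if state.offtrack_correspondence else {},
        residuals=dict(sol.residuals) if sol else {},
        iterations=dict(sol.iterations) if sol else {},
        peak_pdl_strain=dict(sol.peak_pdl_strain) if sol else {},
        forces=dict(sol.forces) if sol else {},
        aligner_reaction=sol.aligner_reaction if sol else None)
    if state.trajectory is not None:
        state.trajectory.records.append(record)
    return state


def run_plan(plan: Optional[StagePlan] = None, config: Optional[RunConfig] = None,
             seed: Optional[int] = None) -> Trajectory:
    """Run the full staging plan and return the recorded trajectory.

    On a stage failure the partial trajectory is attached to the raised
    error (``exc.trajectory``).
    """
    config = config or RunConfig()
    if plan is not None:
        config = config.model_copy(update={"plan": plan})
    state = initialize_state(config, seed=seed)
    try:
        for _ in range(config.plan.n_stages):
            run_stage(state)
    except StageSimError as exc:
        exc.trajectory = state.trajectory
        raise
    return state.trajectory
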