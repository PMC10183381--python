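"""Quasi-static force system on rigid teeth.

Reduced-order formulation: each tooth is a rigid body supported by a
Winkler-type elastic foundation sampled over its root surface (the 0.30 mm
periodontal-ligament shell with a bilinear stress-strain law) and loaded by
unilateral penalty contact springs against the aligner's inner surface
(friction-capped, small-sliding: pairs are frozen within a stage).  The
aligner is held at its wear-in (refit) pose during a solve and acts on the
teeth only through the contact springs, so the coupled equilibrium reduces
to independent 6-DOF Newton solves per tooth.

Units: mm, N, MPa (N/mm^2); moments in N mm; strains dimensionless.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import FoundationError, SolverError
from .transforms import RigidTransform, skew


# --------------------------------------------------------------------------
# constitutive law
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialLawBilinear:
    """Bilinear (two-modulus) stress-strain law, odd-symmetric and continuous.

    sigma = e1 * eps                                   for |eps| <= threshold
    sigma = sign(eps) * (e1*thr + e2*(|eps| - thr))    otherwise
    """

    e1: float = 0.05     # MPa, tangent modulus below threshold
    e2: float = 0.22     # MPa, tangent modulus above threshold
    eps_threshold: float = 0.075

    def __post_init__(self):
        if not (self.e2 > self.e1 > 0):
            raise ValueError("require e2 > e1 > 0")

    def stress(self, strain):
        eps = np.asarray(strain, dtype=float)
        a = np.abs(eps)
        thr = self.eps_threshold
        mag = np.where(a <= thr, self.e1 * a,
                       self.e1 * thr + self.e2 * (a - thr))
        out = np.sign(eps) * mag
        return out if out.ndim else float(out)

    def tangent(self, strain):
        eps = np.asarray(strain, dtype=float)
        out = np.where(np.abs(eps) <= self.eps_threshold, self.e1, self.e2)
        return out if out.ndim else float(out)


def pdl_stress(strain, law: MaterialLawBilinear | None = None):
    """PDL stress (MPa) at the given strain under the bilinear law."""
    return (law or MaterialLawBilinear()).stress(strain)


# --------------------------------------------------------------------------
# PDL foundation
# --------------------------------------------------------------------------

@dataclass
class PDLFoundation:
    """Root-surface support-point sampling of the periodontal ligament.

    ``points`` / ``normals`` are in whatever frame they were sampled in
    (tooth-local at construction; use :meth:`transformed` for world-frame
    anchors).  ``areas`` are tributary areas (mm^2) that partition the
    sampled root surface.
    """

    points: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    reference_thickness: float = 0.30
    law: MaterialLawBilinear = field(default_factory=MaterialLawBilinear)
    shear_fraction: float = 0.5

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.normals = np.atleast_2d(np.asarray(self.normals, float))
        self.areas = np.atleast_1d(np.asarray(self.areas, float))
        if len(self.points) == 0 or self.areas.sum() <= 0:
            raise FoundationError("empty or zero-area PDL sampling")
        if np.any(self.areas <= 0):
            raise FoundationError("non-positive tributary area in PDL sampling")
        if self.reference_thickness <= 0:
            raise FoundationError("reference thickness must be positive")

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def transformed(self, pose: RigidTransform) -> "PDLFoundation":
        return PDLFoundation(pose.apply(self.points), pose.apply_vector(self.normals),
                             self.areas.copy(), self.reference_thickness,
                             self.law, self.shear_fraction)


def foundation_stiffness(pdl: PDLFoundation, CR: np.ndarray,
                         strains: Optional[np.ndarray] = None) -> np.ndarray:
    """Linearised 6x6 foundation stiffness about CR (order: [force; moment]
    vs [translation; rotation]).

    Per-point normal stiffness per area is E_tangent / thickness, tangential
    stiffness the configured fraction of it.  Symmetric PSD by construction.
    """
    n = np.asarray(pdl.normals, float)
    p = np.asarray(pdl.points, float)
    A = np.asarray(pdl.areas, float)
    h = pdl.reference_thickness
    eps = np.zeros(len(A)) if strains is None else np.asarray(strains, float)
    kn = pdl.law.tangent(eps) / h * A           # (m,)
    kt = pdl.shear_fraction * kn
    r = p - np.asarray(CR, float)

    eye = np.eye(3)
    nnT = np.einsum("mi,mj->mij", n, n)
    Kp = kn[:, None, None] * nnT + kt[:, None, None] * (eye - nnT)   # (m,3,3)

    G = -_skew_rows(r)      # d(point displacement)/d(theta) = -[r]x  (m,3,3)
    B = np.concatenate([np.broadcast_to(eye, (len(A), 3, 3)), G], axis=2)  # (m,3,6)
    K6 = np.einsum("mki,mkl,mlj->ij", B, Kp, B)
    if not np.all(np.isfinite(K6)):
        raise FoundationError("non-finite foundation stiffness")
    return K6


def _skew_rows(r: np.ndarray) -> np.ndarray:
    """Stack of cross-product matrices [r_m]x, shape (m, 3, 3)."""
    r = np.atleast_2d(r)
    S = np.zeros((len(r), 3, 3))
    S[:, 0, 1] = -r[:, 2]
    S[:, 0, 2] = r[:, 1]
    S[:, 1, 0] = r[:, 2]
    S[:, 1, 2] = -r[:, 0]
    S[:, 2, 0] = -r[:, 1]
    S[:, 2, 1] = r[:, 0]
    return S


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.cross(a, b)


# --------------------------------------------------------------------------
# contact
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactPair:
    aligner_point: np.ndarray
    crown_point: np.ndarray
    normal: np.ndarray
    gap: float
    area: float
    stiffness: float      # N/mm per mm^2 of tributary area
    mu: float = 0.2
    tooth: int = 0


class ContactSet:
    """Vectorised collection of small-sliding contact pairs for one stage."""

    def __init__(self, aligner_points, crown_points, normals, areas, stiffness,
                 tooth_ids, mu: float = 0.2, clearance: float = 0.0):
        self.aligner_points = np.atleast_2d(np.asarray(aligner_points, float))
        self.crown_points = np.atleast_2d(np.asarray(crown_points, float))
        self.normals = np.atleast_2d(np.asarray(normals, float))
        self.areas = np.atleast_1d(np.asarray(areas, float))
        self.stiffness = np.atleast_1d(np.asarray(stiffness, float))
        self.tooth_ids = np.atleast_1d(np.asarray(tooth_ids, int))
        self.mu = float(mu)
        self.clearance = float(clearance)
        d = self.aligner_points - self.crown_points
        self.gaps = np.einsum("ij,ij->i", d, self.normals)

    def __len__(self):
        return len(self.areas)

    def __getitem__(self, i) -> ContactPair:
        return ContactPair(self.aligner_points[i], self.crown_points[i],
                           self.normals[i], float(self.gaps[i]),
                           float(self.areas[i]), float(self.stiffness[i]),
                           self.mu, int(self.tooth_ids[i]))

    def for_tooth(self, tooth: int) -> "ContactSet":
        m = self.tooth_ids == tooth
        return ContactSet(self.aligner_points[m], self.crown_points[m],
                          self.normals[m], self.areas[m], self.stiffness[m],
                          self.tooth_ids[m], self.mu, self.clearance)


@dataclass
class ForceSystem:
    force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    moment_about_CR: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _contact_force_rows(contacts: ContactSet, d: np.ndarray):
    """Per-pair contact force rows for crown-point displacements ``d`` (n,3)."""
    n = contacts.normals
    kA = contacts.stiffness * contacts.areas
    gap = contacts.gaps - np.einsum("ij,ij->i", n, d)
    pen = np.maximum(0.0, -gap - contacts.clearance)
    fn_mag = kA * pen                                     # N
    f = -fn_mag[:, None] * n
    # tangential: capped penalty, no stick-slip history
    vt = d - np.einsum("ij,ij->i", n, d)[:, None] * n
    vt_norm = np.linalg.norm(vt, axis=1)
    active = (pen > 0) & (vt_norm > 1e-14)
    if np.any(active):
        ft_mag = np.minimum(contacts.mu * fn_mag[active],
                            kA[active] * vt_norm[active])
        f[active] -= (ft_mag / vt_norm[active])[:, None] * vt[active]
    return f, pen


def contact_forces(contacts: ContactSet, displacements: Dict[int, tuple],
                   CRs: Dict[int, np.ndarray]):
    """Evaluate contact force systems per tooth plus the aligner reaction.

    ``displacements`` maps tooth id -> (u, theta): CR translation (mm) and
    small rotation vector (rad).  Unlisted teeth are treated as static.
    Returns (per-tooth {id: ForceSystem}, aligner ForceSystem about the
    origin).
    """
    out: Dict[int, ForceSystem] = {}
    total_f = np.zeros(3)
    total_m = np.zeros(3)
    for tooth in np.unique(contacts.tooth_ids):
        sub = contacts.for_tooth(int(tooth))
        u, th = displacements.get(int(tooth), (np.zeros(3), np.zeros(3)))
        CR = np.asarray(CRs[int(tooth)], float)
        r = sub.crown_points - CR
        d = np.asarray(u, float) + np.cross(np.asarray(th, float), r)
        f, _ = _contact_force_rows(sub, d)
        F = f.sum(axis=0)
        M = _cross_rows(r, f).sum(axis=0)
        out[int(tooth)] = ForceSystem(F, M)
        total_f += F
        total_m += _cross_rows(sub.crown_points, f).sum(axis=0)
    reaction = ForceSystem(-total_f, -total_m)
    return out, reaction


# --------------------------------------------------------------------------
# equilibrium
# --------------------------------------------------------------------------

@dataclass
class WallContact:
    """Unilateral penalty wall (the midsagittal symmetry surface)."""

    points: np.ndarray        # crown sample points, world frame
    areas: np.ndarray
    normal: np.ndarray        # wall outward normal pointing INTO the tooth side
    offset: float             # plane: normal . x = offset
    stiffness: float = 1.0


@dataclass
class ToothSystem:
    """Everything the solver needs for one rigid tooth."""

    tooth_id: int
    CR: np.ndarray
    foundation: PDLFoundation            # world-frame anchors
    contacts: Optional[ContactSet] = None
    wall: Optional[WallContact] = None
    external_wrench: Optional[np.ndarray] = None   # (6,) [F; M about CR]


@dataclass
class EquilibriumSolution:
    displacements: Dict[int, np.ndarray]       # tooth -> (6,) [u; theta]
    forces: Dict[int, ForceSystem]             # converged contact force systems
    aligner_reaction: ForceSystem
    residuals: Dict[int, float]
    iterations: Dict[int, int]
    peak_pdl_strain: Dict[int, float]


def _pdl_residual_jacobian(sys: ToothSystem, x: np.ndarray, want_jac: bool):
    pdl = sys.foundation
    p, n, A = pdl.points, pdl.normals, pdl.areas
    h = pdl.reference_thickness
    law, s = pdl.law, pdl.shear_fraction
    u, th = x[:3], x[3:]
    r = p - sys.CR
    d = u + np.cross(th, r)

    dn = np.einsum("ij,ij->i", n, d)
    eps_n = dn / h
    t_vec = d - dn[:, None] * n
    t_norm = np.linalg.norm(t_vec, axis=1)
    eps_t = t_norm / h

    sig_n = law.stress(eps_n)
    sig_t = law.stress(eps_t)
    f = -(sig_n * A)[:, None] * n
    safe = t_norm > 1e-14
    coef = np.zeros(len(A))
    coef[safe] = s * sig_t[safe] * A[safe] / t_norm[safe]
    f -= coef[:, None] * t_vec

    F = f.sum(axis=0)
    M = _cross_rows(r, f).sum(axis=0)
    strain_peak = float(np.max(np.maximum(np.abs(eps_n), eps_t))) if len(A) else 0.0
    if not want_jac:
        return F, M, strain_peak, None

    eye = np.eye(3)
    nnT = np.einsum("mi,mj->mij", n, n)
    P = eye - nnT
    En = law.tangent(eps_n) / h * A
    Et = law.tangent(eps_t) / h * A
    dfdd = -(En[:, None, None] * nnT)
    # tangential block: secant part on (P - tt^T), tangent part on tt^T
    tt = np.zeros_like(nnT)
    tt[safe] = np.einsum("mi,mj->mij", t_vec[safe] / t_norm[safe, None],
                         t_vec[safe] / t_norm[safe, None])
    sec = np.zeros(len(A))
    sec[safe] = s * sig_t[safe] * A[safe] / (t_norm[safe])
    dfdd -= sec[:, None, None] * (P - tt)
    dfdd -= (s * Et)[:, None, None] * tt
    # unsafe (zero tangential displacement): linear limit
    dfdd[~safe] -= (s * En[~safe])[:, None, None] * P[~safe]

    return F, M, strain_peak, (r, dfdd)


def _contact_residual_jacobian(contacts: ContactSet, CR, x, want_jac: bool):
    n = contacts.normals
    kA = contacts.stiffness * contacts.areas
    u, th = x[:3], x[3:]
    r = contacts.crown_points - CR
    d = u + np.cross(th, r)
    f, pen = _contact_force_rows(contacts, d)
    F = f.sum(axis=0)
    M = _cross_rows(r, f).sum(axis=0)
    if not want_jac:
        return F, M, None

    active = pen > 0
    m = len(kA)
    dfdd = np.zeros((m, 3, 3))
    if np.any(active):
        nnT = np.einsum("mi,mj->mij", n[active], n[active])
        dfdd[active] = -(kA[active])[:, None, None] * nnT
        # friction (stick-branch Jacobian; the slip branch uses the same
        # stiffness capped implicitly via the line search)
        P = np.eye(3) - nnT
        vt = d[active] - np.einsum("ij,ij->i", n[active], d[active])[:, None] * n[active]
        vt_norm = np.linalg.norm(vt, axis=1)
        stick = kA[active] * vt_norm <= contacts.mu * kA[active] * pen[active] + 1e-30
        coef = np.where(stick, kA[active], contacts.mu * kA[active])
        dfdd[active] -= coef[:, None, None] * P
    return F, M, (r, dfdd)


def _assemble(sys: ToothSystem, x: np.ndarray, want_jac: bool):
    F, M, strain_peak, pdl_jac = _pdl_residual_jacobian(sys, x, want_jac)
    parts = [(pdl_jac, None)]
    if sys.contacts is not None and len(sys.contacts):
        Fc, Mc, c_jac = _contact_residual_jacobian(sys.contacts, sys.CR, x, want_jac)
        F = F + Fc
        M = M + Mc
        parts.append((c_jac, None))
    if sys.wall is not None and len(sys.wall.points):
        w = sys.wall
        u, th = x[:3], x[3:]
        r = w.points - sys.CR
        d = u + np.cross(th, r)
        pos = np.einsum("j,ij->i", w.normal, w.points + d) - w.offset
        pen = np.maximum(0.0, -pos)
        fw = (w.stiffness * w.areas * pen)[:, None] * w.normal
        F = F + fw.sum(axis=0)
        M = M + _cross_rows(r, fw).sum(axis=0)
        if want_jac:
            act = pen > 0
            dfdd = np.zeros((len(pen), 3, 3))
            if np.any(act):
                nnT = np.outer(w.normal, w.normal)
                dfdd[act] = -(w.stiffness * w.areas[act])[:, None, None] * nnT
            parts.append(((r, dfdd), None))
    if sys.external_wrench is not None:
        F = F + sys.external_wrench[:3]
        M = M + sys.external_wrench[3:]

    R = np.concatenate([F, M])
    if not want_jac:
        return R, strain_peak, None
    J = np.zeros((6, 6))
    for jac, _ in parts:
        if jac is None:
            continue
        r, dfdd = jac
        rx = _skew_rows(r)      # +[r]x per point
        G = -rx                 # d(point displacement)/d(theta)
        J[:3, :3] += dfdd.sum(axis=0)
        J[:3, 3:] += np.einsum("mij,mjk->ik", dfdd, G)
        # moment rows: dM = [r]x df
        J[3:, :3] += np.einsum("mij,mjk->ik", rx, dfdd)
        J[3:, 3:] += np.einsum("mij,mjk,mkl->il", rx, dfdd, G)
    return R, strain_peak, J


def solve_tooth(sys: ToothSystem, tol_force: float = 1e-4, tol_moment: float = 1e-4,
                max_iterations: int = 100):
    """Damped-Newton solve of one tooth's 6-DOF equilibrium."""
    x = np.zeros(6)
    history = []
    strain_peak = 0.0
    for it in range(max_iterations):
        R, strain_peak, J = _assemble(sys, x, want_jac=True)
        fres = np.linalg.norm(R[:3])
        mres = np.linalg.norm(R[3:])
        history.append(max(fres, mres))
        if fres < tol_force and mres < tol_moment:
            return x, max(fres, mres), it, strain_peak
        try:
            dx = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -R, rcond=None)[0]
        # backtracking line search on the residual norm
        base = np.linalg.norm(R)
        step = 1.0
        for _ in range(30):
            R_new, _, _ = _assemble(sys, x + step * dx, want_jac=False)
            if np.linalg.norm(R_new) < base * (1.0 - 1e-4 * step) or step < 1e-6:
                break
            step *= 0.5
        x = x + step * dx
    R, strain_peak, _ = _assemble(sys, x, want_jac=False)
    if max(np.linalg.norm(R[:3]), np.linalg.norm(R[3:])) < 10 * max(tol_force, tol_moment):
        return x, float(np.linalg.norm(R)), max_iterations, strain_peak
    raise SolverError(
        f"tooth {sys.tooth_id}: equilibrium not converged "
        f"(|F|={np.linalg.norm(R[:3]):.3e} N, |M|={np.linalg.norm(R[3:]):.3e} N mm)",
        residual_history=history)


def solve_equilibrium(systems: Sequence[ToothSystem], tol_force: float = 1e-4,
                      tol_moment: float = 1e-4, max_iterations: int = 100
                      ) -> EquilibriumSolution:
    """Solve every tooth's equilibrium (aligner held at its refit pose)."""
    displacements: Dict[int, np.ndarray] = {}
    residuals: Dict[int, float] = {}
    iterations: Dict[int, int] = {}
    strains: Dict[int, float] = {}
    for sys in systems:
        x, res, it, strain = solve_tooth(sys, tol_force, tol_moment, max_iterations)
        displacements[sys.tooth_id] = x
        residuals[sys.tooth_id] = res
        iterations[sys.tooth_id] = it
        strains[sys.tooth_id] = strain

    # converged contact force systems + aligner reaction
    forces: Dict[int, ForceSystem] = {}
    total_f = np.zeros(3)
    total_m = np.zeros(3)
    for sys in systems:
        if sys.contacts is None or not len(sys.contacts):
            forces[sys.tooth_id] = ForceSystem()
            continue
        x = displacements[sys.tooth_id]
        r = sys.contacts.crown_points - sys.CR
        d = x[:3] + np.cross(x[3:], r)
        f, _ = _contact_force_rows(sys.contacts, d)
        forces[sys.tooth_id] = ForceSystem(f.sum(axis=0), _cross_rows(r, f).sum(axis=0))
        total_f += f.sum(axis=0)
        total_m += _cross_rows(sys.contacts.crown_points, f).sum(axis=0)
    return EquilibriumSolution(displacements, forces,
                               ForceSystem(-total_f, -total_m),
                               residuals, iterations, strains)
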