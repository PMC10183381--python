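"""Measurement battery: rigid-motion decomposition, efficacy, off-track.

All displacements are landmark displacements relative to the baseline
dentition, expressed in the occlusal frame (X transverse toward the
modelled side, Y posterior, Z occlusal); rotations are the frame-axis
components of the relative pose's rotation vector, in degrees, signs by
the right-hand rule.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .arch import FrameDefinition, Landmarks
from .errors import StageSimError
from .transforms import RigidTransform


@dataclass
class MotionDecomposition:
    """Per-tooth displacement/rotation components in frame coordinates."""

    tooth: int
    crown_displacement: np.ndarray      # mm, (x, y, z) frame components
    root_displacement: np.ndarray       # mm
    rotation_deg: np.ndarray            # degrees about the frame axes
    cr_displacement: np.ndarray         # mm, centre-of-resistance translation


def decompose_motion(current_pose: RigidTransform, baseline_pose: RigidTransform,
                     local_landmarks: Landmarks, frame: FrameDefinition,
                     tooth: int = 0) -> MotionDecomposition:
    """Decompose the motion since baseline into landmark displacements and
    frame-axis rotation components.

    The relative rotation is extracted as a rotation vector (matrix
    logarithm), which is unambiguous for the sub-10-degree rotations that
    occur during staging, then projected on the frame axes.
    """
    delta = current_pose.compose(baseline_pose.inverse())
    rotvec = delta.rotvec()

    def disp(p_local):
        return frame.to_frame(current_pose.apply(p_local) - baseline_pose.apply(p_local))

    return MotionDecomposition(
        tooth=tooth,
        crown_displacement=disp(local_landmarks.crown_point),
        root_displacement=disp(local_landmarks.root_point),
        rotation_deg=np.degrees(frame.to_frame(rotvec)),
        cr_displacement=disp(local_landmarks.CR),
    )


def trajectory_kinematics(trajectory) -> pd.DataFrame:
    """Long-form per-stage, per-tooth kinematics table."""
    rows = []
    arch = trajectory.arch
    frame = trajectory.frame
    for rec in trajectory.records:
        for tooth in arch.teeth:
            fdi = tooth.fdi_id
            dec = decompose_motion(rec.poses[fdi], trajectory.baseline_poses[fdi],
                                   tooth.landmarks, frame, tooth=fdi)
            rows.append({
                "stage": rec.stage, "tooth": fdi,
                "crown_dx": dec.crown_displacement[0],
                "crown_dy": dec.crown_displacement[1],
                "crown_dz": dec.crown_displacement[2],
                "root_dx": dec.root_displacement[0],
                "root_dy": dec.root_displacement[1],
                "root_dz": dec.root_displacement[2],
                "rot_x_deg": dec.rotation_deg[0],
                "rot_y_deg": dec.rotation_deg[1],
                "rot_z_deg": dec.rotation_deg[2],
            })
    return pd.DataFrame(rows)


def _crown_world(trajectory, fdi: int, pose: RigidTransform) -> np.ndarray:
    return pose.apply(trajectory.arch.tooth(fdi).landmarks.crown_point)


def efficacy_distalization(trajectory, plan) -> pd.DataFrame:
    """Per-stage distalization efficacy of the target tooth, percent.

    100 x (distal component of the target crown-point displacement) /
    (stage x step size).  "Distal" is the local arch-tangent direction at
    the target tooth at baseline; the frame-Y (posterior) component is
    reported alongside.
    """
    if not trajectory.records:
        raise StageSimError("empty trajectory")
    if plan.step_size <= 0:
        raise StageSimError("zero prescribed step; efficacy undefined")
    fdi = plan.target_tooth
    base_pose = trajectory.baseline_poses[fdi]
    c0 = _crown_world(trajectory, fdi, base_pose)
    distal = trajectory.distal_dirs[fdi]
    rows = []
    for rec in trajectory.records:
        prescribed = rec.stage * plan.step_size
        d = _crown_world(trajectory, fdi, rec.poses[fdi]) - c0
        rows.append({
            "stage": rec.stage,
            "prescribed_mm": prescribed,
            "distal_displacement_mm": float(d @ distal),
            "posterior_displacement_mm": float(d @ trajectory.frame.y_axis),
            "efficacy_pct": 100.0 * float(d @ distal) / prescribed,
        })
    return pd.DataFrame(rows)


def efficacy_space_opening(trajectory, plan) -> pd.DataFrame:
    """Per-stage inter-molar space-opening efficacy, percent.

    100 x (enlargement of the crown-point distance between the target
    tooth and its mesial neighbour) / (stage x step size).
    """
    if not trajectory.records:
        raise StageSimError("empty trajectory")
    if plan.step_size <= 0:
        raise StageSimError("zero prescribed step; efficacy undefined")
    ids = [t.fdi_id for t in trajectory.arch.teeth]
    fdi = plan.target_tooth
    mesial = ids[ids.index(fdi) - 1]
    d0 = np.linalg.norm(_crown_world(trajectory, fdi, trajectory.baseline_poses[fdi])
                        - _crown_world(trajectory, mesial, trajectory.baseline_poses[mesial]))
    rows = []
    for rec in trajectory.records:
        prescribed = rec.stage * plan.step_size
        dist = np.linalg.norm(_crown_world(trajectory, fdi, rec.poses[fdi])
                              - _crown_world(trajectory, mesial, rec.poses[mesial]))
        rows.append({
            "stage": rec.stage,
            "prescribed_mm": prescribed,
            "space_opening_mm": float(dist - d0),
            "efficacy_pct": 100.0 * float(dist - d0) / prescribed,
        })
    return pd.DataFrame(rows)


def offtrack_gap(state) -> Dict[str, float]:
    """Distances from the target tooth's distal cusps to their corresponding
    aligner inner-surface points (correspondence fixed at stage fitting)."""
    if state.aligner is None or not state.offtrack_correspondence:
        raise StageSimError("no aligner / cusp correspondence established")
    tooth = state.arch.tooth(state.config.plan.target_tooth)
    lm = tooth.world_landmarks()
    out = {}
    for name, idx in state.offtrack_correspondence.items():
        cusp = lm.cusp_points[name]
        out[name] = float(np.linalg.norm(cusp - state.aligner.vertices[idx]))
    return out


def write_reports(trajectory, out_dir) -> Dict[str, Path]:
    """Write kinematics.csv, efficacy.csv and summary.json for a trajectory."""
    if not trajectory.records:
        raise StageSimError("empty trajectory: nothing to report")
    out = Path(out_dir)
    kin = trajectory_kinematics(trajectory)
    plan = trajectory.plan
    eff_d = efficacy_distalization(trajectory, plan)
    eff_s = efficacy_space_opening(trajectory, plan)
    eff = eff_d.merge(eff_s[["stage", "space_opening_mm", "efficacy_pct"]],
                      on="stage", suffixes=("_distalization", "_space_opening"))
    gaps = pd.DataFrame([{"stage": r.stage, **{f"offtrack_{k}_mm": v
                                               for k, v in r.offtrack.items()}}
                         for r in trajectory.records])
    if len(gaps.columns) > 1:
        eff = eff.merge(gaps, on="stage")

    out.mkdir(parents=True, exist_ok=True)
    kin_path = out / "kinematics.csv"
    eff_path = out / "efficacy.csv"
    sum_path = out / "summary.json"
    kin.to_csv(kin_path, index=False, float_format="%.9g")
    eff.to_csv(eff_path, index=False, float_format="%.9g")

    last = trajectory.records[-1]
    final_kin = kin[kin.stage == last.stage].set_index("tooth")
    fdi = plan.target_tooth
    summary = {
        "stages": int(last.stage),
        "elapsed_weeks": float(last.elapsed_weeks),
        "prescribed_mm": float(last.stage * plan.step_size),
        "target_tooth": int(fdi),
        "target_crown_distal_mm": float(eff_d.iloc[-1]["distal_displacement_mm"]),
        "target_coronal_axis_rotation_deg": float(final_kin.loc[fdi, "rot_x_deg"]),
        "target_intrusion_mm": float(-final_kin.loc[fdi, "crown_dz"]),
        "distalization_efficacy_pct": float(eff_d.iloc[-1]["efficacy_pct"]),
        "space_opening_efficacy_pct": float(eff_s.iloc[-1]["efficacy_pct"]),
        "offtrack_gaps_mm": {k: float(v) for k, v in last.offtrack.items()},
        "mean_distalization_efficacy_pct": float(eff_d["efficacy_pct"].mean()),
        "mean_space_opening_efficacy_pct": float(eff_s["efficacy_pct"].mean()),
    }
    sum_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"kinematics": kin_path, "efficacy": eff_path, "summary": sum_path}
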