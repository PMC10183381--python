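"""Motion decomposition, efficacy metrics, off-track and report files."""
import numpy as np
import pandas as pd
import pytest
from scipy.linalg import logm

from stagesim import kinematics as kin
from stagesim.arch import FrameDefinition, Landmarks
from stagesim.errors import StageSimError
from stagesim.transforms import RigidTransform
from tests.conftest import random_rigid


def _frame(rot=np.eye(3), origin=np.zeros(3)):
    return FrameDefinition(origin, rot[:, 0], rot[:, 1], rot[:, 2],
                           (origin, rot[:, 2]))


def _landmarks():
    return Landmarks(crown_point=np.array([0.0, 0.0, 8.0]),
                     root_point=np.array([0.0, 0.0, -12.0]),
                     CR=np.array([0.0, 0.0, -4.0]),
                     LA=np.array([0.0, 0.0, -1.0]))


class TestDecomposition:
    def test_identity_pose_all_zero(self):
        dec = kin.decompose_motion(RigidTransform.identity(),
                                   RigidTransform.identity(), _landmarks(), _frame())
        assert np.allclose(dec.crown_displacement, 0)
        assert np.allclose(dec.root_displacement, 0)
        assert np.allclose(dec.rotation_deg, 0)

    def test_pure_rotation_about_frame_axis_through_cr(self):
        lm = _landmarks()
        pose = RigidTransform.about_point(np.radians([5.0, 0, 0]), lm.CR)
        dec = kin.decompose_motion(pose, RigidTransform.identity(), lm, _frame())
        assert dec.rotation_deg[0] == pytest.approx(5.0, abs=1e-9)
        assert abs(dec.rotation_deg[1]) < 1e-9
        assert abs(dec.rotation_deg[2]) < 1e-9
        assert np.allclose(dec.cr_displacement, 0, atol=1e-12)

    def test_matches_matrix_logarithm_oracle(self):
        rng = np.random.default_rng(9)
        frame_rot = random_rigid(rng).rotation
        frame = _frame(frame_rot)
        lm = _landmarks()
        for _ in range(10):
            base = random_rigid(rng)
            delta = random_rigid(rng)
            cur = delta.compose(base)
            dec = kin.decompose_motion(cur, base, lm, frame)
            # independent oracle: matrix log of the relative rotation
            W = np.real(logm(delta.rotation))
            rotvec = np.array([W[2, 1], W[0, 2], W[1, 0]])
            expected = np.degrees(np.stack([frame.x_axis, frame.y_axis,
                                            frame.z_axis]) @ rotvec)
            assert np.allclose(dec.rotation_deg, expected, atol=1e-9)


class _FakeTraj:
    """Minimal trajectory stub around constructed poses."""

    def __init__(self, arch, baseline, records, frame, distal, plan, config=None):
        self.arch = arch
        self.baseline_poses = baseline
        self.records = records
        self.frame = frame
        self.distal_dirs = distal
        self.plan = plan
        self.config = config


class _FakeRec:
    def __init__(self, stage, poses, offtrack=None, weeks=None):
        self.stage = stage
        self.poses = poses
        self.offtrack = offtrack or {}
        self.elapsed_weeks = weeks if weeks is not None else 2.0 * stage


class _FakeTooth:
    def __init__(self, fdi, landmarks):
        self.fdi_id = fdi
        self.landmarks = landmarks


class _FakeArch:
    def __init__(self, teeth):
        self.teeth = teeth

    def tooth(self, fdi):
        return next(t for t in self.teeth if t.fdi_id == fdi)


def _two_molar_traj(d17_per_stage, d16_per_stage, stages, step=0.1):
    lm16 = Landmarks(np.array([0.0, 30.0, 7.0]), np.zeros(3),
                     np.array([0.0, 30.0, -3.0]), np.array([0.0, 0.0, -1.0]))
    lm17 = Landmarks(np.array([0.0, 40.0, 7.0]), np.zeros(3),
                     np.array([0.0, 40.0, -3.0]), np.array([0.0, 0.0, -1.0]))
    arch = _FakeArch([_FakeTooth(16, lm16), _FakeTooth(17, lm17)])
    baseline = {16: RigidTransform.identity(), 17: RigidTransform.identity()}
    recs = []
    for s in range(1, stages + 1):
        poses = {16: RigidTransform(np.eye(3), [0, -d16_per_stage * s, 0]),
                 17: RigidTransform(np.eye(3), [0, d17_per_stage * s, 0])}
        recs.append(_FakeRec(s, poses))
    frame = _frame()
    distal = {17: np.array([0.0, 1.0, 0.0]), 16: np.array([0.0, 1.0, 0.0])}
    from stagesim.config import StagePlanConfig
    plan = StagePlanConfig(step_size=step)
    return _FakeTraj(arch, baseline, recs, frame, distal, plan)


class TestEfficacy:
    def test_constructed_partial_expression_is_68_percent(self):
        # 0.68 mm achieved of 1.0 mm prescribed after 10 stages of 0.1 mm
        traj = _two_molar_traj(0.068, 0.0, stages=10)
        eff = kin.efficacy_distalization(traj, traj.plan)
        assert eff.iloc[-1]["efficacy_pct"] == pytest.approx(68.0, abs=1e-9)

    def test_prescription_following_pose_is_100_percent(self):
        traj = _two_molar_traj(0.1, 0.0, stages=5)
        eff = kin.efficacy_distalization(traj, traj.plan)
        assert np.allclose(eff["efficacy_pct"], 100.0, atol=1e-9)

    def test_pure_rotation_about_cr_gives_zero_distal_efficacy(self):
        traj = _two_molar_traj(0.1, 0.0, stages=1)
        lm17 = traj.arch.tooth(17).landmarks
        # rotation about the distal axis through CR: crown point sweeps
        # transversely/vertically with exactly zero distal component
        traj.records[0].poses[17] = RigidTransform.about_point(
            np.radians([0, 3.0, 0]), lm17.CR)
        eff = kin.efficacy_distalization(traj, traj.plan)
        assert abs(eff.iloc[0]["efficacy_pct"]) < 1e-9

    def test_space_opening_static_molars_zero(self):
        traj = _two_molar_traj(0.0, 0.0, stages=3)
        eff = kin.efficacy_space_opening(traj, traj.plan)
        assert np.allclose(eff["efficacy_pct"], 0.0, atol=1e-12)

    def test_space_opening_with_anchorage_loss_is_90_percent(self):
        # collinear crown points: 17 distal 0.8 mm, 16 mesial 0.1 mm of 1.0 mm
        traj = _two_molar_traj(0.08, 0.01, stages=10)
        eff = kin.efficacy_space_opening(traj, traj.plan)
        assert eff.iloc[-1]["efficacy_pct"] == pytest.approx(90.0, abs=1e-9)

    def test_empty_trajectory_rejected(self):
        traj = _two_molar_traj(0.1, 0.0, stages=1)
        traj.records = []
        with pytest.raises(StageSimError):
            kin.efficacy_distalization(traj, traj.plan)


def test_offtrack_rigid_occlusal_offset(sim_config):
    from stagesim import staging
    state = staging.initialize_state(sim_config, seed=0)
    staging.setup_stage(state)
    g0 = kin.offtrack_gap(state)
    state.aligner.vertices = state.aligner.vertices + np.array([0.0, 0.0, 0.5])
    g1 = kin.offtrack_gap(state)
    for name in g1:
        # rigid 0.5 mm occlusal lift opens both cusp gaps by ~0.5 mm
        assert g1[name] == pytest.approx(np.sqrt(0.5 ** 2 + g0[name] ** 2), abs=0.2)
        assert g1[name] >= 0.3
    state.aligner.vertices = state.aligner.vertices - np.array([0.0, 0.0, 0.5])


def test_scene_rotation_leaves_reported_scalars_unchanged(default_run):
    """Frame equivariance: rigidly rotating the whole scene must not change
    any reported kinematic scalar."""
    traj = default_run.trajectory
    kt0 = kin.trajectory_kinematics(traj)
    rng = np.random.default_rng(2)
    T = random_rigid(rng)
    moved_arch = traj.arch.apply_transform(T)
    import copy
    traj2 = copy.copy(traj)
    traj2.arch = moved_arch
    # transport the *baseline* frame (the arch object itself carries the
    # final-stage poses, so its recomputed frame is not the baseline one)
    f0 = traj.frame
    from stagesim.arch import FrameDefinition
    traj2.frame = FrameDefinition(T.apply(f0.origin), T.apply_vector(f0.x_axis),
                                  T.apply_vector(f0.y_axis), T.apply_vector(f0.z_axis),
                                  (T.apply(f0.occlusal_plane[0]),
                                   T.apply_vector(f0.occlusal_plane[1])))
    traj2.baseline_poses = {f: T.compose(p) for f, p in traj.baseline_poses.items()}
    traj2.records = [copy.copy(r) for r in traj.records]
    for r in traj2.records:
        r.poses = {f: T.compose(p) for f, p in r.poses.items()}
    kt1 = kin.trajectory_kinematics(traj2)
    for col in ("crown_dx", "crown_dy", "crown_dz", "rot_x_deg", "rot_y_deg", "rot_z_deg"):
        assert np.allclose(kt0[col], kt1[col], atol=1e-8), col


class TestReports:
    def test_row_counts_and_rerun_byte_identical(self, default_run, tmp_path):
        traj = default_run.trajectory
        p1 = kin.write_reports(traj, tmp_path / "a")
        p2 = kin.write_reports(traj, tmp_path / "b")
        kt = pd.read_csv(p1["kinematics"])
        assert len(kt) == 20 * 7
        for key in p1:
            assert (p1[key].read_bytes() == p2[key].read_bytes())

    def test_empty_trajectory_writes_nothing(self, default_run, tmp_path):
        import copy
        traj = copy.copy(default_run.trajectory)
        traj.records = []
        out = tmp_path / "empty"
        with pytest.raises(StageSimError):
            kin.write_reports(traj, out)
        assert not out.exists()
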