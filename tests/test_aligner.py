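"""Aligner shell, TCM band deformation and wear-in registration."""
import numpy as np
import pytest

from stagesim.aligner import TCMParams, apply_tcm_step, build_aligner, define_band, \
    refit_aligner
from stagesim.transforms import RigidTransform


@pytest.fixture()
def aligner_with_band(arch_coarse):
    aligner = build_aligner(arch_coarse)
    band = define_band(aligner, arch_coarse, 16, 17)
    return aligner, band


def test_inner_surface_coincides_with_crowns_before_activation(arch_coarse):
    aligner = build_aligner(arch_coarse)
    poses = {t.fdi_id: t.pose for t in arch_coarse.teeth}
    cent = aligner.face_centroids()
    for fdi in aligner.covered_teeth():
        m = aligner.face_tooth == fdi
        c = poses[fdi].apply(aligner.face_local_centroid[m])
        n = poses[fdi].apply_vector(aligner.face_local_normal[m])
        gaps = np.einsum("ij,ij->i", cent[m] - c, n)
        assert np.abs(gaps).max() < 1e-12


def test_aligner_stores_shell_parameters(arch_coarse):
    aligner = build_aligner(arch_coarse, thickness=0.7, elastic_modulus=1500.0)
    assert aligner.thickness == 0.7
    assert aligner.elastic_modulus == 1500.0
    assert aligner.covered_teeth() == [11, 12, 13, 14, 15, 16, 17]


def test_aligner_area_covers_trimmed_crown_area(arch_coarse):
    aligner = build_aligner(arch_coarse)
    trim = arch_coarse.config.gingival_trim_fraction
    covered = 0.0
    for t in arch_coarse.teeth:
        mesh, _ = t.contact_mesh()
        z0 = trim * t.spec.crown_height
        keep = mesh.triangles.mean(axis=1)[:, 2] >= z0
        covered += mesh.area_faces[keep].sum()
    assert aligner.area >= covered - 1e-9


class TestBand:
    def test_width_parameter_and_midpoint(self, aligner_with_band):
        _, band = aligner_with_band
        assert band.d == 2.0
        assert np.allclose(band.P_c, 0.5 * (band.P_i + band.P_j), atol=1e-12)
        assert np.linalg.norm(band.direction) == pytest.approx(1.0, abs=1e-12)

    def test_membership_is_exactly_the_projection_slab(self, aligner_with_band):
        aligner, band = aligner_with_band
        # oracle: exhaustive projection scan of every vertex
        p = aligner.vertices @ band.direction
        c = band.P_c @ band.direction
        inside = np.abs(p - c) <= band.d / 2.0
        member = np.zeros(len(p), dtype=bool)
        member[band.member_idx] = True
        assert np.array_equal(member, inside)

    def test_non_adjacent_teeth_rejected(self, arch_coarse):
        from stagesim.errors import BandError
        aligner = build_aligner(arch_coarse)
        with pytest.raises(BandError):
            define_band(aligner, arch_coarse, 14, 17)


class TestTCM:
    def test_single_step_widens_band_by_U(self, aligner_with_band):
        aligner, band = aligner_with_band
        apply_tcm_step(aligner, band, TCMParams(0.1))
        assert aligner.band_width_increase(band) == pytest.approx(0.1, rel=0.01)
        assert band.delta_sum == pytest.approx(0.1)
        assert band.kt_history == [pytest.approx(0.1 / 2.0)]

    def test_zero_step_is_identity(self, aligner_with_band):
        aligner, band = aligner_with_band
        before = aligner.vertices.copy()
        apply_tcm_step(aligner, band, TCMParams(0.0))
        assert np.array_equal(aligner.vertices, before)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            TCMParams(-0.1)

    def test_five_steps_accumulate_and_update_thermal_strain(self, aligner_with_band):
        aligner, band = aligner_with_band
        for _ in range(5):
            apply_tcm_step(aligner, band, TCMParams(0.1))
        assert aligner.band_width_increase(band) == pytest.approx(0.5, rel=0.01)
        assert band.delta_sum == pytest.approx(0.5)
        # k*t of the 5th step: U / (d + sum of the previous four)
        assert band.kt_history[-1] == pytest.approx(0.1 / (2.0 + 0.4))

    def test_mesial_side_is_bit_identical(self, aligner_with_band):
        aligner, band = aligner_with_band
        p = aligner.vertices @ band.direction
        mesial = p < band.b_mesial
        before = aligner.vertices[mesial].copy()
        apply_tcm_step(aligner, band, TCMParams(0.1))
        assert np.array_equal(aligner.vertices[mesial], before)

    @pytest.mark.parametrize("n_steps", [1, 7, 20])
    def test_conservation_over_n_steps(self, arch_coarse, n_steps):
        aligner = build_aligner(arch_coarse)
        band = define_band(aligner, arch_coarse, 16, 17)
        for _ in range(n_steps):
            apply_tcm_step(aligner, band, TCMParams(0.1))
        assert aligner.band_width_increase(band) == pytest.approx(0.1 * n_steps, rel=0.01)
        assert band.delta_sum == pytest.approx(0.1 * n_steps, abs=1e-12)


class TestRefit:
    def test_already_fitting_returns_identity(self, arch_coarse):
        aligner = build_aligner(arch_coarse)
        T = refit_aligner(aligner, arch_coarse)
        assert np.linalg.norm(T.rotvec()) < 1e-6
        assert np.linalg.norm(T.translation) < 1e-9

    def test_recovers_posterior_translation(self, arch_coarse):
        aligner = build_aligner(arch_coarse)
        moved = arch_coarse.apply_transform(
            RigidTransform(np.eye(3), np.array([0.0, 0.3, 0.0])))
        T = refit_aligner(aligner, moved)
        assert np.allclose(T.translation, [0.0, 0.3, 0.0], atol=1e-3)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_midsagittal_constraint_suppresses_x_translation(self, arch_coarse):
        aligner = build_aligner(arch_coarse)
        moved = arch_coarse.apply_transform(
            RigidTransform(np.eye(3), np.array([0.3, 0.0, 0.0])))
        T = refit_aligner(aligner, moved)
        assert abs(T.translation[0]) < 1e-6

    def test_residuals_non_increasing(self, arch_coarse):
        aligner = build_aligner(arch_coarse)
        band = define_band(aligner, arch_coarse, 16, 17)
        apply_tcm_step(aligner, band, TCMParams(0.3))
        refit_aligner(aligner, arch_coarse)
        res = aligner.last_refit_residuals
        assert len(res) >= 2
        assert all(b <= a + 1e-12 for a, b in zip(res[:-1], res[1:]))
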