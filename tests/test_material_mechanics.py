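"""Bilinear PDL law, foundation stiffness, contact and equilibrium."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stagesim import mechanics as mech
from stagesim.transforms import skew


LAW = mech.MaterialLawBilinear()


class TestBilinearLaw:
    def test_zero_strain_zero_stress(self):
        assert LAW.stress(0.0) == 0.0

    def test_tangent_moduli_on_both_branches(self):
        assert LAW.tangent(0.04) == pytest.approx(0.05)
        assert LAW.tangent(0.10) == pytest.approx(0.22)
        assert LAW.tangent(-0.10) == pytest.approx(0.22)

    def test_hand_evaluated_stresses(self):
        # sigma(0.075) = 0.05*0.075; sigma(0.10) = that + 0.22*0.025
        assert LAW.stress(0.075) == pytest.approx(0.00375, abs=1e-12)
        assert LAW.stress(0.10) == pytest.approx(0.00925, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    def test_odd_symmetric_and_monotone(self, e1, e2):
        assert LAW.stress(-e1) == pytest.approx(-LAW.stress(e1), abs=1e-15)
        if e1 < e2:
            assert LAW.stress(e1) < LAW.stress(e2) + 1e-15

    def test_continuous_at_threshold(self):
        eps = 1e-9
        below = LAW.stress(LAW.eps_threshold - eps)
        above = LAW.stress(LAW.eps_threshold + eps)
        assert above - below == pytest.approx(0.0, abs=1e-8)


class TestFoundationStiffness:
    def test_single_point_matches_hand_assembly(self):
        p = np.array([[1.0, 2.0, 0.5]])
        n = np.array([[0.0, 0.6, 0.8]])
        A = np.array([2.0])
        pdl = mech.PDLFoundation(p, n, A, 0.3)
        CR = np.array([0.5, -1.0, 0.0])
        K = mech.foundation_stiffness(pdl, CR)
        kn = LAW.e1 / 0.3 * 2.0
        kt = 0.5 * kn
        Kp = kn * np.outer(n[0], n[0]) + kt * (np.eye(3) - np.outer(n[0], n[0]))
        B = np.hstack([np.eye(3), -skew(p[0] - CR)])
        assert np.allclose(K, B.T @ Kp @ B, atol=1e-12)
        # one support point cannot constrain all six DOFs
        assert np.linalg.matrix_rank(K, tol=1e-10) == 3

    def test_symmetric_positive_definite_for_spherical_sampling(self):
        rng = np.random.default_rng(4)
        dirs = rng.normal(size=(500, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        pdl = mech.PDLFoundation(dirs * 5.0, dirs, np.full(500, 4 * np.pi * 25 / 500), 0.3)
        K = mech.foundation_stiffness(pdl, np.zeros(3))
        assert np.abs(K - K.T).max() < 1e-10 * np.abs(K).max()
        assert np.all(np.linalg.eigvalsh(K) > 0)
        # translational block isotropic for a symmetric sphere
        tt = np.diag(K[:3, :3])
        assert tt.max() / tt.min() < 1.05


class TestContact:
    def _single_pair(self, gap):
        return mech.ContactSet(
            aligner_points=[[0.0, 0.0, gap]], crown_points=[[0.0, 0.0, 0.0]],
            normals=[[0.0, 0.0, 1.0]], areas=[1.0], stiffness=[10.0],
            tooth_ids=[17], mu=0.2)

    def test_open_gap_gives_zero_force(self):
        contacts = self._single_pair(0.05)
        forces, reaction = mech.contact_forces(contacts, {}, {17: np.zeros(3)})
        assert np.allclose(forces[17].force, 0.0)
        assert np.allclose(reaction.force, 0.0)

    def test_hand_evaluated_penalty_and_friction_cap(self):
        # gap -0.1 mm, k*A = 10 N/mm -> normal force 1.0 N; friction <= 0.2 N
        contacts = self._single_pair(-0.1)
        forces, _ = mech.contact_forces(
            contacts, {17: (np.array([0.3, 0.0, 0.0]), np.zeros(3))},
            {17: np.zeros(3)})
        f = forces[17].force
        f_normal = f[2]
        f_tangential = np.linalg.norm(f[:2])
        assert abs(f_normal) == pytest.approx(1.0, rel=1e-9)
        assert f_tangential == pytest.approx(0.2 * 1.0, rel=1e-9)
        assert f[2] < 0     # pushes the crown along -normal

    def test_no_tensile_force_and_cap_under_random_states(self):
        rng = np.random.default_rng(5)
        m = 300
        n = rng.normal(size=(m, 3))
        n /= np.linalg.norm(n, axis=1)[:, None]
        contacts = mech.ContactSet(
            aligner_points=rng.normal(scale=5, size=(m, 3)),
            crown_points=rng.normal(scale=5, size=(m, 3)),
            normals=n, areas=rng.uniform(0.1, 1, m),
            stiffness=np.full(m, 0.5), tooth_ids=np.full(m, 17), mu=0.2)
        for _ in range(20):
            d = rng.normal(scale=0.2, size=(m, 3))
            f, pen = mech._contact_force_rows(contacts, d)
            fn = -np.einsum("ij,ij->i", f, n)       # normal components
            ft = np.linalg.norm(f + fn[:, None] * n, axis=1)
            assert np.all(fn >= -1e-12)             # never tensile
            assert np.all(ft <= 0.2 * fn + 1e-9)    # friction cap everywhere
            assert np.all(fn[pen == 0] < 1e-12)

    def test_action_reaction_closes_to_machine_precision(self):
        rng = np.random.default_rng(6)
        m = 200
        n = rng.normal(size=(m, 3))
        n /= np.linalg.norm(n, axis=1)[:, None]
        contacts = mech.ContactSet(
            aligner_points=rng.normal(scale=4, size=(m, 3)),
            crown_points=rng.normal(scale=4, size=(m, 3)),
            normals=n, areas=rng.uniform(0.1, 1, m), stiffness=np.full(m, 1.0),
            tooth_ids=rng.choice([11, 14, 17], m), mu=0.2)
        disp = {t: (rng.normal(scale=0.05, size=3), rng.normal(scale=0.01, size=3))
                for t in (11, 14, 17)}
        CRs = {t: rng.normal(scale=3, size=3) for t in (11, 14, 17)}
        forces, reaction = mech.contact_forces(contacts, disp, CRs)
        total = sum(f.force for f in forces.values()) + reaction.force
        assert np.linalg.norm(total) < 1e-9


def _spherical_foundation(rng, m=400, radius=4.0, center=(0, 0, -6.0)):
    dirs = rng.normal(size=(m, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    pts = dirs * radius + np.asarray(center)
    return mech.PDLFoundation(pts, dirs, np.full(m, 4 * np.pi * radius ** 2 / m), 0.3)


class TestEquilibrium:
    def test_zero_activation_zero_displacement(self):
        rng = np.random.default_rng(0)
        pdl = _spherical_foundation(rng)
        sys = mech.ToothSystem(17, np.array([0, 0, -6.0]), pdl)
        sol = mech.solve_equilibrium([sys])
        assert np.allclose(sol.displacements[17], 0.0)

    def test_single_tooth_linear_regime_matches_dense_solve(self):
        rng = np.random.default_rng(1)
        pdl = _spherical_foundation(rng)
        CR = np.array([0, 0, -6.0])
        F = np.array([0.02, -0.01, 0.005, 0.004, -0.002, 0.001])
        sys = mech.ToothSystem(17, CR, pdl, external_wrench=F)
        sol = mech.solve_equilibrium([sys])
        K = mech.foundation_stiffness(pdl, CR)
        assert np.abs(sol.displacements[17] - np.linalg.solve(K, F)).max() < 1e-8

    def test_contact_work_equals_pdl_strain_energy(self):
        # linearised system, small frictionless activation, ramped loading
        rng = np.random.default_rng(2)
        pdl = _spherical_foundation(rng)
        CR = np.array([0, 0, -6.0])
        m = 60
        n = rng.normal(size=(m, 3))
        n /= np.linalg.norm(n, axis=1)[:, None]
        pts = n * 4.0 + np.array([0, 0, 2.0])
        full_gap = -0.002
        xs = [np.zeros(6)]
        lambdas = np.linspace(0, 1, 201)
        for lam in lambdas[1:]:
            contacts = mech.ContactSet(pts + lam * full_gap * n, pts, n,
                                       np.full(m, 0.5), np.full(m, 2.0),
                                       np.full(m, 17), mu=0.0)
            sys = mech.ToothSystem(17, CR, pdl, contacts=contacts)
            x, _, _, _ = mech.solve_tooth(sys, tol_force=1e-10, tol_moment=1e-10)
            xs.append(x)
        # path integral of the contact wrench against the displacement path
        work = 0.0
        for lam0, lam1, x0, x1 in zip(lambdas[:-1], lambdas[1:], xs[:-1], xs[1:]):
            lam = 0.5 * (lam0 + lam1)
            xm = 0.5 * (x0 + x1)
            contacts = mech.ContactSet(pts + lam * full_gap * n, pts, n,
                                       np.full(m, 0.5), np.full(m, 2.0),
                                       np.full(m, 17), mu=0.0)
            r = contacts.crown_points - CR
            d = xm[:3] + np.cross(xm[3:], r)
            f, _ = mech._contact_force_rows(contacts, d)
            F = f.sum(axis=0)
            M = np.cross(r, f).sum(axis=0)
            work += F @ (x1[:3] - x0[:3]) + M @ (x1[3:] - x0[3:])
        K = mech.foundation_stiffness(pdl, CR)
        energy = 0.5 * xs[-1] @ K @ xs[-1]
        assert work == pytest.approx(energy, rel=0.01)

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        pdl = _spherical_foundation(rng, m=120)
        CR = np.array([0, 0, -6.0])
        m = 40
        n = rng.normal(size=(m, 3))
        n /= np.linalg.norm(n, axis=1)[:, None]
        pts = n * 4.0 + np.array([0.2, -0.1, 1.5])
        contacts = mech.ContactSet(pts - 0.01 * n, pts, n, np.full(m, 0.4),
                                   np.full(m, 1.0), np.full(m, 17), mu=0.0)
        sys = mech.ToothSystem(17, CR, pdl, contacts=contacts)
        x0 = rng.normal(scale=1e-3, size=6)
        R0, _, J = mech._assemble(sys, x0, want_jac=True)
        h = 1e-7
        J_fd = np.zeros((6, 6))
        for k in range(6):
            dx = np.zeros(6)
            dx[k] = h
            Rp, _, _ = mech._assemble(sys, x0 + dx, want_jac=False)
            Rm, _, _ = mech._assemble(sys, x0 - dx, want_jac=False)
            J_fd[:, k] = (Rp - Rm) / (2 * h)
        assert np.abs(J - J_fd).max() < 1e-4 * max(1.0, np.abs(J).max())
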