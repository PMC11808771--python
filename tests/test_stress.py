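"""Stress densities and surface-integral forces.

The sign conventions of the whole stress stack are pinned by two
oracles exercised here: the repulsive point-charge pair (Coulomb's law
through the Maxwell stress) and the finite-difference energy gradient
(H2+, in the acceptance suite).
"""

import numpy as np
import pytest

from stresskit import Molecule
from stresskit.fields import UniformGrid, make_grid
from stresskit.fixtures import gaussian_orbital_state, point_charge_system
from stresskit.stress import (
    GridStateProvider,
    force_error_estimate,
    hellmann_feynman_force,
    integration_radius,
    kinetic_stress,
    maxwell_stress,
    stress_force,
    stress_force_report,
    total_stress,
    xc_stress,
)
from stresskit.xc import svwn5, toy_gga


class TestMaxwellStress:
    def test_uniform_field_closed_form(self):
        E0 = 1.7
        sig = maxwell_stress(np.array([[E0, 0.0, 0.0]]))[0]
        assert sig[0, 0] == pytest.approx(E0**2 / (8 * np.pi), rel=1e-12)
        assert sig[1, 1] == pytest.approx(-(E0**2) / (8 * np.pi), rel=1e-12)
        assert sig[2, 2] == pytest.approx(-(E0**2) / (8 * np.pi), rel=1e-12)
        off = sig - np.diag(np.diag(sig))
        assert np.max(np.abs(off)) == 0.0

    def test_zero_field(self):
        assert np.all(maxwell_stress(np.zeros((4, 3))) == 0.0)

    def test_trace(self, rng):
        E = rng.standard_normal((10, 3))
        sig = maxwell_stress(E)
        tr = np.trace(sig, axis1=-2, axis2=-1)
        assert np.allclose(tr, -np.sum(E * E, axis=-1) / (8 * np.pi), atol=1e-14)

    def test_coulomb_law_through_stress_theorem(self):
        """Two unit charges at d=2: sphere integral around one gives a
        repulsive 1/d^2 = 0.25 force."""
        sys_ = point_charge_system([(1.0, [0, 0, 0]), (1.0, [0, 0, 2.0])])
        F = stress_force(sys_, 0, radius=0.5, degree=17)
        assert F[2] == pytest.approx(-0.25, rel=1e-8)
        assert abs(F[0]) < 1e-12 and abs(F[1]) < 1e-12

    @pytest.mark.parametrize(
        "q1,q2,d", [(1, 1, 1.5), (1, -1, 2.0), (2, 1, 3.0), (-2, 1, 6.0), (1, 2, 4.5)]
    )
    def test_coulomb_oracle_sweep(self, q1, q2, d):
        sys_ = point_charge_system([(q1, [0.3, 0.1, -0.2]), (q2, [0.3, 0.1, -0.2 + d])])
        F = stress_force(sys_, 0, radius=0.2 * d, degree=17)
        rel = np.linalg.norm(F - sys_.expected_forces[0]) / np.linalg.norm(
            sys_.expected_forces[0]
        )
        assert rel < 1e-8

    def test_empty_sphere_null_analytic(self):
        """No nucleus inside -> no force (vacuum carries no momentum flux
        divergence)."""
        from stresskit.lebedev import lebedev_sphere

        sys_ = point_charge_system([(1.0, [0, 0, 0]), (1.0, [6.0, 0, 0])])
        sph = lebedev_sphere([3.0, 1.0, 0.5], 1.0, 17)
        samples = total_stress(sys_, sph.points)
        traction = np.einsum("nij,nj->ni", samples.sigma_total, sph.normals)
        F = sph.surface_integral(traction)
        assert np.linalg.norm(F) < 1e-6


class TestKineticStress:
    @pytest.fixture(scope="class")
    def gauss_state(self):
        return gaussian_orbital_state(
            [[0.0, 0.0, 0.0], [0.8, -0.3, 0.4]], [0.5, 0.9], [2.0, 1.0]
        )

    def test_product_rule_identity(self, gauss_state, rng):
        """Both printed forms of the kinetic stress agree pointwise when
        evaluated with analytic derivatives."""
        pts = rng.uniform(-1.2, 1.2, size=(60, 3))
        s1 = kinetic_stress(
            gauss_state.occupations,
            gauss_state.orbital_gradients(pts),
            density_hessian=gauss_state.density_hessian(pts),
        )
        s2 = kinetic_stress(
            gauss_state.occupations,
            gauss_state.orbital_gradients(pts),
            orbital_values=gauss_state.orbital_values(pts),
            orbital_hessians=gauss_state.orbital_hessians(pts),
            form="second_derivative",
        )
        assert np.max(np.abs(s1 - s2)) < 1e-10

    def test_zero_in_constant_region(self):
        occ = [2.0]
        grads = np.zeros((1, 5, 3))
        hess = np.zeros((5, 3, 3))
        assert np.all(kinetic_stress(occ, grads, density_hessian=hess) == 0.0)

    def test_grid_derivatives_converge_to_analytic(self, gauss_state, rng):
        """Grid-based kinetic stress approaches the analytic one at the
        stencil order when h halves."""
        pts = rng.uniform(-0.8, 0.8, size=(40, 3))
        exact = kinetic_stress(
            gauss_state.occupations,
            gauss_state.orbital_gradients(pts),
            density_hessian=gauss_state.density_hessian(pts),
        )
        errs = []
        for h in (0.25, 0.125):
            n = int(round(12.0 / h)) + 1
            n += n % 2
            grid = UniformGrid((-6.0, -6.0, -6.0), h, (n, n, n))
            X, Y, Z = grid.meshgrid()
            gpts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

            class P:
                occupations = gauss_state.occupations
                one_electron = False

                def orbital_gradients(self, q, _g=grid):
                    from stresskit.fields import FieldInterpolator, ScalarField, differentiate

                    psi = gauss_state.orbitals_fn(gpts)
                    out = []
                    for k in range(len(psi)):
                        f = ScalarField(_g, psi[k].reshape(_g.shape))
                        out.append(FieldInterpolator(differentiate(f, "gradient"))(q))
                    return np.stack(out)

                def density_hessian(self, q, _g=grid):
                    from stresskit.fields import FieldInterpolator, ScalarField, differentiate

                    rho = gauss_state.density(gpts).reshape(_g.shape)
                    return FieldInterpolator(differentiate(ScalarField(_g, rho), "hessian"))(q)

            p = P()
            approx = kinetic_stress(
                p.occupations, p.orbital_gradients(pts), density_hessian=p.density_hessian(pts)
            )
            errs.append(np.max(np.abs(approx - exact)))
        assert errs[1] < errs[0] / 8.0

    def test_complex_orbitals_rejected(self):
        with pytest.raises(ValueError):
            kinetic_stress([1.0], np.zeros((1, 2, 3), complex), density_hessian=np.zeros((2, 3, 3)))


class TestXcStress:
    def test_lda_isotropic_for_uniform_density(self):
        rho = np.full(5, 0.4)
        eps, v, _ = svwn5(rho)
        sig = xc_stress(rho, eps, v)
        for s in sig:
            assert s[0, 0] == pytest.approx(s[1, 1], rel=1e-14)
            assert s[1, 1] == pytest.approx(s[2, 2], rel=1e-14)
            assert np.max(np.abs(s - np.diag(np.diag(s)))) == 0.0

    def test_vanishes_with_density(self):
        rho = np.zeros(4)
        eps, v, _ = svwn5(rho)
        assert np.all(xc_stress(rho, eps, v) == 0.0)

    def test_gga_term_is_symmetric_dyadic(self, rng):
        rho = rng.uniform(0.1, 1.0, 6)
        grad = rng.standard_normal((6, 3))
        sigma = np.sum(grad**2, axis=-1)
        func = toy_gga()
        eps, dfdrho, dfdsigma = func(rho, sigma)
        fgrad = 2 * dfdsigma[:, None] * grad
        sig = xc_stress(rho, eps, dfdrho, grad, fgrad)
        asym = np.max(np.abs(sig - np.swapaxes(sig, -1, -2)))
        assert asym < 1e-14


class TestTotalStress:
    def test_decomposition_sums(self, h2plus_state):
        prov = GridStateProvider(h2plus_state)
        pts = np.array([[0.5, 0.2, -0.3], [0.0, 0.0, 1.8]])
        s = total_stress(prov, pts)
        assert np.max(np.abs(s.sigma_total - (s.sigma_kin + s.sigma_maxwell + s.sigma_xc))) == 0.0

    def test_vacuum_point_vanishes(self):
        sys_ = point_charge_system([(1.0, [0, 0, 0])])
        pts = np.array([[300.0, 0.0, 0.0]])
        s = total_stress(sys_, pts)
        assert np.max(np.abs(s.sigma_total)) < 1e-10

    def test_mirror_symmetry_of_homonuclear_dimer(self, h2plus_state):
        prov = GridStateProvider(h2plus_state)
        p = np.array([[0.4, 0.1, 0.9]])
        q = np.array([[0.4, 0.1, -0.9]])  # mirror through the bond midplane
        sp = total_stress(prov, p).sigma_total[0]
        sq = total_stress(prov, q).sigma_total[0]
        M = np.diag([1.0, 1.0, -1.0])
        assert np.max(np.abs(sp - M @ sq @ M)) < 1e-6


class TestIntegrationRadius:
    def test_half_nearest_neighbor(self):
        pos = np.array([[0, 0, 0], [0, 0, 1.4]])
        assert integration_radius(pos, 0) == pytest.approx(0.7)

    def test_single_atom_default(self):
        assert integration_radius(np.array([[1.0, 2.0, 3.0]]), 0) == 2.0

    def test_custom_fraction(self):
        pos = np.array([[0, 0, 0], [2.0, 0, 0]])
        assert integration_radius(pos, 0, fraction=0.25) == pytest.approx(0.5)

    def test_cap(self):
        pos = np.array([[0, 0, 0], [10.0, 0, 0]])
        assert integration_radius(pos, 0, cap=3.0) == 3.0


class TestStressForceGuards:
    def test_sphere_swallowing_neighbor_rejected(self):
        sys_ = point_charge_system([(1.0, [0, 0, 0]), (1.0, [0, 0, 1.0])])
        with pytest.raises(ValueError, match="another nucleus"):
            stress_force(sys_, 0, radius=1.5)

    def test_sphere_clipping_box_rejected(self):
        from stresskit import solve_one_electron

        mol = Molecule.from_symbols(["H"], [[0.0, 0.0, 0.0]], 0.5)
        st = solve_one_electron(mol, spacing=0.4, margin=3.0, eig_tol=1e-7)
        prov = GridStateProvider(st)
        with pytest.raises(ValueError, match="outside"):
            stress_force(prov, 0, radius=2.9)


class TestHellmannFeynman:
    def test_single_atom_zero_force(self):
        mol = Molecule.from_symbols(["H"], [[0.0, 0.0, 0.0]], 0.5)
        from stresskit import solve_one_electron

        st = solve_one_electron(mol, spacing=0.3, margin=6.0, eig_tol=1e-9)
        rep = hellmann_feynman_force(st)
        assert np.max(np.abs(rep.forces)) < 1e-8

    def test_newton_third_law_on_symmetric_dimer(self, h2plus_state):
        rep = hellmann_feynman_force(h2plus_state)
        assert np.max(np.abs(rep.forces[0] + rep.forces[1])) < 1e-6


class TestForceErrorEstimate:
    def test_zero_forces(self):
        assert force_error_estimate(np.zeros((4, 3))) == 0.0

    def test_exactly_cancelling_forces(self):
        F = np.array([[0.1, -0.2, 0.3], [-0.1, 0.2, -0.3]])
        assert force_error_estimate(F) == 0.0

    def test_matches_direct_formula(self, rng):
        """sigma = sqrt(sum_i s_i^2 / (3 N)) with s the column sums."""
        F = rng.standard_normal((7, 3))
        s = F.sum(axis=0)
        expected = np.sqrt((s[0] ** 2 + s[1] ** 2 + s[2] ** 2) / (3 * 7))
        assert force_error_estimate(F) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            force_error_estimate(np.zeros((0, 3)))


class TestForceReport:
    def test_sums_match_recomputation(self, h2plus_state):
        prov = GridStateProvider(h2plus_state)
        rep = stress_force_report(prov, degree=11)
        assert np.allclose(rep.sums, rep.forces.sum(axis=0), atol=0)
        assert rep.method == "stress_surface"
        assert rep.settings["degree"] == 11


class TestGgaStressForce:
    def test_gga_stress_force_consistent_with_energy(self):
        """End-to-end check of the gradient-channel xc stress: on a toy
        GGA the surface-integral force matches the (egg-box-cancelling)
        central-difference gradient of the total energy."""
        from stresskit import run_scf
        from stresskit.fields import UniformGrid

        func = toy_gga(a=0.7386, b=0.01)
        R = 2.4
        mol = Molecule.from_symbols(["H", "H"], [[0, 0, -R / 2], [0, 0, R / 2]], 0.35)
        grid0 = make_grid(mol, 0.3, 5.0)
        grid = UniformGrid(
            tuple(np.array(grid0.origin) + np.array([0.13, 0.07, 0.19]) * 0.3),
            0.3, grid0.shape,
        )
        st = run_scf(mol, grid=grid, functional=func, mixing=0.5)
        F = stress_force(GridStateProvider(st), 0, degree=17)
        h = 0.3
        orbs = st.orbitals

        def energy(z0):
            m = mol.with_positions([[0, 0, z0], [0, 0, R / 2]])
            return run_scf(m, grid=grid, functional=func, tol_energy=1e-9,
                           tol_density=1e-7, mixing=0.5, initial_orbitals=orbs).energy

        ffd = -(8 * (energy(-R / 2 + h) - energy(-R / 2 - h))
                - (energy(-R / 2 + 2 * h) - energy(-R / 2 - 2 * h))) / (12 * h)
        assert F[2] == pytest.approx(ffd, abs=1e-3)
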