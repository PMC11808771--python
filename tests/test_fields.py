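"""Grid, derivative, interpolation and Poisson-solver contracts."""

import numpy as np
import pytest
from scipy.special import erf

from stresskit import Molecule
from stresskit.fields import (
    FieldInterpolator,
    ScalarField,
    UniformGrid,
    differentiate,
    interpolate,
    make_grid,
    poisson_free_space,
    volume_integrate,
)


def _scalar(fn, grid):
    X, Y, Z = grid.meshgrid()
    return ScalarField(grid, fn(X, Y, Z))


@pytest.fixture()
def small_grid():
    return UniformGrid((-3.0, -3.0, -3.0), 0.25, (26, 26, 26))


class TestMakeGrid:
    def test_single_atom_box_and_even_dims(self):
        mol = Molecule.from_symbols(["H"], [[0, 0, 0]], 0.2)
        grid = make_grid(mol, 0.5, 6.0)
        assert all(n % 2 == 0 for n in grid.shape)
        assert np.all(grid.box_lengths >= 12.0)

    def test_margin_respected_for_dimer(self):
        mol = Molecule.from_symbols(["H", "H"], [[-1, 0, 0], [1, 0, 0]], 0.2)
        grid = make_grid(mol, 0.25, 8.0)
        lo = np.asarray(grid.origin)
        hi = grid.upper
        for R in mol.positions:
            assert np.all(R - lo >= 8.0 - 1e-12)
            assert np.all(hi - R >= 8.0 - 1e-12)

    def test_pure_function(self):
        mol = Molecule.from_symbols(["H", "O"], [[-1, 0.2, 0], [1, 0, 0.3]], 0.2)
        g1 = make_grid(mol, 0.25, 8.0)
        g2 = make_grid(mol, 0.25, 8.0)
        assert g1 == g2

    def test_origin_shift_keeps_margin(self):
        mol = Molecule.from_symbols(["H"], [[0, 0, 0]], 0.2)
        grid = make_grid(mol, 0.4, 5.0, origin_shift=(0.13, -0.07, 0.19))
        lo = np.asarray(grid.origin)
        assert np.all(mol.positions[0] - lo >= 5.0 - 1e-12)
        assert np.all(grid.upper - mol.positions[0] >= 5.0 - 1e-12)

    def test_rejects_bad_input(self):
        mol = Molecule.from_symbols(["H"], [[0, 0, 0]], 0.2)
        with pytest.raises(ValueError):
            make_grid(mol, -0.1, 5.0)
        with pytest.raises(ValueError):
            make_grid(mol, 0.25, 50.0, max_points=10_000)
        bad = Molecule.from_symbols(["H"], [[0, 0, 0]], 0.2)
        bad.positions[0, 0] = np.nan
        with pytest.raises(ValueError):
            make_grid(bad, 0.25, 5.0)


class TestDifferentiate:
    def test_laplacian_exact_on_quadratic(self, small_grid):
        f = _scalar(lambda x, y, z: x**2, small_grid)
        lap = differentiate(f, "laplacian").values
        interior = lap[3:-3, 3:-3, 3:-3]
        assert np.max(np.abs(interior - 2.0)) < 1e-10

    def test_gradient_annihilates_constants(self, small_grid):
        f = _scalar(lambda x, y, z: np.ones_like(x), small_grid)
        g = differentiate(f, "gradient").values
        assert np.max(np.abs(g[3:-3, 3:-3, 3:-3])) < 1e-13

    def test_gaussian_gradient_fourth_order(self):
        """Interior gradient error vs the closed form drops ~16x when h halves."""
        errs = []
        for h in (0.25, 0.125):
            n = int(round(6.0 / h)) + 1
            grid = UniformGrid((-3.0, -3.0, -3.0), h, (n, n, n))
            X, Y, Z = grid.meshgrid()
            r2 = X**2 + Y**2 + Z**2
            f = ScalarField(grid, np.exp(-0.5 * r2))
            g = differentiate(f, "gradient").values
            exact = -X * np.exp(-0.5 * r2)
            m = int(round(1.0 / h))  # trim boundary
            err = np.max(np.abs(g[m:-m, m:-m, m:-m, 0] - exact[m:-m, m:-m, m:-m]))
            errs.append(err)
        assert errs[1] < errs[0] / 10.0  # ~h^4 (allow slack)

    def test_hessian_symmetric_and_trace_is_laplacian(self, small_grid):
        X, Y, Z = small_grid.meshgrid()
        f = ScalarField(small_grid, np.exp(-0.3 * (X**2 + 2 * Y**2 + 0.5 * Z**2 + X * Y)))
        H = differentiate(f, "hessian")
        assert H.symmetric
        asym = np.max(np.abs(H.values - np.swapaxes(H.values, -1, -2)))
        assert asym == 0.0
        lap = differentiate(f, "laplacian").values
        trace = np.trace(H.values, axis1=-2, axis2=-1)
        assert np.max(np.abs(trace - lap)) < 1e-12

    def test_bad_requests_rejected(self):
        grid = UniformGrid((0, 0, 0), 0.5, (8, 8, 8))
        f = _scalar(lambda x, y, z: x, grid)
        with pytest.raises(ValueError):
            differentiate(f, "nonsense")
        with pytest.raises(ValueError):
            differentiate(f, "gradient", accuracy=3)


class TestInterpolate:
    def test_identity_at_grid_nodes(self, small_grid):
        X, Y, Z = small_grid.meshgrid()
        f = ScalarField(small_grid, np.sin(X) * np.cos(Y) + Z**2)
        axes = small_grid.axes()
        pts = np.array([[axes[0][7], axes[1][9], axes[2][11]],
                        [axes[0][12], axes[1][5], axes[2][6]]])
        vals = interpolate(f, pts)
        assert abs(vals[0] - f.values[7, 9, 11]) < 1e-12
        assert abs(vals[1] - f.values[12, 5, 6]) < 1e-12

    def test_exact_on_trilinear(self, small_grid, rng):
        f = _scalar(lambda x, y, z: x + 2 * y + 3 * z, small_grid)
        pts = rng.uniform(-1.5, 1.5, size=(50, 3))
        vals = interpolate(f, pts)
        exact = pts[:, 0] + 2 * pts[:, 1] + 3 * pts[:, 2]
        assert np.max(np.abs(vals - exact)) < 1e-10

    def test_gaussian_error_converges(self, rng):
        pts = rng.uniform(-1.0, 1.0, size=(100, 3))
        exact = np.exp(-0.5 * np.sum(pts**2, axis=1))
        errs = []
        for h in (0.25, 0.125):
            n = int(round(6.0 / h)) + 1
            grid = UniformGrid((-3.0, -3.0, -3.0), h, (n, n, n))
            X, Y, Z = grid.meshgrid()
            f = ScalarField(grid, np.exp(-0.5 * (X**2 + Y**2 + Z**2)))
            errs.append(np.max(np.abs(interpolate(f, pts) - exact)))
        assert errs[1] < errs[0] / 8.0  # cubic spline ~h^4

    def test_out_of_box_named_error(self, small_grid):
        f = _scalar(lambda x, y, z: x, small_grid)
        with pytest.raises(ValueError, match="outside"):
            interpolate(f, [[10.0, 0.0, 0.0]])


class TestVolumeIntegrate:
    def test_normalized_gaussian(self):
        grid = UniformGrid((-8.0, -8.0, -8.0), 0.25, (66, 66, 66))
        X, Y, Z = grid.meshgrid()
        rho = np.exp(-0.5 * (X**2 + Y**2 + Z**2)) / (2 * np.pi) ** 1.5
        assert abs(volume_integrate(ScalarField(grid, rho)) - 1.0) < 1e-8

    def test_ones_give_box_volume(self):
        grid = UniformGrid((0, 0, 0), 0.5, (10, 10, 10))
        f = _scalar(lambda x, y, z: np.ones_like(x), grid)
        with pytest.warns(RuntimeWarning):
            v = volume_integrate(f)
        assert v == pytest.approx(1000 * 0.5**3)


class TestPoisson:
    def test_gaussian_closed_form(self):
        grid = UniformGrid((-8.0, -8.0, -8.0), 0.25, (66, 66, 66))
        X, Y, Z = grid.meshgrid()
        a = 1.0
        r = np.sqrt(X**2 + Y**2 + Z**2)
        rho = np.exp(-0.5 * r**2 / a**2) / (a**3 * (2 * np.pi) ** 1.5)
        v = poisson_free_space(ScalarField(grid, rho)).values
        with np.errstate(invalid="ignore", divide="ignore"):
            exact = erf(r / (a * np.sqrt(2))) / r
        exact[r < 1e-12] = np.sqrt(2 / np.pi) / a
        assert np.max(np.abs(v - exact)) < 1e-5

    def test_linearity(self, rng):
        grid = UniformGrid((-4.0, -4.0, -4.0), 0.4, (22, 22, 22))
        X, Y, Z = grid.meshgrid()
        r1 = np.exp(-((X - 0.5) ** 2 + Y**2 + Z**2))
        r2 = np.exp(-(X**2 + (Y + 0.7) ** 2 + Z**2) / 0.8)
        v1 = poisson_free_space(ScalarField(grid, r1)).values
        v2 = poisson_free_space(ScalarField(grid, r2)).values
        v12 = poisson_free_space(ScalarField(grid, r1 + r2)).values
        assert np.max(np.abs(v12 - v1 - v2)) < 1e-12

    def test_two_gaussian_interaction_energy(self):
        """Mutual electrostatic energy of two separated unit Gaussians
        equals 1/d (they look like point charges from afar)."""
        d = 6.0
        grid = UniformGrid((-8.0, -8.0, -11.0), 0.25, (66, 66, 90))
        X, Y, Z = grid.meshgrid()
        a = 0.5

        def gauss(z0):
            return np.exp(-((X**2 + Y**2 + (Z - z0) ** 2)) / (2 * a**2)) / (
                a**3 * (2 * np.pi) ** 1.5
            )

        r1 = gauss(-d / 2)
        r2 = gauss(+d / 2)
        v1 = poisson_free_space(ScalarField(grid, r1))
        e_int = volume_integrate(ScalarField(grid, v1.values * r2), boundary_threshold=1.0)
        assert abs(e_int - 1.0 / d) < 1e-6

    def test_laplacian_recovers_source_at_stencil_order(self):
        """nabla^2 v_H + 4 pi rho -> 0 at the finite-difference rate
        (the potential itself is spectrally accurate, so the residual is
        pure differentiation error, ~h^4 for the order-4 stencil)."""
        errs = []
        for h in (0.25, 0.125):
            n = int(round(12.0 / h)) + 1
            n += n % 2
            grid = UniformGrid((-6.0, -6.0, -6.0), h, (n, n, n))
            X, Y, Z = grid.meshgrid()
            rho = np.exp(-(X**2 + Y**2 + Z**2))
            v = poisson_free_space(ScalarField(grid, rho))
            lap = differentiate(v, "laplacian", accuracy=4).values
            m = int(round(2.0 / h))
            errs.append(np.max(np.abs(lap + 4 * np.pi * rho)[m:-m, m:-m, m:-m]))
        assert errs[1] < errs[0] / 8.0  # nominal factor 16

    def test_nan_rejected(self, small_grid):
        f = _scalar(lambda x, y, z: x * 0, small_grid)
        f.values[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            poisson_free_space(f)
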