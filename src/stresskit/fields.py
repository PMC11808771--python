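"""Uniform Cartesian grids and scalar/vector/tensor fields.

Provides centered finite-difference derivatives, smooth off-grid
interpolation, volume integration and a free-space Poisson solver --
the substrate on which the Kohn-Sham state and all stress densities
are represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.fft import rfftn, irfftn, next_fast_len

__all__ = [
    "UniformGrid",
    "ScalarField",
    "VectorField",
    "TensorField",
    "make_grid",
    "differentiate",
    "interpolate",
    "FieldInterpolator",
    "volume_integrate",
    "poisson_free_space",
]

# centered finite-difference stencils, accuracy order -> half coefficients
_D1_STENCILS = {
    2: np.array([-0.5, 0.0, 0.5]),
    4: np.array([1 / 12, -2 / 3, 0.0, 2 / 3, -1 / 12]),
    6: np.array([-1 / 60, 3 / 20, -3 / 4, 0.0, 3 / 4, -3 / 20, 1 / 60]),
}
_D2_STENCILS = {
    2: np.array([1.0, -2.0, 1.0]),
    4: np.array([-1 / 12, 4 / 3, -5 / 2, 4 / 3, -1 / 12]),
    6: np.array([1 / 90, -3 / 20, 3 / 2, -49 / 18, 3 / 2, -3 / 20, 1 / 90]),
}


@dataclass(frozen=True)
class UniformGrid:
    """Isotropic uniform Cartesian grid.

    The box spans ``origin + [0, (n_i - 1) * spacing]`` along each axis;
    grid nodes sit at ``origin + j * spacing``.
    """

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self):
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if len(self.shape) != 3 or any(int(n) < 8 for n in self.shape):
            raise ValueError(f"grid needs >= 8 points per axis, got {self.shape}")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError(f"non-finite origin {self.origin}")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def box_lengths(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * self.spacing

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + self.box_lengths

    @property
    def npoints(self) -> int:
        n1, n2, n3 = self.shape
        return n1 * n2 * n3

    @property
    def cell_volume(self) -> float:
        return self.spacing**3

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(o[i] + self.spacing * np.arange(self.shape[i]) for i in range(3))

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(np.meshgrid(*self.axes(), indexing="ij"))

    def translated(self, shift: Sequence[float]) -> "UniformGrid":
        o = np.asarray(self.origin) + np.asarray(shift, float)
        return UniformGrid(tuple(o), self.spacing, self.shape)

    def contains(self, points: np.ndarray, pad: float = 0.0) -> np.ndarray:
        """Boolean mask: points at least `pad` inside the box on every axis."""
        pts = np.atleast_2d(np.asarray(points, float))
        lo = np.asarray(self.origin) + pad
        hi = self.upper - pad
        return np.all((pts >= lo) & (pts <= hi), axis=-1)


@dataclass
class ScalarField:
    grid: UniformGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())


@dataclass
class VectorField:
    grid: UniformGrid
    values: np.ndarray  # (n1, n2, n3, 3)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape + (3,):
            raise ValueError(f"vector field shape {self.values.shape} inconsistent with grid")

    def component(self, i: int) -> ScalarField:
        return ScalarField(self.grid, self.values[..., i])


@dataclass
class TensorField:
    grid: UniformGrid
    values: np.ndarray  # (n1, n2, n3, 3, 3)
    symmetric: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape + (3, 3):
            raise ValueError(f"tensor field shape {self.values.shape} inconsistent with grid")
        if self.symmetric:
            asym = np.max(np.abs(self.values - np.swapaxes(self.values, -1, -2)))
            if asym > 1e-10:
                raise ValueError(f"tensor flagged symmetric but max asymmetry {asym:.3e}")


def make_grid(
    molecule,
    spacing: float,
    margin: float,
    max_points: int = 40_000_000,
    origin_shift: Sequence[float] = (0.0, 0.0, 0.0),
) -> UniformGrid:
    """Build an even-dimensioned grid box enclosing `molecule` with the
    requested vacuum margin on every side.

    The box is centered on the geometric center of the nuclei; with even
    point counts the center falls mid-cell, so atoms placed symmetrically
    never coincide with grid nodes (important for the smoothed-potential
    sampling near nuclei). ``origin_shift`` (fractions of the spacing,
    each in [-0.5, 0.5]) displaces the whole lattice; use it to break
    the exact lattice symmetry that a centered high-symmetry molecule
    otherwise enjoys, mirroring the "no atoms on special points"
    precaution for general-case tests.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    R = np.atleast_2d(np.asarray(molecule.positions, float))
    if R.size == 0:
        raise ValueError("molecule is empty")
    if not np.all(np.isfinite(R)):
        raise ValueError("non-finite nuclear coordinates")
    shift = np.asarray(origin_shift, float)
    if shift.shape != (3,) or np.any(np.abs(shift) > 0.5):
        raise ValueError("origin_shift must be three fractions in [-0.5, 0.5]")
    lo = R.min(axis=0) - margin
    hi = R.max(axis=0) + margin
    shape = []
    origin = []
    for ax in range(3):
        n = int(np.ceil((hi[ax] - lo[ax]) / spacing)) + 1
        if n % 2:
            n += 1
        if shift[ax] != 0.0:
            n += 2  # keep the requested margin on both faces after the shift
        n = max(n, 8)
        center = 0.5 * (lo[ax] + hi[ax])
        origin.append(center - 0.5 * (n - 1) * spacing + shift[ax] * spacing)
        shape.append(n)
    grid = UniformGrid(tuple(origin), spacing, tuple(shape))
    if grid.npoints > max_points:
        raise ValueError(
            f"grid of {grid.npoints} points exceeds the configured maximum {max_points}"
        )
    return grid


def _stencil(kind: str, accuracy: int) -> np.ndarray:
    table = _D1_STENCILS if kind == "d1" else _D2_STENCILS
    try:
        return table[accuracy]
    except KeyError:
        raise ValueError(
            f"unsupported finite-difference accuracy order {accuracy}; choose from {sorted(table)}"
        ) from None


def _axis_derivative(values: np.ndarray, axis: int, h: float, kind: str, accuracy: int) -> np.ndarray:
    w = _stencil(kind, accuracy)
    if values.shape[axis] < len(w):
        raise ValueError(
            f"field has {values.shape[axis]} points on axis {axis}, "
            f"smaller than the {len(w)}-point stencil"
        )
    out = ndimage.correlate1d(values, w, axis=axis, mode="constant", cval=0.0)
    power = 1 if kind == "d1" else 2
    return out / h**power


def differentiate(field: ScalarField, order: str, accuracy: int = 4):
    """Centered finite-difference derivatives of a scalar field.

    order='gradient' -> VectorField, 'laplacian' -> ScalarField,
    'hessian' -> symmetric TensorField. Boundary points (within half a
    stencil width of the faces) are polluted by the zero-extension and
    must not be consumed.
    """
    v = field.values
    h = field.grid.spacing
    if order == "gradient":
        g = np.stack([_axis_derivative(v, ax, h, "d1", accuracy) for ax in range(3)], axis=-1)
        return VectorField(field.grid, g)
    if order == "laplacian":
        lap = sum(_axis_derivative(v, ax, h, "d2", accuracy) for ax in range(3))
        return ScalarField(field.grid, lap)
    if order == "hessian":
        out = np.empty(field.grid.shape + (3, 3))
        firsts = [_axis_derivative(v, ax, h, "d1", accuracy) for ax in range(3)]
        for i in range(3):
            out[..., i, i] = _axis_derivative(v, i, h, "d2", accuracy)
        for i in range(3):
            for j in range(i + 1, 3):
                mixed = _axis_derivative(firsts[i], j, h, "d1", accuracy)
                out[..., i, j] = mixed
                out[..., j, i] = mixed
        return TensorField(field.grid, out, symmetric=True)
    raise ValueError(f"unknown derivative order {order!r}")


class FieldInterpolator:
    """Tensor-product cubic-spline interpolator for repeated off-grid
    evaluation.

    Not-a-knot cubic splines are fitted once per axis (banded solves)
    and evaluated through ``scipy.interpolate.NdBSpline``. The
    interpolant is C^2, reproduces grid values at the nodes to
    round-off, and is exact for tricubic polynomials (no boundary
    pollution in the interior).
    """

    #: margin (in cells) inside which evaluation is considered unsafe
    SUPPORT_CELLS = 2

    def __init__(self, field):
        from scipy.interpolate import NdBSpline, make_interp_spline

        self.grid = field.grid
        vals = field.values
        self._trailing = vals.shape[3:]
        flat = vals.reshape(self.grid.shape + (-1,)) if self._trailing else vals[..., None]
        axes = self.grid.axes()
        knots = []
        c = flat  # spline axis is processed at the front, then moved back
        for ax in range(3):
            spl = make_interp_spline(axes[ax], np.moveaxis(c, ax, 0), k=3, axis=0)
            knots.append(spl.t)
            c = np.moveaxis(spl.c, 0, ax)
        self._splines = [
            NdBSpline(tuple(knots), np.ascontiguousarray(c[..., j]), k=3)
            for j in range(c.shape[-1])
        ]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        pad = self.SUPPORT_CELLS * self.grid.spacing
        inside = self.grid.contains(pts, pad=pad)
        if not np.all(inside):
            bad = pts[~inside][0]
            raise ValueError(
                f"point {tuple(bad)} is outside the interpolation-safe region "
                f"(box {tuple(self.grid.origin)} .. {tuple(self.grid.upper)}, pad {pad})"
            )
        cols = [s(pts) for s in self._splines]
        out = np.stack(cols, axis=-1)
        if self._trailing:
            out = out.reshape(pts.shape[:-1] + self._trailing)
        else:
            out = out[..., 0]
        return out


def interpolate(field, points: np.ndarray) -> np.ndarray:
    """Evaluate a scalar/vector/tensor field at arbitrary interior points."""
    return FieldInterpolator(field)(points)


def volume_integrate(field: ScalarField, boundary_threshold: float = 1e-8) -> float:
    """Riemann-sum volume integral h^3 * sum(values).

    Warns when the field has not decayed below `boundary_threshold`
    at the box faces (the open-boundary assumption is then violated).
    """
    v = field.values
    faces = [v[0], v[-1], v[:, 0], v[:, -1], v[:, :, 0], v[:, :, -1]]
    bmax = max(np.max(np.abs(f)) for f in faces)
    if bmax > boundary_threshold:
        warnings.warn(
            f"field boundary maximum {bmax:.3e} exceeds threshold {boundary_threshold:.1e}; "
            "volume integral may be truncated",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(v.sum()) * field.grid.cell_volume


_POISSON_CACHE: dict = {}


def _poisson_kernel(shape: tuple, h: float):
    """Fourier samples of the spherically truncated Coulomb kernel.

    Truncating 1/r at L (any L larger than the maximum source-target
    distance in the box) leaves the open-boundary convolution exact while
    making the kernel's Fourier transform, 4*pi*(1-cos(kL))/k^2, smooth
    and band-limited enough for spectral accuracy on the padded grid.
    """
    key = (shape, h)
    if key in _POISSON_CACHE:
        return _POISSON_CACHE[key]
    n1, n2, n3 = shape
    L = h * float(np.sqrt((n1 - 1) ** 2 + (n2 - 1) ** 2 + (n3 - 1) ** 2))
    padded = tuple(next_fast_len(int(np.ceil((n - 1) + L / h)) + 1) for n in shape)
    kx = 2 * np.pi * np.fft.fftfreq(padded[0], h)
    ky = 2 * np.pi * np.fft.fftfreq(padded[1], h)
    kz = 2 * np.pi * np.fft.rfftfreq(padded[2], h)
    k2 = kx[:, None, None] ** 2 + ky[None, :, None] ** 2 + kz[None, None, :] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        G = 4 * np.pi * (1 - np.cos(np.sqrt(k2) * L)) / k2
    G[0, 0, 0] = 2 * np.pi * L**2
    _POISSON_CACHE.clear()  # keep at most one kernel alive
    _POISSON_CACHE[key] = (padded, G)
    return padded, G


def poisson_free_space(density: ScalarField) -> ScalarField:
    """Solve nabla^2 v = -4 pi rho with open (free-space) boundaries.

    Returns the Coulomb potential v(r) = int rho(r')/|r-r'| d3r' of the
    given (positive) density, via zero-padded FFT convolution with the
    truncated 1/r kernel. Spectrally accurate for densities that decay
    inside the box.
    """
    rho = density.values
    if not np.all(np.isfinite(rho)):
        raise ValueError("NaN or Inf in Poisson source density")
    n1, n2, n3 = rho.shape
    padded, G = _poisson_kernel(density.grid.shape, density.grid.spacing)
    work = np.zeros(padded)
    work[:n1, :n2, :n3] = rho
    v = irfftn(rfftn(work) * G, padded)[:n1, :n2, :n3]
    return ScalarField(density.grid, np.ascontiguousarray(v))
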