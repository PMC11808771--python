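"""Molecular structure and the smoothed finite-nucleus model.

The bare electron-nucleus attraction -Z/r is replaced by the smooth,
finite potential U(r) = u(r/c)/c built from the error function plus two
Gaussian correction terms,

    u(x) = erf(x)/x + (1/(3 sqrt(pi))) * (exp(-x^2) + 16 exp(-4 x^2)),

which tends to 1/x for large x and stays finite and smooth at the
origin. The length scale c controls how far the model deviates from the
point-charge potential; c -> 0 recovers -Z/r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

from .constants import SYMBOL_TO_Z, normalize_symbol
from .fields import ScalarField, UniformGrid

__all__ = [
    "Molecule",
    "smoothed_u",
    "smoothed_u_prime",
    "smoothed_U",
    "smoothing_length",
    "external_potential",
    "nuclear_electric_field",
    "electric_field_total",
    "nuclear_repulsion_energy",
    "nuclear_repulsion_forces",
]

_SQRT_PI = float(np.sqrt(np.pi))


@dataclass
class Molecule:
    """Nuclei: element symbols, proton numbers Z, positions (bohr) and
    per-atom smoothing lengths c (bohr)."""

    symbols: list
    charges: np.ndarray  # Z_k, positive integers
    positions: np.ndarray  # (n_atoms, 3) bohr
    smoothing: np.ndarray  # c_k > 0, bohr

    def __post_init__(self):
        self.symbols = [normalize_symbol(s) for s in self.symbols]
        self.charges = np.asarray(self.charges, float)
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.smoothing = np.asarray(self.smoothing, float)
        n = len(self.symbols)
        if self.charges.shape != (n,) or self.positions.shape != (n, 3):
            raise ValueError("inconsistent molecule arrays")
        if self.smoothing.shape != (n,):
            raise ValueError("need one smoothing length per atom")
        if np.any(self.charges < 1):
            raise ValueError("proton numbers must be >= 1")
        if np.any(self.smoothing <= 0):
            raise ValueError("smoothing lengths must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(self.positions[i] - self.positions[j]) == 0.0:
                    raise ValueError(f"atoms {i} and {j} coincide")

    @classmethod
    def from_symbols(
        cls,
        symbols: Sequence[str],
        positions,
        smoothing=0.2,
    ) -> "Molecule":
        symbols = [normalize_symbol(s) for s in symbols]
        Z = np.array([SYMBOL_TO_Z[s] for s in symbols], float)
        c = np.asarray(smoothing, float)
        if c.ndim == 0:
            c = np.full(len(symbols), float(c))
        return cls(symbols, Z, np.asarray(positions, float), c)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def n_electrons_neutral(self) -> int:
        return int(round(self.charges.sum()))

    def with_positions(self, positions) -> "Molecule":
        return Molecule(list(self.symbols), self.charges.copy(),
                        np.asarray(positions, float), self.smoothing.copy())

    def nearest_neighbor_distance(self, atom_index: int) -> float:
        if self.n_atoms < 2:
            raise ValueError("nearest neighbor undefined for a single atom")
        d = np.linalg.norm(self.positions - self.positions[atom_index], axis=1)
        d[atom_index] = np.inf
        return float(d.min())


def smoothed_u(x) -> np.ndarray:
    """Dimensionless smoothed-Coulomb profile u(x); u(x) -> 1/x for large x."""
    x = np.asarray(x, float)
    if np.any(x < 0):
        raise ValueError("smoothed_u requires x >= 0")
    small = x < 1e-4
    xs = np.where(small, 1.0, x)
    core = np.where(small, 2.0 / _SQRT_PI * (1 - x * x / 3.0), erf(xs) / xs)
    tail = (np.exp(-(x * x)) + 16.0 * np.exp(-4.0 * x * x)) / (3.0 * _SQRT_PI)
    return core + tail


def smoothed_u_prime(x) -> np.ndarray:
    """du/dx of the smoothed-Coulomb profile (analytic)."""
    x = np.asarray(x, float)
    if np.any(x < 0):
        raise ValueError("smoothed_u_prime requires x >= 0")
    small = x < 1e-4
    xs = np.where(small, 1.0, x)
    # d/dx [erf(x)/x] = 2 exp(-x^2)/(sqrt(pi) x) - erf(x)/x^2
    core = np.where(
        small,
        2.0 / _SQRT_PI * (-2.0 * x / 3.0 + 4.0 * x**3 / 10.0),
        2.0 * np.exp(-(xs * xs)) / (_SQRT_PI * xs) - erf(xs) / (xs * xs),
    )
    tail = (-2.0 * x * np.exp(-(x * x)) - 128.0 * x * np.exp(-4.0 * x * x)) / (3.0 * _SQRT_PI)
    return core + tail


def smoothed_U(r, c: float):
    """Smoothed nuclear potential U(r) = u(r/c)/c and its radial derivative.

    Returns ``(U, dU_dr)``. U -> 1/r as c -> 0; finite at r = 0.
    """
    if c <= 0:
        raise ValueError("smoothing length c must be positive")
    r = np.asarray(r, float)
    x = r / c
    return smoothed_u(x) / c, smoothed_u_prime(x) / c**2


def smoothing_length(Z: float, target_precision: float) -> float:
    """Default smoothing-length rule c(Z, eps).

    Uses the standard prescription for the erf-based smoothed potential:
    the energy error of the smoothed model scales as ~0.00435 * Z^5 * c^3,
    so c = (eps / (0.00435 Z^5))^(1/3). Monotone: tighter precision or
    larger Z give smaller c. The rule is pluggable -- any callable with
    the same signature may be used when building molecules.
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    if not (0 < target_precision < 1):
        raise ValueError("target_precision must lie in (0, 1)")
    return float((target_precision / (0.00435 * Z**5)) ** (1.0 / 3.0))


def external_potential(molecule: Molecule, grid: UniformGrid) -> ScalarField:
    """V_ext(r) = -sum_k Z_k U(|r - R_k|; c_k), finite everywhere."""
    X, Y, Z = grid.meshgrid()
    v = np.zeros(grid.shape)
    for k in range(molecule.n_atoms):
        Rk = molecule.positions[k]
        r = np.sqrt((X - Rk[0]) ** 2 + (Y - Rk[1]) ** 2 + (Z - Rk[2]) ** 2)
        U, _ = smoothed_U(r, molecule.smoothing[k])
        v -= molecule.charges[k] * U
    return ScalarField(grid, v)


def nuclear_electric_field(
    molecule: Molecule, points: np.ndarray, smoothed: bool = True
) -> np.ndarray:
    """Electric field of the (smeared) nuclei at arbitrary points.

    Each nucleus contributes -Z_k grad U(|r - R_k|; c_k); with
    ``smoothed=False`` the point-charge field Z_k (r-R_k)/|r-R_k|^3 is
    used instead (sensitivity switch).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    E = np.zeros_like(pts)
    for k in range(molecule.n_atoms):
        d = pts - molecule.positions[k]
        r = np.linalg.norm(d, axis=-1)
        r_safe = np.where(r < 1e-14, 1.0, r)
        if smoothed:
            _, dU = smoothed_U(r, molecule.smoothing[k])
            E += -molecule.charges[k] * dU[..., None] * d / r_safe[..., None]
        else:
            E += molecule.charges[k] * d / r_safe[..., None] ** 3
    return E


def electric_field_total(state, molecule: Molecule, points: np.ndarray,
                         smoothed_nuclei: bool = True) -> np.ndarray:
    """Total electric field E = E_nuclei + E_electrons at given points.

    The electronic part is +grad(v_H) (the electron cloud carries charge
    -rho, so its electrostatic potential is -v_H), evaluated by
    interpolating the finite-difference gradient of the Hartree
    potential. The nuclear part uses the smoothed-nucleus field so that
    Maxwell-stress forces are consistent with the smoothed Hamiltonian.
    """
    E = nuclear_electric_field(molecule, points, smoothed=smoothed_nuclei)
    if state is not None and getattr(state, "v_hartree", None) is not None:
        E = E + state.electron_field_at(points)
    return E


def nuclear_repulsion_energy(molecule: Molecule) -> float:
    """Point-charge nuclear repulsion sum_{k<l} Z_k Z_l / |R_k - R_l|."""
    e = 0.0
    for k in range(molecule.n_atoms):
        for l in range(k + 1, molecule.n_atoms):
            d = np.linalg.norm(molecule.positions[k] - molecule.positions[l])
            e += molecule.charges[k] * molecule.charges[l] / d
    return e


def nuclear_repulsion_forces(molecule: Molecule) -> np.ndarray:
    """Point-charge nuclear repulsion forces, (n_atoms, 3)."""
    F = np.zeros((molecule.n_atoms, 3))
    for k in range(molecule.n_atoms):
        for l in range(molecule.n_atoms):
            if l == k:
                continue
            d = molecule.positions[k] - molecule.positions[l]
            r = np.linalg.norm(d)
            F[k] += molecule.charges[k] * molecule.charges[l] * d / r**3
    return F
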