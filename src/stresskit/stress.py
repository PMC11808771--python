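"""Stress densities and surface-integral forces.

The quantum-mechanical stress tensor density is the sum of three parts
(Hartree atomic units, real orbitals, Einstein summation):

kinetic (two algebraically equivalent forms)::

    sigma^kin_ij = -(1/2) sum_k f_k (d_i psi_k d_j psi_k - psi_k d_i d_j psi_k)
                 = -sum_k f_k d_i psi_k d_j psi_k + (1/4) d_i d_j rho

Maxwell::

    sigma^M_ij = (1/(4 pi)) (E_i E_j - (1/2) delta_ij |E|^2)

exchange-correlation (f = rho eps_xc)::

    sigma^xc_ij = delta_ij (rho eps_xc - rho v_xc) - d_i rho * df/d(d_j rho)

With these conventions div(sigma) equals the force density on the
matter at each point, so integrating sigma_ij n_j with the *outward*
normal over a sphere that encloses exactly one nucleus yields the force
on that nucleus; in the surrounding vacuum div(sigma) = 0 (no net force
density acts on the electrons in the ground state).

For one-electron states the Hamiltonian carries no Hartree term, and
the consistent Maxwell contribution is sigma^M(E_nuc + E_e) -
sigma^M(E_e): the electron's self-field Maxwell stress must be removed
because nothing in the one-electron momentum balance compensates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np

from .fields import FieldInterpolator, ScalarField, differentiate
from .lebedev import LebedevSphere, lebedev_sphere
from .molecule import (
    Molecule,
    nuclear_electric_field,
    nuclear_repulsion_forces,
    smoothed_U,
)
from .xc import xc_eval

__all__ = [
    "StressSamples",
    "ForceReport",
    "GridStateProvider",
    "kinetic_stress",
    "maxwell_stress",
    "xc_stress",
    "total_stress",
    "integration_radius",
    "stress_force",
    "stress_force_report",
    "hellmann_feynman_force",
    "force_error_estimate",
]


# ---------------------------------------------------------------------------
# elementary tensor builders (array in, array out)


def maxwell_stress(E: np.ndarray) -> np.ndarray:
    """Maxwell stress (1/4pi)(E_i E_j - 1/2 delta_ij |E|^2) for fields
    of shape (..., 3); returns (..., 3, 3). Trace is -(1/8pi)|E|^2."""
    E = np.asarray(E, float)
    outer = E[..., :, None] * E[..., None, :]
    e2 = np.sum(E * E, axis=-1)
    eye = np.eye(3)
    return (outer - 0.5 * e2[..., None, None] * eye) / (4.0 * np.pi)


def kinetic_stress(
    occupations,
    orbital_gradients: np.ndarray,
    density_hessian: Optional[np.ndarray] = None,
    orbital_values: Optional[np.ndarray] = None,
    orbital_hessians: Optional[np.ndarray] = None,
    form: str = "orbital_gradient",
) -> np.ndarray:
    """Kinetic stress density at sample points.

    form='orbital_gradient' (default) uses gradients plus the density
    hessian; form='second_derivative' uses per-orbital hessians. The
    two are identical by the product rule.

    Shapes: orbital_gradients (n_orb, n, 3); density_hessian (n, 3, 3);
    orbital_values (n_orb, n); orbital_hessians (n_orb, n, 3, 3).
    """
    if np.iscomplexobj(orbital_gradients) or np.iscomplexobj(orbital_values):
        raise ValueError("complex orbitals are not supported")
    f = np.asarray(occupations, float)
    g = np.asarray(orbital_gradients, float)
    if form == "orbital_gradient":
        if density_hessian is None:
            raise ValueError("orbital_gradient form needs the density hessian")
        gg = np.einsum("k,kni,knj->nij", f, g, g)
        return -gg + 0.25 * np.asarray(density_hessian, float)
    if form == "second_derivative":
        if orbital_values is None or orbital_hessians is None:
            raise ValueError("second_derivative form needs orbital values and hessians")
        psi = np.asarray(orbital_values, float)
        hp = np.asarray(orbital_hessians, float)
        gg = np.einsum("k,kni,knj->nij", f, g, g)
        ph = np.einsum("k,kn,knij->nij", f, psi, hp)
        return -0.5 * (gg - ph)
    raise ValueError(f"unknown kinetic stress form {form!r}")


def xc_stress(
    rho: np.ndarray,
    eps_xc: np.ndarray,
    v_xc: np.ndarray,
    grad_rho: Optional[np.ndarray] = None,
    fgrad: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Exchange-correlation stress at sample points.

    Isotropic part delta_ij (rho eps_xc - rho v_xc); for a GGA the
    dyadic gradient-channel term -d_i(rho) * fgrad_j is added, where
    fgrad = d(rho eps_xc)/d(grad rho).
    """
    rho = np.asarray(rho, float)
    iso = rho * (np.asarray(eps_xc, float) - np.asarray(v_xc, float))
    out = iso[..., None, None] * np.eye(3)
    if fgrad is not None:
        if grad_rho is None:
            raise ValueError("GGA stress needs grad_rho alongside fgrad")
        out = out - np.asarray(grad_rho, float)[..., :, None] * np.asarray(fgrad, float)[..., None, :]
    return out


# ---------------------------------------------------------------------------
# sampled stress with decomposition


@dataclass
class StressSamples:
    """Stress tensors sampled at a batch of points, with the
    kinetic/Maxwell/xc decomposition (sigma_total is their sum)."""

    points: np.ndarray  # (n, 3)
    sigma_kin: np.ndarray  # (n, 3, 3)
    sigma_maxwell: np.ndarray
    sigma_xc: np.ndarray

    @property
    def sigma_total(self) -> np.ndarray:
        return self.sigma_kin + self.sigma_maxwell + self.sigma_xc

    def __len__(self):
        return len(self.points)


class GridStateProvider:
    """Exposes a converged Kohn-Sham grid state as smooth point-wise
    fields for stress evaluation.

    All derivatives are taken on the grid by finite differences first
    and then interpolated (derivative-then-interpolate), so the
    integrands seen by the quadrature are C^2-smooth.
    """

    def __init__(self, state, smoothed_nuclei: bool = True):
        self.state = state
        self.molecule = state.molecule
        self.smoothed_nuclei = smoothed_nuclei
        self.one_electron = state.one_electron
        self.occupations = state.occupations
        self._cache: dict = {}

    @property
    def positions(self) -> np.ndarray:
        return self.molecule.positions

    def _interp(self, key, builder) -> FieldInterpolator:
        if key not in self._cache:
            self._cache[key] = FieldInterpolator(builder())
        return self._cache[key]

    def orbital_values(self, points):
        grid = self.state.grid
        return np.stack([
            self._interp(("psi", k), lambda k=k: ScalarField(grid, self.state.orbitals[k]))(points)
            for k in range(len(self.state.orbitals))
        ])

    def orbital_gradients(self, points):
        acc = self.state.fd_accuracy
        grid = self.state.grid
        return np.stack([
            self._interp(
                ("dpsi", k),
                lambda k=k: differentiate(ScalarField(grid, self.state.orbitals[k]), "gradient", acc),
            )(points)
            for k in range(len(self.state.orbitals))
        ])

    def orbital_hessians(self, points):
        acc = self.state.fd_accuracy
        grid = self.state.grid
        return np.stack([
            self._interp(
                ("ddpsi", k),
                lambda k=k: differentiate(ScalarField(grid, self.state.orbitals[k]), "hessian", acc),
            )(points)
            for k in range(len(self.state.orbitals))
        ])

    def density(self, points):
        return self._interp(("rho",), lambda: self.state.rho)(points)

    def density_gradient(self, points):
        acc = self.state.fd_accuracy
        return self._interp(("drho",), lambda: differentiate(self.state.rho, "gradient", acc))(points)

    def density_hessian(self, points):
        acc = self.state.fd_accuracy
        return self._interp(("ddrho",), lambda: differentiate(self.state.rho, "hessian", acc))(points)

    def electron_field(self, points):
        return self.state.electron_field_at(points)

    def total_field(self, points):
        E = nuclear_electric_field(self.molecule, points, smoothed=self.smoothed_nuclei)
        return E + self.electron_field(points)

    def xc_point_data(self, points):
        """(eps_xc, v_xc, grad_rho, fgrad) at points; None for one-electron."""
        if self.one_electron or self.state.functional.kind == "none":
            return None
        state = self.state
        eps = self._interp(("epsxc",), lambda: state.eps_xc)(points)
        vxc = self._interp(("vxc",), lambda: state.v_xc)(points)
        if state.functional.kind == "gga":
            def _fgrad():
                _, _, fg = xc_eval(state.functional, state.rho)
                return fg
            fgrad = self._interp(("fgrad",), _fgrad)(points)
            grad_rho = self.density_gradient(points)
            return eps, vxc, grad_rho, fgrad
        return eps, vxc, None, None


def total_stress(provider, points: np.ndarray, kinetic_form: str = "orbital_gradient") -> StressSamples:
    """Sample the decomposed stress tensor at the given points."""
    pts = np.atleast_2d(np.asarray(points, float))
    n = len(pts)
    occ = np.asarray(getattr(provider, "occupations", []), float)

    if occ.size:
        grads = provider.orbital_gradients(pts)
        if kinetic_form == "second_derivative":
            s_kin = kinetic_stress(
                occ, grads,
                orbital_values=provider.orbital_values(pts),
                orbital_hessians=provider.orbital_hessians(pts),
                form=kinetic_form,
            )
        else:
            s_kin = kinetic_stress(occ, grads, density_hessian=provider.density_hessian(pts))
    else:
        s_kin = np.zeros((n, 3, 3))

    E = provider.total_field(pts)
    s_max = maxwell_stress(E)
    if getattr(provider, "one_electron", False):
        # remove the uncompensated electron self-field Maxwell stress
        s_max = s_max - maxwell_stress(provider.electron_field(pts))

    xc_data = provider.xc_point_data(pts) if hasattr(provider, "xc_point_data") else None
    if xc_data is None:
        s_xc = np.zeros((n, 3, 3))
    else:
        eps, vxc, grad_rho, fgrad = xc_data
        s_xc = xc_stress(provider.density(pts), eps, vxc, grad_rho, fgrad)

    return StressSamples(pts, s_kin, s_max, s_xc)


# ---------------------------------------------------------------------------
# surface-integral forces


def integration_radius(
    positions: np.ndarray,
    atom_index: int,
    fraction: float = 0.5,
    single_atom_default: float = 2.0,
    cap: Optional[float] = None,
) -> float:
    """Sphere radius for surface integration: `fraction` times the
    nearest-neighbor distance (default half), or a fixed default for an
    isolated atom. An optional cap keeps spheres inside the box."""
    R = np.atleast_2d(np.asarray(positions, float))
    if len(R) < 2:
        r = single_atom_default
    else:
        d = np.linalg.norm(R - R[atom_index], axis=1)
        d[atom_index] = np.inf
        r = fraction * float(d.min())
    if cap is not None:
        r = min(r, cap)
    return r


@dataclass
class ForceReport:
    """Per-atom forces with the sum-rule error estimate.

    ``sums`` holds s_i = sum over atoms of the i-th force component;
    for exact forces each s_i vanishes. ``error_estimate`` is the
    standard deviation of the per-component force error inferred from
    the sums: sigma = sqrt(sum_i s_i^2 / (3 N_at)).
    """

    method: str
    forces: np.ndarray  # (n_atoms, 3)
    error_estimate: float
    settings: dict = dataclass_field(default_factory=dict)
    warnings: list = dataclass_field(default_factory=list)

    @property
    def sums(self) -> np.ndarray:
        return self.forces.sum(axis=0)

    @property
    def max_component(self) -> float:
        return float(np.max(np.abs(self.forces)))


def force_error_estimate(forces: np.ndarray) -> float:
    """Estimate of the force-error standard deviation from the
    (ideally zero) total-force sums s_i: sigma = sqrt(sum s_i^2/(3 N))."""
    F = np.atleast_2d(np.asarray(forces, float))
    if F.size == 0:
        raise ValueError("empty force report")
    s = F.sum(axis=0)
    return float(np.sqrt(np.dot(s, s) / (3.0 * len(F))))


def stress_force(
    provider,
    atom_index: int,
    radius: Optional[float] = None,
    degree: int = 17,
    radius_fraction: float = 0.5,
    kinetic_form: str = "orbital_gradient",
) -> np.ndarray:
    """Force on one atom: F_i = r^2 sum_k w_k sigma_ij(x_k) n_j(x_k)
    over an atom-centered Lebedev sphere with outward normals."""
    positions = np.atleast_2d(np.asarray(provider.positions, float))
    center = positions[atom_index]
    if radius is None:
        radius = integration_radius(positions, atom_index, radius_fraction)
    d = np.linalg.norm(positions - center, axis=1)
    d[atom_index] = np.inf
    if np.any(d <= radius):
        raise ValueError(
            f"integration sphere around atom {atom_index} (radius {radius:.3f}) "
            "contains another nucleus"
        )
    sphere = lebedev_sphere(center, radius, degree)
    samples = total_stress(provider, sphere.points, kinetic_form=kinetic_form)
    traction = np.einsum("nij,nj->ni", samples.sigma_total, sphere.normals)
    return sphere.surface_integral(traction)


def stress_force_report(
    provider,
    radius: Optional[float] = None,
    degree: int = 17,
    radius_fraction: float = 0.5,
    kinetic_form: str = "orbital_gradient",
) -> ForceReport:
    """Surface-integral forces for every atom plus the error estimate."""
    positions = np.atleast_2d(np.asarray(provider.positions, float))
    forces = np.stack([
        stress_force(provider, k, radius=radius, degree=degree,
                     radius_fraction=radius_fraction, kinetic_form=kinetic_form)
        for k in range(len(positions))
    ])
    return ForceReport(
        method="stress_surface",
        forces=forces,
        error_estimate=force_error_estimate(forces),
        settings={
            "degree": degree,
            "radius_fraction": radius_fraction,
            "radius": radius,
            "kinetic_form": kinetic_form,
        },
    )


def hellmann_feynman_force(state, use_smoothed: bool = True) -> ForceReport:
    """Hellmann-Feynman forces from the smoothed external potential.

    Electronic term: +Z_k int rho(r) U'(|r - R_k|) (R_k - r)/|r - R_k| dr
    (the analytic derivative of the smeared attraction; no orbital
    derivatives), plus point-charge nuclear-nuclear repulsion.
    """
    molecule = state.molecule
    grid = state.grid
    h = grid.spacing
    X, Y, Z = grid.meshgrid()
    rho = state.rho.values
    warns = []
    if not state.converged:
        warns.append("state is not converged; Hellmann-Feynman forces unreliable")
    forces = np.zeros((molecule.n_atoms, 3))
    for k in range(molecule.n_atoms):
        Rk = molecule.positions[k]
        dx, dy, dz = Rk[0] - X, Rk[1] - Y, Rk[2] - Z
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        r_safe = np.maximum(r, 1e-14)
        if use_smoothed:
            _, dU = smoothed_U(r, molecule.smoothing[k])
        else:
            dU = -1.0 / r_safe**2
        w = molecule.charges[k] * rho * dU / r_safe * h**3
        forces[k, 0] = np.sum(w * dx)
        forces[k, 1] = np.sum(w * dy)
        forces[k, 2] = np.sum(w * dz)
    forces += nuclear_repulsion_forces(molecule)
    return ForceReport(
        method="hellmann_feynman",
        forces=forces,
        error_estimate=force_error_estimate(forces),
        settings={"use_smoothed": use_smoothed},
        warnings=warns,
    )
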