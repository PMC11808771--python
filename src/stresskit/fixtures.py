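"""Deterministic analytic test systems.

Every oracle in the test suite runs against these closed-form states:
classical point-charge electrostatics (Maxwell-stress/Coulomb checks),
Gaussian-orbital states with exact derivatives (kinetic-stress
identities and interpolation convergence), and toy potential-energy
surfaces with exact gradients (line-integral and Verlet checks).

Analytic states implement the same provider protocol as
``stress.GridStateProvider``, so the identical production code path
(total_stress, stress_force) runs on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Optional, Sequence

import numpy as np

from .molecule import smoothed_U

__all__ = ["AnalyticState", "point_charge_system", "gaussian_orbital_state", "toy_pes", "ToyPES"]


@dataclass
class AnalyticState:
    """Closed-form state: callables over (n, 3) point arrays.

    Flags record which stress channels are physically meaningful for
    the fixture (e.g. a pure point-charge system has no kinetic or xc
    stress).
    """

    positions: np.ndarray  # charge/atom sites, (m, 3)
    occupations: np.ndarray
    rho_fn: Callable
    grad_rho_fn: Callable
    hess_rho_fn: Callable
    field_fn: Callable  # total electric field
    orbitals_fn: Optional[Callable] = None  # (n_orb, n)
    orbital_grads_fn: Optional[Callable] = None
    orbital_hess_fn: Optional[Callable] = None
    expected_forces: Optional[np.ndarray] = None
    channels: tuple = ("maxwell",)
    one_electron: bool = False

    # provider protocol ----------------------------------------------------
    def density(self, points):
        return self.rho_fn(np.atleast_2d(points))

    def density_gradient(self, points):
        return self.grad_rho_fn(np.atleast_2d(points))

    def density_hessian(self, points):
        return self.hess_rho_fn(np.atleast_2d(points))

    def total_field(self, points):
        return self.field_fn(np.atleast_2d(points))

    def electron_field(self, points):
        return np.zeros_like(np.atleast_2d(points))

    def orbital_values(self, points):
        return self.orbitals_fn(np.atleast_2d(points))

    def orbital_gradients(self, points):
        return self.orbital_grads_fn(np.atleast_2d(points))

    def orbital_hessians(self, points):
        return self.orbital_hess_fn(np.atleast_2d(points))

    def xc_point_data(self, points):
        return None

    # self-test ------------------------------------------------------------
    def derivative_self_test(self, points=None, seed: int = 7, tol: float = 1e-8,
                             scale: float = 1.5, step: float = 1e-5) -> float:
        """Compare analytic density gradient with central differences of
        the density callable at random points; returns the max error."""
        if points is None:
            rng = np.random.default_rng(seed)
            points = rng.uniform(-scale, scale, size=(100, 3))
        pts = np.atleast_2d(points)
        g = self.density_gradient(pts)
        num = np.empty_like(g)
        for i in range(3):
            e = np.zeros(3)
            e[i] = step
            num[:, i] = (self.rho_fn(pts + e) - self.rho_fn(pts - e)) / (2 * step)
        err = float(np.max(np.abs(g - num)))
        if err > tol:
            raise AssertionError(f"analytic-derivative self-test failed: {err:.3e} > {tol:.1e}")
        return err


def _zeros_rho(points):
    return np.zeros(len(np.atleast_2d(points)))


def _zeros_vec(points):
    return np.zeros((len(np.atleast_2d(points)), 3))


def _zeros_tens(points):
    return np.zeros((len(np.atleast_2d(points)), 3, 3))


def point_charge_system(charges: Sequence, smoothing: Optional[float] = None) -> AnalyticState:
    """Classical point charges: rho = 0, E = sum_q q (r-r_q)/|r-r_q|^3.

    `charges` is a sequence of (q, position). With `smoothing` set, each
    charge's field uses the smeared-nucleus profile -q U'(r; c) r_hat
    instead of the bare Coulomb field. ``expected_forces`` holds the
    pairwise Coulomb sum on each charge for assertions.
    """
    qs = np.array([float(q) for q, _ in charges])
    pos = np.array([np.asarray(p, float) for _, p in charges])
    if len(pos) != len({tuple(p) for p in pos}):
        raise ValueError("coincident charges")

    def field(points):
        pts = np.atleast_2d(points)
        E = np.zeros_like(pts)
        for q, p in zip(qs, pos):
            d = pts - p
            r = np.linalg.norm(d, axis=-1)
            r = np.where(r < 1e-14, 1.0, r)
            if smoothing is None:
                E += q * d / r[..., None] ** 3
            else:
                _, dU = smoothed_U(r, smoothing)
                E += -q * dU[..., None] * d / r[..., None]
        return E

    expected = np.zeros_like(pos)
    for i in range(len(qs)):
        for j in range(len(qs)):
            if i == j:
                continue
            d = pos[i] - pos[j]
            r = np.linalg.norm(d)
            expected[i] += qs[i] * qs[j] * d / r**3

    return AnalyticState(
        positions=pos,
        occupations=np.array([]),
        rho_fn=_zeros_rho,
        grad_rho_fn=_zeros_vec,
        hess_rho_fn=_zeros_tens,
        field_fn=field,
        expected_forces=expected,
        channels=("maxwell",),
    )


def gaussian_orbital_state(
    centers: Sequence,
    exponents: Sequence[float],
    occupations: Sequence[float],
) -> AnalyticState:
    """Normalized Gaussian orbitals psi_k = (2 a_k/pi)^(3/4) exp(-a_k |r-C_k|^2)
    with analytic first and second derivatives; the density and its
    derivatives follow from the orbital sums. Used as the
    kinetic-stress oracle (no meaningful Maxwell/xc channels)."""
    C = np.atleast_2d(np.asarray(centers, float))
    a = np.asarray(exponents, float)
    f = np.asarray(occupations, float)
    if np.any(a <= 0):
        raise ValueError("Gaussian exponents must be positive")
    norm = (2.0 * a / np.pi) ** 0.75

    def orbitals(points):
        pts = np.atleast_2d(points)
        out = []
        for k in range(len(a)):
            d2 = np.sum((pts - C[k]) ** 2, axis=-1)
            out.append(norm[k] * np.exp(-a[k] * d2))
        return np.stack(out)

    def orbital_grads(points):
        pts = np.atleast_2d(points)
        psi = orbitals(pts)
        out = []
        for k in range(len(a)):
            d = pts - C[k]
            out.append(-2.0 * a[k] * d * psi[k][:, None])
        return np.stack(out)

    def orbital_hess(points):
        pts = np.atleast_2d(points)
        psi = orbitals(pts)
        eye = np.eye(3)
        out = []
        for k in range(len(a)):
            d = pts - C[k]
            outer = d[:, :, None] * d[:, None, :]
            out.append((4 * a[k] ** 2 * outer - 2 * a[k] * eye) * psi[k][:, None, None])
        return np.stack(out)

    def rho(points):
        psi = orbitals(points)
        return np.einsum("k,kn->n", f, psi**2)

    def grad_rho(points):
        psi = orbitals(points)
        g = orbital_grads(points)
        return 2.0 * np.einsum("k,kn,kni->ni", f, psi, g)

    def hess_rho(points):
        psi = orbitals(points)
        g = orbital_grads(points)
        hp = orbital_hess(points)
        return 2.0 * (
            np.einsum("k,kni,knj->nij", f, g, g)
            + np.einsum("k,kn,knij->nij", f, psi, hp)
        )

    return AnalyticState(
        positions=C,
        occupations=f,
        rho_fn=rho,
        grad_rho_fn=grad_rho,
        hess_rho_fn=hess_rho,
        field_fn=_zeros_vec,
        orbitals_fn=orbitals,
        orbital_grads_fn=orbital_grads,
        orbital_hess_fn=orbital_hess,
        channels=("kinetic",),
    )


@dataclass
class ToyPES:
    """Closed-form potential-energy surface over 3N coordinates.

    ``__call__(positions)`` returns ``(energy, forces)``. A constant
    non-conservative bias can be injected on one atom as a negative
    control for the line-integral consistency test.
    """

    kind: str
    spring: np.ndarray  # (n_atoms, 3) spring constants (harmonic)
    minimum: np.ndarray  # (n_atoms, 3)
    depth: float = 1.0
    width: float = 1.0
    bias: np.ndarray = dataclass_field(default_factory=lambda: np.zeros(3))
    bias_atom: int = 0

    def __call__(self, positions):
        x = np.atleast_2d(np.asarray(positions, float))
        d = x - self.minimum
        if self.kind == "harmonic":
            e = 0.5 * float(np.sum(self.spring * d * d))
            F = -self.spring * d
        elif self.kind == "morse-like":
            r = np.sqrt(np.sum(d * d, axis=1))
            q = np.exp(-r / self.width)
            e = float(np.sum(self.depth * (1 - q) ** 2))
            # dE/dr = 2 D (1-q) q / w, so F = -(dE/dr) d_hat
            with np.errstate(invalid="ignore"):
                coef = 2 * self.depth * (1 - q) * q / (self.width * np.where(r < 1e-12, 1.0, r))
            coef = np.where(r < 1e-12, 0.0, coef)
            F = -coef[:, None] * d
        else:
            raise ValueError(f"unknown toy PES kind {self.kind!r}")
        F = F.copy()
        F[self.bias_atom] += self.bias
        return e, F


def toy_pes(
    kind: str = "harmonic",
    n_atoms: int = 3,
    spring=1.0,
    minimum=None,
    depth: float = 1.0,
    width: float = 1.0,
    bias=None,
    bias_atom: int = 0,
    seed: int = 0,
) -> ToyPES:
    """Build a toy energy/force engine with exact gradients.

    With default arguments the minimum geometry is a deterministic
    pseudo-random configuration (seeded) so circles in configuration
    space are generic.
    """
    rng = np.random.default_rng(seed)
    if minimum is None:
        minimum = rng.uniform(-1.0, 1.0, size=(n_atoms, 3))
    minimum = np.atleast_2d(np.asarray(minimum, float))
    k = np.asarray(spring, float)
    if k.ndim == 0:
        k = np.full((n_atoms, 3), float(k))
    bias_vec = np.zeros(3) if bias is None else np.asarray(bias, float)
    return ToyPES(kind, k, minimum, depth, width, bias_vec, bias_atom)
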