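"""Validation instruments for force engines.

Three independent checks of force quality:

* finite-difference forces -- central differences of the total energy,
  the model-free oracle every force method must reproduce;
* the radius scan -- surface-integral force and its error estimate as a
  function of the integration-sphere radius (the plateau defends the
  half-nearest-neighbor default);
* the line-integral consistency test -- energies along a closed circle
  in 3N-dimensional configuration space compared with the path integral
  of -F.t, which coincide exactly when forces are the true gradient of
  the energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Optional, Sequence

import numpy as np

from .stress import ForceReport, force_error_estimate, stress_force

__all__ = [
    "finite_difference_forces",
    "radius_scan",
    "LineIntegralResult",
    "line_integral_test",
    "circle_directions",
]


def finite_difference_forces(
    energy_engine: Callable,
    positions: np.ndarray,
    step: float = 1e-3,
    richardson: bool = False,
    only_atoms: Optional[Sequence[int]] = None,
) -> ForceReport:
    """Central-difference forces F = -dE/dR from an energy engine.

    ``energy_engine(positions) -> float`` must solve the electronic
    problem afresh for each displaced geometry. With ``richardson`` the
    5-point (steps `step` and 2*`step`) combination is used; choosing
    ``step`` equal to the grid spacing then cancels the periodic
    egg-box component of a grid-discretized energy surface exactly,
    leaving the smooth gradient (see docs/methods.md).
    """
    R = np.atleast_2d(np.asarray(positions, float)).copy()
    n = len(R)
    atoms = range(n) if only_atoms is None else only_atoms
    F = np.zeros((n, 3))
    for a in atoms:
        for i in range(3):
            def e_at(delta):
                Rd = R.copy()
                Rd[a, i] += delta
                return energy_engine(Rd)

            if richardson:
                d1 = e_at(step) - e_at(-step)
                d2 = e_at(2 * step) - e_at(-2 * step)
                F[a, i] = -(8 * d1 - d2) / (12 * step)
            else:
                F[a, i] = -(e_at(step) - e_at(-step)) / (2 * step)
    return ForceReport(
        method="finite_difference",
        forces=F,
        error_estimate=force_error_estimate(F),
        settings={"step": step, "richardson": richardson},
    )


def radius_scan(
    provider,
    atom_index: int,
    radii: Sequence[float],
    degree: int = 17,
) -> list:
    """Surface-integral force at each radius, with the sum-rule error
    estimate computed from the all-atom report at that radius.

    Returns a list of ``(radius, force_vector, sigma_err)`` tuples.
    """
    out = []
    n_at = len(np.atleast_2d(provider.positions))
    for r in radii:
        forces = np.stack([
            stress_force(provider, k, radius=r, degree=degree) for k in range(n_at)
        ])
        out.append((float(r), forces[atom_index], force_error_estimate(forces)))
    return out


@dataclass
class LineIntegralResult:
    """Energies along a configuration-space circle vs the reconstruction
    from the force line integral (anchored at the first node)."""

    phi: np.ndarray
    energies: np.ndarray
    reconstructed: np.ndarray
    max_deviation: float
    closure: float  # |loop integral of F . dr| over the full circle
    failures: list = dataclass_field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failures


def circle_directions(n_atoms: int, seed: int = 0) -> tuple:
    """Two seeded random orthonormal direction vectors in 3N space,
    generically oriented (no alignment with coordinate axes)."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(3 * n_atoms)
    v = rng.standard_normal(3 * n_atoms)
    u /= np.linalg.norm(u)
    v -= u * (u @ v)
    v /= np.linalg.norm(v)
    return u.reshape(n_atoms, 3), v.reshape(n_atoms, 3)


def line_integral_test(
    center_positions: np.ndarray,
    direction_u: np.ndarray,
    direction_v: np.ndarray,
    radius: float,
    n_phi: int,
    force_engine: Callable,
    energy_engine: Callable,
) -> LineIntegralResult:
    """Compare E(phi) with the trapezoidal integral of -F . t along a
    circle R(phi) = R0 + radius (cos(phi) u + sin(phi) v).

    ``force_engine(positions) -> (n_atoms, 3)`` and
    ``energy_engine(positions) -> float``. Both functions are evaluated
    at n_phi uniform nodes on (0, 2pi]; the reconstruction is anchored
    at the first node. The closure value |sum F . dR| over the full
    loop vanishes for conservative engines.
    """
    if n_phi < 8:
        raise ValueError("need at least 8 nodes on the circle")
    R0 = np.atleast_2d(np.asarray(center_positions, float))
    u = np.asarray(direction_u, float).reshape(R0.shape)
    v = np.asarray(direction_v, float).reshape(R0.shape)
    phi = 2 * np.pi * (np.arange(n_phi) + 1) / n_phi

    energies = np.empty(n_phi)
    # dE/dphi from forces: -F . dR/dphi, dR/dphi = radius(-sin u + cos v)
    dE_dphi = np.empty(n_phi)
    failures = []
    for m, p in enumerate(phi):
        pos = R0 + radius * (np.cos(p) * u + np.sin(p) * v)
        try:
            energies[m] = energy_engine(pos)
            F = np.asarray(force_engine(pos), float).reshape(R0.shape)
            tangent = radius * (-np.sin(p) * u + np.cos(p) * v)
            dE_dphi[m] = -float(np.sum(F * tangent))
        except Exception as exc:  # engine failure at a node -> partial result
            failures.append((m, repr(exc)))
            energies[m] = np.nan
            dE_dphi[m] = np.nan

    dphi = 2 * np.pi / n_phi
    recon = np.empty(n_phi)
    recon[0] = energies[0]
    for m in range(1, n_phi):
        recon[m] = recon[m - 1] + 0.5 * dphi * (dE_dphi[m - 1] + dE_dphi[m])
    closure = 0.5 * dphi * float(np.sum(dE_dphi + np.roll(dE_dphi, -1)))

    dev = np.abs(recon - energies)
    max_dev = float(np.nanmax(dev)) if np.any(np.isfinite(dev)) else np.nan
    return LineIntegralResult(phi, energies, recon, max_dev, abs(closure), failures)
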