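"""Born-Oppenheimer molecular dynamics (velocity Verlet) and a naive
geometry relaxer.

Masses are standard atomic weights in electron-mass units. The force
engine abstraction is a callable ``engine(positions) -> (energy,
forces)``; SCF-backed engines restart from the previous step's orbitals.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Optional

import numpy as np

from .constants import KB_HARTREE, mass_au

__all__ = ["MDTrajectory", "initialize_velocities", "velocity_verlet_run",
           "relax_geometry", "RelaxResult", "masses_for"]


def masses_for(symbols) -> np.ndarray:
    return np.array([mass_au(s) for s in symbols])


def initialize_velocities(
    molecule,
    temperature: float,
    seed: Optional[int] = None,
    remove_com: bool = False,
) -> np.ndarray:
    """Maxwell-Boltzmann velocities at the given temperature (kelvin).

    Each Cartesian component is normal with variance k_B T / m_k.
    Deterministic for a fixed seed. Center-of-mass motion is kept
    unless ``remove_com`` is set (then the mass-weighted mean velocity
    is subtracted).
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    m = masses_for(molecule.symbols)
    if temperature == 0:
        return np.zeros((molecule.n_atoms, 3))
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB_HARTREE * temperature / m)
    v = rng.standard_normal((molecule.n_atoms, 3)) * sigma[:, None]
    if remove_com:
        p = (m[:, None] * v).sum(axis=0) / m.sum()
        v = v - p
    return v


@dataclass
class MDTrajectory:
    times: np.ndarray  # (n_frames,) a.u.
    positions: np.ndarray  # (n_frames, n_atoms, 3)
    velocities: np.ndarray
    potential_energies: np.ndarray
    kinetic_energies: np.ndarray
    dt: float
    force_method: str = ""
    truncated: bool = False
    seed_info: dict = dataclass_field(default_factory=dict)

    @property
    def total_energies(self) -> np.ndarray:
        return self.potential_energies + self.kinetic_energies

    @property
    def n_frames(self) -> int:
        return len(self.times)


def velocity_verlet_run(
    molecule,
    positions0: np.ndarray,
    velocities0: np.ndarray,
    dt: float,
    n_steps: int,
    engine: Callable,
    force_method: str = "",
) -> MDTrajectory:
    """Velocity-Verlet propagation.

    Standard update: x += v dt + (F/m) dt^2/2; recompute F; v += dt
    (F_old + F_new)/(2 m). If the engine raises mid-trajectory the
    trajectory is returned truncated and flagged.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    m = masses_for(molecule.symbols)[:, None]
    x = np.atleast_2d(np.asarray(positions0, float)).copy()
    v = np.asarray(velocities0, float).copy()

    e_pot, F = engine(x)
    frames = {"t": [0.0], "x": [x.copy()], "v": [v.copy()], "epot": [e_pot],
              "ekin": [float(np.sum(0.5 * m * v * v))]}
    truncated = False
    for step in range(1, n_steps + 1):
        x = x + v * dt + 0.5 * (F / m) * dt * dt
        try:
            e_pot, F_new = engine(x)
        except Exception:
            truncated = True
            break
        v = v + 0.5 * dt * (F + F_new) / m
        F = F_new
        frames["t"].append(step * dt)
        frames["x"].append(x.copy())
        frames["v"].append(v.copy())
        frames["epot"].append(e_pot)
        frames["ekin"].append(float(np.sum(0.5 * m * v * v)))
    return MDTrajectory(
        times=np.array(frames["t"]),
        positions=np.array(frames["x"]),
        velocities=np.array(frames["v"]),
        potential_energies=np.array(frames["epot"]),
        kinetic_energies=np.array(frames["ekin"]),
        dt=dt,
        force_method=force_method,
        truncated=truncated,
    )


@dataclass
class RelaxResult:
    positions: np.ndarray
    converged: bool
    n_steps: int
    force_norms: list  # max |F component| per iteration
    energies: list


def relax_geometry(
    positions0: np.ndarray,
    engine: Callable,
    max_force: float = 1e-4,
    max_steps: int = 200,
    step0: float = 0.5,
) -> RelaxResult:
    """Damped gradient-descent relaxer with an adaptive step size.

    Walks along the force with step length alpha (grown 1.1x after a
    downhill move, halved on an uphill one) until every force component
    is below ``max_force``. Deliberately simple: the quality of the
    forces, not the optimizer, is what the diagnostics probe.
    """
    x = np.atleast_2d(np.asarray(positions0, float)).copy()
    e, F = engine(x)
    norms = [float(np.max(np.abs(F)))]
    energies = [e]
    if norms[0] < max_force:
        return RelaxResult(x, True, 0, norms, energies)
    alpha = step0
    for step in range(1, max_steps + 1):
        x_new = x + alpha * F
        e_new, F_new = engine(x_new)
        if e_new <= e + 1e-12:
            x, e, F = x_new, e_new, F_new
            alpha = min(alpha * 1.1, 2.0)
        else:
            alpha = max(alpha * 0.5, 1e-4)
        norms.append(float(np.max(np.abs(F))))
        energies.append(e)
        if np.max(np.abs(F)) < max_force:
            return RelaxResult(x, True, step, norms, energies)
    return RelaxResult(x, False, max_steps, norms, energies)
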