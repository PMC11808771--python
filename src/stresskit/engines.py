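"""SCF-backed energy/force engines.

Bridge between the electronic-structure layer and the consumers that
repeatedly re-solve at displaced geometries (finite-difference forces,
line-integral test, MD, relaxation). Engines keep the grid fixed and
warm-start each solve from the previous orbitals.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .fields import UniformGrid, make_grid
from .scf import run_scf, solve_one_electron
from .stress import GridStateProvider, hellmann_feynman_force, stress_force_report
from .xc import XCFunctional, svwn5

__all__ = ["ScfEngine"]


class ScfEngine:
    """Callable engine: ``engine(positions) -> (energy, forces)``.

    ``method`` selects the force engine: 'stress' (surface integral),
    'hf' (Hellmann-Feynman) or 'none' (energies only). The grid is
    built once from the initial geometry and reused, so displaced
    geometries must stay within the original margins.
    """

    def __init__(
        self,
        molecule,
        spacing: float = 0.25,
        margin: float = 6.0,
        functional: XCFunctional = svwn5,
        charge: int = 0,
        one_electron: bool = False,
        method: str = "stress",
        eig_tol: float = 1e-8,
        scf_tol_energy: float = 1e-8,
        scf_tol_density: float = 1e-6,
        degree: int = 17,
        radius_fraction: float = 0.5,
        grid: Optional[UniformGrid] = None,
        warm_start: bool = True,
    ):
        if method not in ("stress", "hf", "none"):
            raise ValueError(f"unknown force method {method!r}")
        self.template = molecule
        self.functional = functional
        self.charge = charge
        self.one_electron = one_electron
        self.method = method
        self.eig_tol = eig_tol
        self.scf_tol_energy = scf_tol_energy
        self.scf_tol_density = scf_tol_density
        self.degree = degree
        self.radius_fraction = radius_fraction
        self.grid = grid if grid is not None else make_grid(molecule, spacing, margin)
        self.warm_start = warm_start
        self._last_orbitals = None
        self._last_density = None
        self.last_state = None
        self.n_solves = 0

    def solve(self, positions):
        mol = self.template.with_positions(positions)
        x0 = self._last_orbitals if self.warm_start else None
        if self.one_electron:
            state = solve_one_electron(
                mol, grid=self.grid, eig_tol=self.eig_tol, initial_orbitals=x0
            )
        else:
            state = run_scf(
                mol,
                functional=self.functional,
                charge=self.charge,
                grid=self.grid,
                eig_tol=self.eig_tol,
                tol_energy=self.scf_tol_energy,
                tol_density=self.scf_tol_density,
                initial_orbitals=x0,
                initial_density=self._last_density if self.warm_start else None,
            )
        if self.warm_start:
            self._last_orbitals = state.orbitals
            self._last_density = state.rho.values
        self.last_state = state
        self.n_solves += 1
        return state

    def energy(self, positions) -> float:
        return self.solve(positions).energy

    def force_report(self, positions):
        state = self.solve(positions)
        if self.method == "hf":
            return state, hellmann_feynman_force(state)
        provider = GridStateProvider(state)
        return state, stress_force_report(
            provider, degree=self.degree, radius_fraction=self.radius_fraction
        )

    def forces(self, positions):
        state, report = self.force_report(positions)
        return state.energy, report.forces

    def __call__(self, positions):
        return self.forces(positions)
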