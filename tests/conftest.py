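"""Shared fixtures: small grids and a couple of expensive shared states."""

import numpy as np
import pytest

from stresskit import Molecule, make_grid, solve_one_electron


@pytest.fixture(scope="session")
def h2plus_molecule():
    return Molecule.from_symbols(
        ["H", "H"], [[0.0, 0.0, -1.0], [0.0, 0.0, 1.0]], smoothing=0.2
    )


@pytest.fixture(scope="session")
def h2plus_state(h2plus_molecule):
    """Converged one-electron H2+ state on a modest grid, reused by the
    stress/force tests (box 16 bohr, h = 0.25, c = 0.2)."""
    grid = make_grid(h2plus_molecule, 0.25, 7.0)
    return solve_one_electron(h2plus_molecule, grid=grid, eig_tol=1e-9)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
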