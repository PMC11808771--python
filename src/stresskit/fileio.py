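"""File formats: XYZ (angstrom), Gaussian cube (bohr), TOML run
configuration, and JSON reports.

XYZ follows the standard two-header-line dialect; cube files use the
conventional layout (two comment lines; atom count + origin; three
voxel-vector rows; one row per atom with Z, charge, position; volumetric
data in z-fastest order). Cube round-trips are bit-exact through the
%.17g representation.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Optional

import numpy as np

from .constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM, SYMBOL_TO_Z, Z_TO_SYMBOL, normalize_symbol
from .fields import ScalarField, UniformGrid
from .lebedev import available_degrees
from .molecule import Molecule, smoothing_length

__all__ = ["read_xyz", "write_xyz", "read_cube", "write_cube",
           "RunConfig", "read_config", "write_extended_xyz_frame"]


# ---------------------------------------------------------------------------
# XYZ


def read_xyz(path, smoothing=None, smoothing_precision: float = 1e-5) -> Molecule:
    """Read a standard XYZ file (coordinates in angstrom -> bohr).

    Per-atom smoothing lengths default to the smoothing_length rule at
    ``smoothing_precision`` unless an explicit value is given.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}:1: malformed atom count line {lines[0]!r}") from None
    body = lines[2 : 2 + count]
    if len(body) < count:
        raise ValueError(
            f"{path}: expected {count} atom lines, found {len(body)}"
        )
    symbols, coords = [], []
    for i, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{i}: expected 'symbol x y z', got {line!r}")
        sym = normalize_symbol(parts[0])
        if sym not in SYMBOL_TO_Z:
            raise ValueError(f"{path}:{i}: unknown element {parts[0]!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ValueError(f"{path}:{i}: non-numeric coordinate in {line!r}") from None
        symbols.append(sym)
        coords.append(xyz)
    positions = np.asarray(coords) * BOHR_PER_ANGSTROM
    if smoothing is None:
        smoothing = np.array(
            [smoothing_length(SYMBOL_TO_Z[s], smoothing_precision) for s in symbols]
        )
    return Molecule.from_symbols(symbols, positions, smoothing)


def write_xyz(molecule: Molecule, path, comment: str = "") -> None:
    lines = [str(molecule.n_atoms), comment.replace("\n", " ")]
    for sym, pos in zip(molecule.symbols, molecule.positions):
        x, y, z = pos * ANGSTROM_PER_BOHR
        lines.append(f"{sym} {x:.12f} {y:.12f} {z:.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_extended_xyz_frame(handle, molecule: Molecule, positions_bohr,
                             energy: float, time_au: Optional[float] = None) -> None:
    """Append one extended-XYZ frame (positions in angstrom, energy in
    the comment field) to an open text handle."""
    comment = f"energy={energy:.12f}"
    if time_au is not None:
        comment += f" time={time_au:.4f}"
    handle.write(f"{molecule.n_atoms}\n{comment}\n")
    for sym, pos in zip(molecule.symbols, np.atleast_2d(positions_bohr)):
        x, y, z = np.asarray(pos) * ANGSTROM_PER_BOHR
        handle.write(f"{sym} {x:.12f} {y:.12f} {z:.12f}\n")


# ---------------------------------------------------------------------------
# Gaussian cube


def write_cube(field: ScalarField, path, molecule: Optional[Molecule] = None,
               comment: str = "stresskit scalar field") -> None:
    grid = field.grid
    n_at = molecule.n_atoms if molecule is not None else 0
    h = grid.spacing
    lines = [comment, "cube written by stresskit (bohr)"]
    ox, oy, oz = grid.origin
    lines.append(f"{n_at:5d} {ox:.17g} {oy:.17g} {oz:.17g}")
    for ax in range(3):
        v = [0.0, 0.0, 0.0]
        v[ax] = h
        lines.append(f"{grid.shape[ax]:5d} {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
    if molecule is not None:
        for z, pos in zip(molecule.charges, molecule.positions):
            lines.append(
                f"{int(z):5d} {float(z):.17g} {pos[0]:.17g} {pos[1]:.17g} {pos[2]:.17g}"
            )
    vals = field.values.reshape(-1)  # C order = z fastest
    for start in range(0, len(vals), 6):
        lines.append(" ".join(f"{v:.17g}" for v in vals[start : start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path):
    """Read a cube file -> (ScalarField, Molecule | None).

    Only axis-aligned isotropic voxel vectors are supported (the only
    kind this package writes).
    """
    lines = Path(path).read_text().splitlines()
    header = lines[2].split()
    n_at = int(header[0])
    origin = tuple(float(x) for x in header[1:4])
    shape = []
    spacings = []
    for ax in range(3):
        parts = lines[3 + ax].split()
        shape.append(int(parts[0]))
        vec = np.array([float(p) for p in parts[1:4]])
        if np.count_nonzero(vec) != 1 or vec[ax] <= 0:
            raise ValueError(f"{path}: unsupported (non axis-aligned) voxel vector {vec}")
        spacings.append(vec[ax])
    if not np.allclose(spacings, spacings[0], rtol=0, atol=1e-15):
        raise ValueError(f"{path}: anisotropic spacing {spacings} unsupported")
    molecule = None
    atom_lines = lines[6 : 6 + abs(n_at)]
    data_start = 6 + abs(n_at)
    if n_at > 0:
        Zs, pos = [], []
        for line in atom_lines:
            parts = line.split()
            Zs.append(int(parts[0]))
            pos.append([float(p) for p in parts[2:5]])
        symbols = [Z_TO_SYMBOL[z] for z in Zs]
        molecule = Molecule.from_symbols(symbols, np.array(pos), 0.2)
    flat = []
    for line in lines[data_start:]:
        flat.extend(float(p) for p in line.split())
    grid = UniformGrid(origin, spacings[0], tuple(shape))
    values = np.asarray(flat).reshape(tuple(shape))
    return ScalarField(grid, values), molecule


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved run configuration with provenance.

    ``provenance`` maps each key to 'default' or 'file'. All numeric
    entries are validated for sign/range; unknown keys in the file are
    fatal (silent typos in tolerance names are worse than errors).
    """

    spacing: float = 0.25
    margin: float = 6.0
    smoothing: Optional[float] = None  # None -> derive from smoothing_precision
    smoothing_precision: float = 1e-5
    functional: str = "svwn5"
    charge: int = 0
    one_electron: bool = False
    scf_tol_energy: float = 1e-8
    scf_tol_density: float = 1e-6
    scf_max_iter: int = 60
    eig_tol: float = 1e-8
    mixing: float = 0.3
    fd_accuracy: int = 4
    lebedev_order: int = 17
    radius_fraction: float = 0.5
    force_method: str = "stress"
    md_dt: float = 10.3
    md_steps: int = 20
    md_temperature: float = 500.0
    md_remove_com: bool = False
    relax_max_force: float = 1e-4
    relax_max_steps: int = 200
    seed: int = 0
    provenance: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        positive = ["spacing", "scf_tol_energy", "scf_tol_density", "eig_tol",
                    "mixing", "md_dt", "md_temperature", "relax_max_force",
                    "smoothing_precision"]
        for key in positive:
            if getattr(self, key) is not None and getattr(self, key) <= 0:
                raise ValueError(f"config: {key} must be positive, got {getattr(self, key)}")
        if self.margin < 0:
            raise ValueError("config: margin must be >= 0")
        if self.smoothing is not None and self.smoothing <= 0:
            raise ValueError("config: smoothing must be positive")
        if self.lebedev_order not in available_degrees():
            raise ValueError(
                f"config: lebedev_order {self.lebedev_order} not tabulated; "
                f"supported orders: {available_degrees()}"
            )
        if not (0 < self.radius_fraction <= 1):
            raise ValueError("config: radius_fraction must be in (0, 1]")
        if self.fd_accuracy not in (2, 4, 6):
            raise ValueError("config: fd_accuracy must be one of 2, 4, 6")
        if self.force_method not in ("stress", "hf", "fd", "all"):
            raise ValueError(f"config: unknown force_method {self.force_method!r}")
        if self.functional not in ("svwn5", "slater", "none"):
            raise ValueError(f"config: unknown functional {self.functional!r}")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        from . import __version__

        d["code_version"] = __version__
        return d


def read_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Parse a TOML config file; unknown keys are fatal. Returns the
    resolved config with per-key provenance recorded."""
    data = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(RunConfig)} - {"provenance"}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"config: unknown keys {sorted(unknown)}; valid keys: {sorted(valid)}")
    provenance = {k: ("file" if k in data else "default") for k in valid}
    typed = {}
    for f in dataclasses.fields(RunConfig):
        if f.name in data:
            value = data[f.name]
            if f.name in ("charge", "scf_max_iter", "md_steps", "relax_max_steps",
                          "seed", "lebedev_order", "fd_accuracy"):
                if not isinstance(value, int):
                    raise ValueError(f"config: {f.name} must be an integer, got {value!r}")
            elif f.name in ("one_electron", "md_remove_com"):
                if not isinstance(value, bool):
                    raise ValueError(f"config: {f.name} must be a boolean, got {value!r}")
            elif f.name in ("functional", "force_method"):
                if not isinstance(value, str):
                    raise ValueError(f"config: {f.name} must be a string, got {value!r}")
            else:
                if isinstance(value, bool) or not isinstance(value, (int, float)):
                    raise ValueError(f"config: {f.name} must be a number, got {value!r}")
                value = float(value)
            typed[f.name] = value
    return RunConfig(**typed, provenance=provenance)
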