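"""Minimal closed-shell real-space Kohn-Sham solver.

The Hamiltonian T + V_eff is applied matrix-free on the uniform grid
(finite-difference kinetic operator, zero Dirichlet boundaries);
eigenpairs come from block LOBPCG with a Fourier-space kinetic
preconditioner. The SCF loop uses linear density mixing.

One-electron mode performs a single exact diagonalization of
T + V_ext with Hartree and exchange-correlation terms excluded from the
Hamiltonian (no self-interaction); the Hartree potential of the density
is still computed and stored because the stress machinery needs the
electronic electric field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.fft import rfftn, irfftn
from scipy.sparse.linalg import LinearOperator, lobpcg

from .fields import (
    FieldInterpolator,
    ScalarField,
    UniformGrid,
    _D2_STENCILS,
    differentiate,
    make_grid,
    poisson_free_space,
    volume_integrate,
)
from .molecule import Molecule, external_potential, nuclear_repulsion_energy
from .xc import XCFunctional, no_xc, svwn5, xc_eval

__all__ = ["KohnShamState", "run_scf", "solve_one_electron", "total_energy",
           "ScfError", "eigen_residuals"]


class ScfError(RuntimeError):
    """Raised on non-convergence; carries the residual history."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


@dataclass
class KohnShamState:
    molecule: Molecule
    grid: UniformGrid
    orbitals: np.ndarray  # (n_orb, n1, n2, n3), real
    occupations: np.ndarray  # f_k in (0, 2]
    eigenvalues: np.ndarray  # hartree
    rho: ScalarField
    v_hartree: ScalarField
    v_xc: ScalarField
    v_ext: ScalarField
    eps_xc: ScalarField
    functional: XCFunctional
    energy_terms: dict
    converged: bool
    residual_history: list = dataclass_field(default_factory=list)
    one_electron: bool = False
    fd_accuracy: int = 4
    _electron_field_interp: Optional[FieldInterpolator] = dataclass_field(
        default=None, repr=False, compare=False
    )

    @property
    def n_electrons(self) -> float:
        return float(self.occupations.sum())

    @property
    def energy(self) -> float:
        return float(self.energy_terms["total"])

    def electron_field_at(self, points: np.ndarray) -> np.ndarray:
        """Electric field of the electron cloud, E_e = +grad(v_H)."""
        if self._electron_field_interp is None:
            grad_vh = differentiate(self.v_hartree, "gradient", self.fd_accuracy)
            object.__setattr__(self, "_electron_field_interp", FieldInterpolator(grad_vh))
        return self._electron_field_interp(points)


# ---------------------------------------------------------------------------
# Hamiltonian application and eigensolver


def _kinetic_apply(psi: np.ndarray, h: float, accuracy: int) -> np.ndarray:
    w = _D2_STENCILS[accuracy]
    out = ndimage.correlate1d(psi, w, axis=0, mode="constant")
    out += ndimage.correlate1d(psi, w, axis=1, mode="constant")
    out += ndimage.correlate1d(psi, w, axis=2, mode="constant")
    return out * (-0.5 / h**2)


def _kinetic_symbol(shape, h: float, accuracy: int) -> np.ndarray:
    """Fourier symbol of the FD kinetic operator (periodic surrogate)."""
    w = _D2_STENCILS[accuracy]
    half = len(w) // 2
    syms = []
    freqs = [np.fft.fftfreq(shape[0]), np.fft.fftfreq(shape[1]), np.fft.rfftfreq(shape[2])]
    for f in freqs:
        theta = 2 * np.pi * f
        s = np.full_like(theta, w[half])
        for j in range(1, half + 1):
            s += 2 * w[half + j] * np.cos(j * theta)
        syms.append(-0.5 * s / h**2)
    return syms[0][:, None, None] + syms[1][None, :, None] + syms[2][None, None, :]


def _solve_eigenpairs(grid, v_eff, n_states, x0=None, tol=1e-7, accuracy=4,
                      maxiter=400):
    """Lowest eigenpairs of T + V on the grid via preconditioned LOBPCG.

    Returns (eigenvalues, orbitals (n_states, *shape)) with orbitals
    L2-normalized on the grid measure (int psi^2 = 1).
    """
    shape = grid.shape
    h = grid.spacing
    N = grid.npoints
    v = v_eff.values.ravel()

    def _ham(mat):
        mat = mat.reshape(N, -1)
        out = np.empty_like(mat)
        for j in range(mat.shape[1]):
            psi = mat[:, j].reshape(shape)
            out[:, j] = (_kinetic_apply(psi, h, accuracy) + v.reshape(shape) * psi).ravel()
        return out

    sym = _kinetic_symbol(shape, h, accuracy)
    shift = 1.0
    denom = sym + shift

    def _prec(mat):
        mat = mat.reshape(N, -1)
        out = np.empty_like(mat)
        for j in range(mat.shape[1]):
            psi = mat[:, j].reshape(shape)
            out[:, j] = irfftn(rfftn(psi) / denom, shape).ravel()
        return out

    A = LinearOperator((N, N), matvec=_ham, matmat=_ham, dtype=float)
    M = LinearOperator((N, N), matvec=_prec, matmat=_prec, dtype=float)

    m = n_states + 1
    if x0 is None or x0.shape[1] < m:
        raise ValueError("initial block required")
    X = np.ascontiguousarray(x0[:, :m])
    X, _ = np.linalg.qr(X)

    def _run(X0, iters):
        import warnings as _warnings

        with _warnings.catch_warnings():
            # the guard vector rarely reaches the block tolerance; we
            # check the residuals of the kept states explicitly below
            _warnings.simplefilter("ignore", UserWarning)
            return lobpcg(A, X0, M=M, tol=tol, maxiter=iters, largest=False)

    vals, vecs = _run(X, maxiter)
    # explicit residual check on the states we keep; one restart if needed
    for _ in range(2):
        order = np.argsort(vals)[:n_states]
        res = _ham(vecs[:, order]) - vecs[:, order] * vals[order]
        worst = max(
            np.linalg.norm(res[:, j]) / np.linalg.norm(vecs[:, order[j]])
            for j in range(n_states)
        )
        if worst <= 10 * tol:
            break
        vals, vecs = _run(np.ascontiguousarray(vecs), maxiter)
    order = np.argsort(vals)[:n_states]
    vals = vals[order]
    vecs = vecs[:, order]
    # normalize on the grid measure and fix sign (largest-|psi| component > 0)
    orbitals = np.empty((n_states,) + shape)
    for k in range(n_states):
        p = vecs[:, k]
        p = p / (np.linalg.norm(p) * h**1.5)
        imax = np.argmax(np.abs(p))
        if p[imax] < 0:
            p = -p
        orbitals[k] = p.reshape(shape)
    return vals, orbitals


def eigen_residuals(state: KohnShamState) -> np.ndarray:
    """||H psi - eps psi|| / ||psi|| for each occupied orbital."""
    h = state.grid.spacing
    v = state.v_ext.values.copy()
    if not state.one_electron:
        v += state.v_hartree.values + state.v_xc.values
    out = []
    for k in range(len(state.eigenvalues)):
        psi = state.orbitals[k]
        r = _kinetic_apply(psi, h, state.fd_accuracy) + v * psi - state.eigenvalues[k] * psi
        out.append(np.linalg.norm(r) / np.linalg.norm(psi))
    return np.array(out)


# ---------------------------------------------------------------------------
# initial guesses


def _gaussian_guess(molecule: Molecule, grid: UniformGrid, n_vectors: int,
                    seed=None, perturb: float = 0.0) -> np.ndarray:
    """Atom-centered Gaussians (widths ~1/Z) plus p-like shapes; columns
    of the returned (N, n_vectors) block. Deterministic unless a seeded
    perturbation is requested."""
    X, Y, Z = grid.meshgrid()
    cols = []
    n_at = molecule.n_atoms
    for i in range(n_vectors):
        a = i % n_at
        R = molecule.positions[a]
        width = max(0.5 / molecule.charges[a], 0.2) * (1.0 + 0.3 * (i // n_at))
        dx, dy, dz = X - R[0], Y - R[1], Z - R[2]
        g = np.exp(-(dx**2 + dy**2 + dz**2) / (2 * width**2))
        shell = i // n_at
        if shell % 4 == 1:
            g = g * dx
        elif shell % 4 == 2:
            g = g * dy
        elif shell % 4 == 3:
            g = g * dz
        cols.append(g.ravel())
    block = np.stack(cols, axis=1)
    if perturb > 0.0:
        rng = np.random.default_rng(seed)
        block = block + perturb * rng.standard_normal(block.shape) * np.abs(block).max()
    return block


def _density_from_orbitals(grid, orbitals, occupations) -> ScalarField:
    rho = np.zeros(grid.shape)
    for f, psi in zip(occupations, orbitals):
        rho += f * psi**2
    return ScalarField(grid, rho)


def _mix_density(rho, rho_out, mixing, hist, grid, depth: int = 3):
    """Anderson-accelerated linear mixing (depth-3 history).

    Minimizes the residual over the affine span of the last few
    (input, residual) pairs, then applies simple mixing along the
    optimized direction. Falls back to plain linear mixing while the
    history is short or the least-squares system is degenerate.
    """
    x = rho.values.ravel()
    f = rho_out.values.ravel() - x  # residual
    hist.append((x.copy(), f.copy()))
    if len(hist) > depth + 1:
        hist.pop(0)
    if len(hist) >= 2:
        dF = np.stack([hist[-1][1] - h[1] for h in hist[:-1]], axis=1)
        dX = np.stack([hist[-1][0] - h[0] for h in hist[:-1]], axis=1)
        try:
            theta, *_ = np.linalg.lstsq(dF, f, rcond=1e-10)
            x_opt = x - dX @ theta
            f_opt = f - dF @ theta
            new = x_opt + mixing * f_opt
            if np.all(np.isfinite(new)):
                return ScalarField(grid, new.reshape(grid.shape))
        except np.linalg.LinAlgError:
            pass
    return ScalarField(grid, (x + mixing * f).reshape(grid.shape))


# ---------------------------------------------------------------------------
# energies


def _energy_terms(molecule, grid, orbitals, occupations, rho, v_ext, v_h,
                  eps_xc, accuracy, one_electron):
    h = grid.spacing
    t_s = 0.0
    for f, psi in zip(occupations, orbitals):
        t_s += f * float(np.sum(psi * _kinetic_apply(psi, h, accuracy))) * h**3
    e_ext = float(np.sum(rho.values * v_ext.values)) * h**3
    if one_electron:
        e_h = 0.0
        e_xc = 0.0
    else:
        e_h = 0.5 * float(np.sum(rho.values * v_h.values)) * h**3
        e_xc = float(np.sum(rho.values * eps_xc.values)) * h**3
    e_nn = nuclear_repulsion_energy(molecule)
    total = t_s + e_ext + e_h + e_xc + e_nn
    return {
        "kinetic": t_s,
        "external": e_ext,
        "hartree": e_h,
        "xc": e_xc,
        "nuclear": e_nn,
        "total": total,
    }


def total_energy(state: KohnShamState):
    """Recompute the total energy and its breakdown from the state.

    Returns ``(total, terms)``; the terms sum to the total to round-off.
    """
    terms = _energy_terms(
        state.molecule, state.grid, state.orbitals, state.occupations,
        state.rho, state.v_ext, state.v_hartree, state.eps_xc,
        state.fd_accuracy, state.one_electron,
    )
    return terms["total"], terms


# ---------------------------------------------------------------------------
# drivers


def run_scf(
    molecule: Molecule,
    spacing: float = 0.25,
    margin: float = 6.0,
    functional: XCFunctional = svwn5,
    charge: int = 0,
    one_electron: bool = False,
    tol_energy: float = 1e-8,
    tol_density: float = 1e-6,
    mixing: float = 0.3,
    max_iter: int = 60,
    eig_tol: float = 1e-7,
    fd_accuracy: int = 4,
    grid: Optional[UniformGrid] = None,
    seed: Optional[int] = None,
    perturb: float = 0.0,
    initial_orbitals: Optional[np.ndarray] = None,
    initial_density: Optional[np.ndarray] = None,
) -> KohnShamState:
    """Self-consistent Kohn-Sham ground state.

    ``charge`` is the net molecular charge (H2+ -> charge=1). The
    electron count must be even unless ``one_electron`` is set, in which
    case a single exact diagonalization of T + V_ext is performed.
    """
    n_elec = molecule.n_electrons_neutral - charge
    if n_elec <= 0:
        raise ValueError(f"no electrons left (charge {charge})")
    if one_electron:
        if n_elec != 1:
            raise ValueError(f"one-electron mode needs exactly 1 electron, got {n_elec}")
        occupations = np.array([1.0])
    else:
        if n_elec % 2:
            raise ValueError(
                f"odd electron count {n_elec} unsupported without one_electron mode"
            )
        occupations = np.full(n_elec // 2, 2.0)
    n_orb = len(occupations)

    if grid is None:
        grid = make_grid(molecule, spacing, margin)
    v_ext = external_potential(molecule, grid)
    h = grid.spacing

    if initial_orbitals is not None:
        x0 = initial_orbitals.reshape(initial_orbitals.shape[0], -1).T.copy()
        if x0.shape[1] < n_orb + 1:
            extra = _gaussian_guess(molecule, grid, n_orb + 1 - x0.shape[1], seed, perturb)
            x0 = np.concatenate([x0, extra], axis=1)
    else:
        x0 = _gaussian_guess(molecule, grid, n_orb + 1, seed, perturb)

    func = no_xc if one_electron else functional
    history = []

    if one_electron:
        vals, orbitals = _solve_eigenpairs(grid, v_ext, n_orb, x0, eig_tol, fd_accuracy)
        rho = _density_from_orbitals(grid, orbitals, occupations)
        v_h = poisson_free_space(rho)
        zero = ScalarField(grid, np.zeros(grid.shape))
        terms = _energy_terms(molecule, grid, orbitals, occupations, rho,
                              v_ext, v_h, zero, fd_accuracy, True)
        return KohnShamState(
            molecule, grid, orbitals, occupations, vals, rho, v_h,
            zero, v_ext, zero.copy(), func, terms, True, history,
            one_electron=True, fd_accuracy=fd_accuracy,
        )

    # initial density: warm start if provided, else superposition of
    # atomic Gaussians normalized to N
    if initial_density is not None:
        rho_vals = np.asarray(initial_density, float).reshape(grid.shape).copy()
    else:
        guess_block = _gaussian_guess(molecule, grid, molecule.n_atoms)
        rho_vals = np.sum(guess_block**2, axis=1).reshape(grid.shape)
    rho_vals *= n_elec / (rho_vals.sum() * h**3)
    rho = ScalarField(grid, rho_vals)

    e_prev = np.inf
    e_nn = nuclear_repulsion_energy(molecule)
    orbitals = None
    mix_hist: list = []  # (rho_in, residual) pairs for Anderson mixing
    for it in range(max_iter):
        v_h = poisson_free_space(rho)
        eps_xc_f, v_xc_f, _ = xc_eval(func, rho)
        v_eff = ScalarField(grid, v_ext.values + v_h.values + v_xc_f.values)
        vals, orbitals = _solve_eigenpairs(grid, v_eff, n_orb, x0, eig_tol, fd_accuracy)
        x0 = orbitals.reshape(n_orb, -1).T.copy()
        extra = _gaussian_guess(molecule, grid, 1, seed, 0.0)
        x0 = np.concatenate([x0, extra], axis=1)
        rho_out = _density_from_orbitals(grid, orbitals, occupations)
        d_rho = float(np.linalg.norm(rho_out.values - rho.values) * h**1.5)
        # Harris-style energy from input-density potentials (no extra
        # Poisson/xc evaluation; exact at self-consistency)
        band = float(np.dot(occupations, vals))
        e_harris = (
            band
            - float(np.sum(rho_out.values * (v_h.values + v_xc_f.values))) * h**3
            + 0.5 * float(np.sum(rho.values * v_h.values)) * h**3
            + float(np.sum(rho.values * eps_xc_f.values)) * h**3
            + e_nn
        )
        d_e = abs(e_harris - e_prev)
        history.append({"iteration": it, "energy": e_harris,
                        "d_energy": d_e, "d_density": d_rho})
        e_prev = e_harris
        if d_rho < tol_density and d_e < tol_energy:
            rho = rho_out
            break
        rho = _mix_density(rho, rho_out, mixing, mix_hist, grid)
    else:
        raise ScfError(
            f"SCF did not converge in {max_iter} iterations "
            f"(last d_rho={history[-1]['d_density']:.2e}, d_E={history[-1]['d_energy']:.2e})",
            history,
        )

    v_h = poisson_free_space(rho)
    eps_xc_f, v_xc_f, _ = xc_eval(func, rho)
    terms = _energy_terms(molecule, grid, orbitals, occupations, rho, v_ext,
                          v_h, eps_xc_f, fd_accuracy, False)
    return KohnShamState(
        molecule, grid, orbitals, occupations, vals, rho, v_h, v_xc_f,
        v_ext, eps_xc_f, func, terms, True, history,
        one_electron=False, fd_accuracy=fd_accuracy,
    )


def solve_one_electron(molecule: Molecule, spacing: float = 0.25,
                       margin: float = 6.0, grid: Optional[UniformGrid] = None,
                       eig_tol: float = 1e-8, fd_accuracy: int = 4,
                       initial_orbitals=None,
                       charge: Optional[int] = None) -> KohnShamState:
    """Exact single diagonalization for one-electron systems (oracle mode).

    With ``charge=None`` the molecule is ionized down to one electron
    (H -> H, H2 -> H2+); an explicit charge that leaves more than one
    electron is an error.
    """
    if charge is None:
        charge = molecule.n_electrons_neutral - 1
    return run_scf(
        molecule,
        spacing=spacing,
        margin=margin,
        charge=charge,
        one_electron=True,
        eig_tol=eig_tol,
        fd_accuracy=fd_accuracy,
        grid=grid,
        initial_orbitals=initial_orbitals,
    )
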