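# Methods

`stresskit` computes forces on nuclei in Kohn–Sham density functional
theory by integrating the quantum-mechanical stress tensor over
atom-centered spheres, and provides the reference machinery (a
real-space Kohn–Sham solver, Hellmann–Feynman and finite-difference
forces, consistency diagnostics, Born–Oppenheimer dynamics) needed to
measure the quality of those forces without any external code. This
note records the model, the numerical choices, and what the tests do
and do not demonstrate.

All internal quantities are in Hartree atomic units; XYZ files are
read and written in ångström (1 Å = 1.8897259886 bohr).

## Electronic structure model

Closed-shell (spin-restricted) Kohn–Sham DFT on a uniform isotropic
Cartesian grid. Orbitals are real; occupations are 2 except in the
one-electron mode (occupation 1, Hartree and exchange-correlation
terms removed from the Hamiltonian — no self-interaction). The
built-in functional is SVWN5 (Slater exchange plus the VWN5
parametrization of the homogeneous-electron-gas correlation,
implemented by formula); any LDA or GGA evaluator with the documented
contract can be plugged in, including the analytic "toy GGA"
`eps_xc = -a rho^(1/3) - b |grad rho|^2 rho^(-4/3)` used in tests.

The electron–nucleus attraction uses the smoothed finite-nucleus
potential `U(r) = u(r/c)/c` with

    u(x) = erf(x)/x + (1/(3 sqrt(pi))) (exp(-x^2) + 16 exp(-4 x^2)),

finite and smooth at the origin and equal to 1/x beyond a few x. The
per-element length scale defaults to `c = (eps / (0.00435 Z^5))^(1/3)`
for a target precision eps (the energy error of the smoothed model
scales as ~0.00435 Z^5 c^3); the rule is pluggable. Nuclear–nuclear
repulsion uses point charges: at bond-length separations the smeared
correction is below round-off (u(x) − 1/x ≈ e^(−x²) at x = R/c ≳ 7).

**Resolvability requirement.** A uniform grid, unlike an adaptive
basis, cannot represent structure below its spacing. The smoothing
length must be grid-resolvable, c ≳ 2h, for the solver to be
trustworthy: with c ≲ h the discrete eigenvalue error is dominated by
the unresolved core and falls only as O(h²) regardless of stencil
order (measured on hydrogen: +5.0e−3 hartree at h = 0.15 for c = 0.01,
versus −1.8e−4 at h = 0.2 for c = 0.4), and the egg-box modulation of
the energy as atoms move relative to the grid becomes large — for
c < h a nucleus crossing a grid node creates a transient spurious
potential well of depth ~u(0)/c that can destabilize dynamics
entirely. Study conditions in the tests respect c ≳ 2h unless a
deliberately coarse grid is the point of the experiment.

Discretization: centered finite differences of accuracy order 4
(configurable 2/4/6) for the kinetic operator and all field
derivatives; zero Dirichlet boundaries (orbitals decay in the vacuum
margin). Eigenpairs come from block LOBPCG, matrix-free, with a
Fourier-space kinetic preconditioner (1/(T(k) + 1)); one guard vector
is carried beyond the occupied block and residuals of the kept states
are verified explicitly (‖Hψ−εψ‖/‖ψ‖ ≲ 10× the requested tolerance,
with one restart if needed). The SCF loop mixes the density with
Anderson-accelerated linear mixing (depth 3, step 0.3 by default) and
converges on the density residual (L2, default 1e−6) and a
Harris-style total-energy change (default 1e−8) computed from
input-density potentials; the final reported energy recomputes every
term from the converged density. The initial guess is a deterministic
superposition of atom-centered Gaussians (widths ~1/Z); warm starts
from previous orbitals and density are used by all engines that
re-solve at displaced geometries.

The Hartree potential solves the free-space Poisson problem by FFT
convolution with the spherically truncated Coulomb kernel: 1/r cut at
L = the box diagonal, whose Fourier transform 4π(1−cos kL)/k² is
smooth, evaluated on a grid zero-padded so no periodic image can
reach the physical box. For densities that decay inside the box the
result is accurate to machine precision (the Gaussian closed-form test
sits at ~1e−15).

## Stress densities and surface-integral forces

The stress density is the sum of three channels (real orbitals,
Einstein summation):

* kinetic: σ_ij = −Σ_k f_k ∂_iψ_k ∂_jψ_k + ¼ ∂_i∂_jρ, or the
  algebraically identical per-orbital second-derivative form
  −½ Σ_k f_k (∂_iψ_k ∂_jψ_k − ψ_k ∂_i∂_jψ_k); both are implemented and
  agree to 1e−10 on analytic Gaussian states;
* Maxwell: σ_ij = (1/4π)(E_i E_j − ½δ_ij|E|²) with the total field
  E = E_nuclei + E_electrons, where each nucleus contributes the
  smeared field −Z_k ∇U(|r−R_k|; c_k) (a point-charge switch exists
  for sensitivity studies) and the electron part is +∇v_H (the cloud
  carries charge −ρ);
* exchange-correlation: σ_ij = δ_ij(ρ ε_xc − ρ v_xc) −
  ∂_iρ ∂(ρε_xc)/∂(∂_jρ), the gradient-channel dyadic appearing only
  for GGAs.

With these conventions div σ equals the force density on the matter,
vanishing pointwise in the ground-state electron cloud, so the force
on a nucleus is the integral of σ·n over any sphere that encloses that
nucleus alone, with **outward** normals. The sign conventions are
pinned by two executable oracles rather than by documentation: the
repulsive two-point-charge configuration must reproduce q₁q₂/d²
through the Maxwell channel (to 1e−10 relative), and the H2+ force
must match the finite-difference gradient of the total energy.

**One-electron states.** When the Hamiltonian carries no Hartree term
the local momentum balance leaves the electron's self-field Maxwell
term uncompensated; the consistent surface integrand is then
σ_kin + σ_M(E_nuc+E_e) − σ_M(E_e). Without this correction the H2+
surface force is wrong at the several-percent level; with it the
force agrees with the energy gradient to ~1e−4 hartree/bohr.

Surface integration uses Lebedev quadrature. The rules (degrees 3–17,
6–110 points, octahedral symmetry orbits) were regenerated by solving
the moment-exactness equations to ~1e−15 residual and are frozen in
`lebedev.py`; tests verify node normalization, weight sums and
spherical-harmonic orthonormality. Degree 17 (110 points) is the
default. The sphere radius defaults to half the nearest-neighbor
distance (configurable fraction, 2.0 bohr for isolated atoms, capped
so spheres never leave the interpolation-safe region).

All stress ingredients are evaluated derivative-then-interpolate:
finite-difference derivative grids are built first and then sampled at
the Lebedev nodes with a tensor-product not-a-knot cubic spline (C²,
node-exact, exact for tricubic polynomials). Quintic splines were
tried and rejected: on marginally resolved fields they amplify noise
rather than reduce error.

**Radius choice and the smeared-charge caveat.** The integration
sphere must stay clear of both the nuclear core and the neighbor
atom. Because the finite-nucleus model smears the nuclear charge over
a few c, a sphere of radius r encloses the full charge only for
x = r/c ≳ 3.5 (at x = 2 about 0.9% of Z sits outside, in a region of
strong field gradient). Radius scans on H2+ (c = 0.2, h = 0.25) show a
plateau flat to ~4e−4 hartree/bohr for r in [0.5, 1.0] bohr, with the
r = 0.4 point (x = 2) deviating by ~1.4e−3 — persistent under grid
refinement, i.e. a property of the finite-nucleus model rather than of
the quadrature. Radius fractions that keep x ≥ 3.5 are recommended.

## Hellmann–Feynman and finite-difference forces; the egg-box

Hellmann–Feynman forces use the analytic radial derivative of the
smeared attraction, F_k = Z_k ∫ρ(r) U′(|r−R_k|) (R_k−r)/|r−R_k| dr
(a grid sum; no orbital derivatives), plus point-charge repulsion.

On a fixed uniform grid the discrete Hellmann–Feynman theorem is
*exact*: the Hamiltonian depends on nuclear positions only through
V_ext sampled at the nodes, so these forces equal the gradient of the
discrete total energy to eigensolver tolerance (verified at 1e−7
against small-step finite differences). That discrete energy surface,
however, carries an egg-box modulation — a spurious component periodic
in each nuclear coordinate with period h. A central difference with a
small step measures the egg-box slope, not the physical gradient. The
finite-difference oracle therefore supports steps *commensurate with
the grid*: a 5-point central difference with steps h and 2h cancels
the h-periodic component exactly while the Richardson combination
removes the O(h²) truncation error. This commensurate form is the
package's reference gradient for force-consistency measurements; the
plain small-step form remains available.

This distinction decides which comparisons favor which method, and is
the package's main finding about the surface-integral approach on
uniform grids:

* metrics against the *physical* (egg-box-free) energy surface favor
  the stress forces: on H2+ at c = 0.2, h = 0.25 they match the
  commensurate gradient to 1.4e−4…3.9e−4 hartree/bohr while
  Hellmann–Feynman (= small-step FD) deviates by ~4e−3; the sum-rule
  error estimate σ = sqrt(Σᵢ sᵢ²/(3N_at)) (sᵢ the total-force
  components, which vanish for exact forces) is one to two orders
  smaller for stress forces on generically placed grids (2.2e−4 vs
  5.9e−2 for coarse H2+; 3.4e−3 vs 1.3e−1 for H2/SVWN5);
* metrics against the *measured discrete* energies favor
  Hellmann–Feynman by construction: the line-integral reconstruction
  of E(φ) along a configuration-space circle and the conservation of
  the Verlet total energy both compare forces with the same discrete
  surface whose exact gradient Hellmann–Feynman is. Stress forces,
  which filter the egg-box, show the egg-box amplitude as "deviation"
  in these two instruments (~2.7e−5 and RMS ~2e−4 at c = 0.5,
  h = 0.25). In basis sets whose Hellmann–Feynman forces carry
  cusp-region noise the ordering reverses; a fixed collocation grid
  has no such noise term, so these two instruments cannot show a
  stress advantage here. The acceptance suite states the orderings in
  their original direction and reports the measured values; two of
  those ordering assertions fail by design of the discretization, and
  this note is the explanation.

When the grid is auto-centered on a symmetric molecule, the lattice
shares the molecule's inversion center and all sum-rule errors cancel
identically; `make_grid(origin_shift=...)` breaks the alignment for
general-case measurements (the analogue of keeping atoms off special
basis points).

## Diagnostics, dynamics, fixtures

The line-integral instrument parametrizes a circle of radius r in the
3N-dimensional configuration space (center geometry, two seeded random
orthonormal directions), evaluates energies and forces at n_φ uniform
nodes, reconstructs E(φ) by trapezoidal integration of −F·dR/dφ
anchored at the first node, and reports the maximum deviation and the
loop-closure residual. On analytic conservative surfaces the deviation
is pure trapezoid quadrature error (O(n_φ⁻²), <1e−8 at n_φ = 64 for
the soft toy surface used: springs 0.05 hartree/bohr², circle radius
0.01 bohr) and an injected constant bias on one atom produces a
reconstruction error exactly linear in the bias.

Velocity-Verlet dynamics uses standard atomic weights × 1822.888486
(electron masses); initial velocities are Maxwell–Boltzmann (component
variance k_BT/m, k_B = 3.166811563e−6 hartree/K), seeded, with
optional center-of-mass removal. Per-step SCF solves warm-start from
the previous orbitals and density. The naive relaxer is a damped
force-following walker with an adaptive step — deliberately simple,
since the diagnostics probe force quality, not optimizer quality.

Analytic fixtures (point-charge electrostatics, Gaussian-orbital
states with closed-form first and second derivatives, harmonic and
Morse-like toy surfaces with exact gradients, optional non-conservative
bias) implement the same provider interface as grid states, so the
identical production code path runs on both; every fixture self-tests
its analytic derivatives against finite differences.

## Study conditions used by the heavier checks

Chosen once, as the conditions under which this package's claims are
made:

* H2+ reference: R = 2.0 bohr, c = 0.2, h = 0.25, box ≥ 16 bohr,
  eigensolver tolerance 1e−9;
* "deliberately coarse" ordering studies: c = 0.2, h = 0.3, grid
  origin shifted by (0.13, 0.07, 0.19)·h; H2 at R = 1.4 with SVWN5;
* dynamics and circle studies on H2+: c = 0.5, h = 0.25 (resolvable
  regime), Δt = 10.3 a.u., 20 steps, 500 K seeds; circle radius 0.05,
  n_φ = 8;
* hydrogen-atom energy check: c = 0.4, h = 0.2, box 24 bohr
  (−0.5 hartree reproduced to ~2e−4).

## What the synthetic systems do and do not show

Everything here is hydrogen-like or analytic: the test molecules (H,
H2+, H2) have no core electrons, and the toy surfaces are smooth by
construction. Passing tests demonstrate the internal consistency of
the stress-integral machinery — correct electrostatics, correct
algebraic identities, correct force/energy consistency, correct
instrument behavior — at desk scale. They do not demonstrate accuracy
for heavy elements (deep cores need far smaller c than a uniform grid
can resolve), for GGA functionals beyond the analytic toy form, for
systems larger than a few atoms, or for production molecular dynamics.
The known limitations — cusp-limited O(h²) convergence at small c,
egg-box forces on coarse grids, the smeared-charge radius constraint
x ≳ 3.5, and the exactness of discrete Hellmann–Feynman forces on
fixed grids — are quantified above.
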