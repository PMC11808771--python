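# stresskit

Nuclear forces in Kohn–Sham density functional theory, computed as
surface integrals of the quantum-mechanical stress tensor over
atom-centered spheres — together with everything needed to judge those
forces: a self-contained real-space Kohn–Sham solver, Hellmann–Feynman
and finite-difference reference forces, consistency diagnostics and
Born–Oppenheimer molecular dynamics.

**Who it is for.** People studying force evaluation in real-space /
basis-free DFT: the trade-offs between differentiating the energy,
applying the Hellmann–Feynman theorem, and integrating the momentum
flux through a surface far from the nuclear cusps, where orbitals are
smooth and discretization noise is small.

## The model

The total stress density is the sum of a kinetic, a Maxwell and an
exchange-correlation channel (Hartree atomic units, real orbitals ψ_k
with occupations f_k, total electric field **E**, density ρ):

    σ_ij  =  −Σ_k f_k ∂_iψ_k ∂_jψ_k + ¼ ∂_i∂_jρ              (kinetic)
           + (1/4π) (E_i E_j − ½ δ_ij |E|²)                    (Maxwell)
           + δ_ij (ρ ε_xc − ρ v_xc) − ∂_iρ · ∂(ρε_xc)/∂(∂_jρ)  (xc)

In the ground state div σ vanishes in the electron cloud, so the force
on nucleus i is a surface integral over any sphere S enclosing only
that nucleus, evaluated with Lebedev quadrature (nodes x_k, weights
ω_k, outward normals n):

    F_i = ∮_S σ·n dA ≈ r² Σ_k ω_k σ(x_k)·n(x_k)

The sphere radius defaults to half the distance to the nearest
neighbor. The electron–nucleus interaction uses the smoothed
finite-nucleus potential U(r) = u(r/c)/c with
u(x) = erf(x)/x + (1/(3√π))(e^(−x²) + 16 e^(−4x²)), so every field the
quadrature touches is finite and smooth. The solver itself is a
closed-shell finite-difference Kohn–Sham code (SVWN5 by default,
pluggable GGA evaluators, spectral free-space Poisson solver, LOBPCG
eigensolver); a one-electron mode gives exact single diagonalizations
for oracle systems such as H2+. The forces can be cross-examined with
the sum-of-forces error estimate σ_err = sqrt(Σᵢ sᵢ²/(3N_at)), a
line-integral consistency test along circles in configuration space,
radius scans, and energy conservation in velocity-Verlet dynamics.

See `docs/methods.md` for the numerical choices, study conditions and
known limitations (in particular: the smoothing length must be
grid-resolvable, c ≳ 2h, and integration spheres should keep
r/c ≳ 3.5).

## Worked example

Forces on the hydrogen molecular ion (bond length 2.0 bohr) from all
three engines, on a 16-bohr box at spacing 0.25:

```
$ cat h2plus.xyz
2
hydrogen molecular ion
H 0.0 0.0 -0.529177
H 0.0 0.0 0.529177

$ cat run.toml
one_electron = true
charge = 1
smoothing = 0.2
spacing = 0.25
margin = 7.0
eig_tol = 1e-9

$ stresskit forces --xyz h2plus.xyz --config run.toml --method all --out forces.json
# method=stress sigma_err=5.374e-14
H	-0.0000000000	-0.0000000000	-0.0090869539
H	+0.0000000000	-0.0000000000	+0.0090869539
# method=hf sigma_err=2.357e-15
H	+0.0000000000	+0.0000000000	-0.0054786962
H	+0.0000000000	+0.0000000000	+0.0054786962
# method=fd sigma_err=5.769e-13
H	-0.0000000000	+0.0000000000	-0.0054788450
H	-0.0000000000	+0.0000000000	+0.0054788450
```

Reading the numbers: the forces are equal and opposite along the bond
(z) axis, pointing inward — at this spacing the discretized potential
curve has its minimum slightly beyond R = 2.0. The Hellmann–Feynman
and small-step finite-difference forces agree to 1.5e−7 because on a
fixed grid Hellmann–Feynman *is* the exact gradient of the discrete
energy — including its spurious grid-periodic ("egg-box") component.
The stress force (−0.00909) differs from both by ~3.6e−3: it tracks
the egg-box-free energy surface instead, and matches a grid-
commensurate central difference (steps h and 2h, which cancels the
egg-box exactly) to ~1e−4. σ_err is at round-off here only because the
symmetric molecule sits at a symmetry point of the grid; on generic
placements the stress forces keep σ_err one to two orders below
Hellmann–Feynman. Other subcommands: `stresskit scf`, `check`
(line-integral test), `md`, `relax`, `fixtures`.

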