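# gccsd

Generalized coupled cluster (GCCSD) for conical intersections between the
ground and excited electronic states.

## The problem

Standard coupled cluster theory parametrizes the ground state as
|CC⟩ = e^T |HF⟩ and determines the cluster amplitudes t_μ from
Ω_μ = ⟨μ| e^{-T} H e^{T} |HF⟩ = 0.  Near a conical intersection between S0
and S1 this breaks down in two distinct ways: an eigenvalue ω₁ of the
Jacobian A_μν = ∂Ω_μ/∂t_ν approaches zero, so the nonlinear equations
bifurcate into multiple (or no real) solutions; and the single-valued
amplitude parametrization cannot reproduce the geometric (Berry) phase — the
sign change an adiabatic wave function must pick up on a 2π loop around the
intersection — so surfaces become multivalued, divergent, or direction
dependent.  This is why coupled cluster methods have not been usable for
ground-state intersections in nonadiabatic dynamics.

## The method

GCCSD removes the offending Jacobian eigenvector components from the cluster
amplitudes and recovers them by a subsequent diagonalization.  With
biorthonormal left/right Jacobian eigenpairs (ω_n, l_n, r_n), n = 1..k:

* constrain the amplitudes:  ⟨L_n|t⟩ = l_n·t = 0,
* solve the amplitude equations in the complementary manifold
  ⟨μ̃| = ⟨μ|(1 − Σ_n |R_n⟩⟨L_n|), i.e.  Ω̃ = Ω − Σ_n r_n (l_n·Ω) = 0,
* re-solve the Jacobian eigenpairs at the new amplitudes and iterate to joint
  convergence.

The restricted problem has no bifurcation, and the amplitudes stay
single-valued around the intersection.  The projected components are restored
by diagonalizing the similarity-transformed Hamiltonian H̄ = e^{-T} H e^{T}
either in the (k+1)-dimensional **reduced space** {|HF⟩, |R_n⟩} (a cheap,
excellent approximation) or in the **full space** {|HF⟩, |R_n⟩, |ν̃⟩} with
its non-identity metric ⟨μ̃|ν̃⟩ = δ_μν − Σ_n ⟨μ|R_n⟩⟨L_n|ν⟩, which restores
the exact (FCI) limit.  The states from these diagonalizations carry the
correct geometric phase.

The package implements, in a spin-orbital formulation:

* FCIDUMP (Molpro dialect) reader/writer, spin-orbital construction,
  noninteracting direct-sum composites (`gccsd.hamiltonian_io`),
* ground-state CCSD with DIIS (`gccsd.cc_ground`),
* the CC Jacobian, its biorthonormal left/right eigenpairs and spin
  classification of roots (`gccsd.jacobian_eom`),
* the projected GCC equations, reduced- and full-space eigenproblems
  (`gccsd.gcc_core`),
* a brute-force determinant-space oracle — full CI, dense H̄, dense
  Jacobians — against which every contracted quantity is verified
  (`gccsd.oracle_fci`),
* geometry-scan drivers: warm-started bond scans, branching-plane grids,
  circle traversals with phase tracking, branch diagnostics, and a
  size-extensivity harness (`gccsd.scans`),
* a `gccsd` command-line interface (`cc`, `gcc`, `eom`, `fci`, `scan-bond`,
  `scan-circle`, `scan-grid`, `extensivity`, `verify`).

Packaged FCIDUMP fixtures include H2 (STO-3G, 6-31G), a LiH/STO-3G bond
scan, noninteracting H2 monomers, and an H4 family hosting a genuine
S0/S1 conical intersection: a square of side 1.0 Å with rectangular (g) and
rhombic (h) distortions as the branching plane, the intersection located on
the rhombic axis, and a 16-point loop of radius 0.08 Å around it.

## Worked example

```python
import numpy as np
from gccsd import load_fixture, to_spin_orbitals, solve_gcc, fci_solve
from gccsd.gcc_core import reduced_matrix, full_space_matrix, solve_full_space
from gccsd.scans import h4_loop_provider, circle_scan, phase_report

# project the lowest singlet excitation out of the H2 ground state,
# then recover it by reduced- and full-space diagonalization
so = to_spin_orbitals(load_fixture("h2_sto3g").load())
state = solve_gcc(so, k=1, roots="singlet")
rs = reduced_matrix(state, so)
fs = solve_full_space(full_space_matrix(state, so))
fci = fci_solve(so, ms2=None)
print(f"E0 (projected CC)   = {state.e0:.10f}")
print(f"E0 reduced space    = {np.sort(rs.eigenvalues.real)[0]:.10f}")
print(f"E0 full space       = {np.sort(fs.energies.real)[0]:.10f}")
print(f"E0 FCI              = {fci.energies[0]:.10f}")
print(f"max |FS - FCI|      = {np.abs(np.sort(fs.energies.real) - fci.energies).max():.2e}")

# traverse the H4 loop around a real S0/S1 conical intersection twice
provider, radius, n = h4_loop_provider()
scan = circle_scan(provider, radius, n, turns=2, method="gcc", k=1, roots="singlet")
rep = phase_report(scan)
for name in ("amplitudes", "jacobian_eigvec", "rs_eigvec_0", "rs_eigvec_1"):
    print(f"{name:16s} {rep[name]['class']}")
```

prints

```
E0 (projected CC)   = -1.1372701747
E0 reduced space    = -1.1372701747
E0 full space       = -1.1372701747
E0 FCI              = -1.1372701747
max |FS - FCI|      = 8.88e-16
amplitudes       2pi-periodic
jacobian_eigvec  2pi-periodic
rs_eigvec_0      4pi-periodic
rs_eigvec_1      4pi-periodic
```

For two electrons, CCSD singles and doubles span the whole Hilbert space, so
the full-space eigenvalues reproduce every FCI energy to machine precision —
the exact-limit property of the framework.  On the H4 loop, the cluster
amplitudes and the Jacobian eigenvectors return to themselves after one full
turn (they carry no phase), while the reduced-space eigenvectors flip sign at
2π and return at 4π: the geometric phase lives in the final diagonalization,
exactly where it belongs.  Plain CCSD on the same loop instead develops a
region of flipped solutions with a negative excitation energy.

The same computations are available from the shell, e.g.

```
gccsd gcc --fixture h2_sto3g --k 1 --out-dir out
gccsd scan-circle --method gcc --turns 2 --out-dir loop
gccsd verify --fixture h4_center
```

## Scope and limitations

Spin-orbital CCSD only (no triples, no open-shell references); dense
eigensolves sized for desk-scale systems (up to a few thousand amplitudes,
determinant-space oracle up to 16 spin orbitals); integral generation is not
part of the package — molecular systems enter as FCIDUMP files.  See
`docs/methods.md` for the model, algorithms and numerical choices.
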