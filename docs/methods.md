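# Methods

## Model

The electronic ground state is the closed-shell CCSD ansatz
|CC⟩ = e^T|HF⟩, T = Σ_μ t_μ τ_μ, in an interleaved spin-orbital basis built
from canonical RHF molecular orbitals supplied as FCIDUMP integrals.  The
excitation index μ runs over all singles (i,a) in row-major order followed by
the unique antisymmetrized doubles (i<j, a<b) in lexicographic order; every
module shares this ordering.  Energy and residual are the standard
projections E0 = ⟨HF|H̄|HF⟩ and Ω_μ = ⟨μ|H̄|HF⟩ of the similarity-transformed
Hamiltonian H̄ = e^{-T} H e^{T}, with the residual evaluated in the
factorized one-/two-particle intermediate form of Stanton, Gauss, Watts and
Bartlett, written as the *true* residual (full Fock matrix, no denominator
bookkeeping) so that it is valid at any amplitude point, not only along a
quasi-Newton iteration.

The generalized (projected) theory constrains the amplitudes against k
designated biorthonormal Jacobian eigenpairs, l_n·t = 0, and solves
Ω̃ = (1 − Σ_n r_n l_nᵀ) Ω = 0 in the complementary manifold.  The projected
components are recovered by diagonalizing H̄ over {|HF⟩, |R_n⟩} (reduced
space) or over {|HF⟩, |R_n⟩, |ν̃⟩} with metric ⟨μ̃|ν̃⟩ = δ − Σ_n
⟨μ|R_n⟩⟨L_n|ν⟩ (full space).

## Algorithms and numerical choices

**Residual and energy.**  All contractions are `numpy.einsum` with a leading
ellipsis, so a batch axis of amplitude vectors can be pushed through the
residual in one shot.  Correctness is pinned to an independent oracle: a
determinant-space engine (bitmask Slater determinants, Slater–Condon matrix
elements, exp(±T) as terminating matrix power series) reproduces Ω_μ, E0 and
⟨μ|H̄|ν⟩ by dense matrix algebra; the contracted implementation matches it to
machine precision on H2, H4 and LiH at random amplitude points.

**Jacobian transforms.**  The CCSD residual is a quartic polynomial in the
amplitudes, so the directional derivative A(t)·v is evaluated *exactly* by a
4-point central stencil,
(8[Ω(t+hv) − Ω(t−hv)] − [Ω(t+2hv) − Ω(t−2hv)])/12h, whose truncation error
vanishes identically for polynomials of degree ≤ 4.  The scale h = 0.25
merely balances floating-point rounding (any O(1) value is exact in exact
arithmetic).  This gives an analytic, matrix-free right transform without
hand-transcribed sigma equations — every term is inherited from the residual,
so the transform can never drift out of sync with it.  Left transforms and
eigensolves use a dense Jacobian assembled column-wise from the same stencil
(batched, cached on the current amplitudes).  Dense non-Hermitian
`scipy.linalg.eig` replaces an iterative Davidson solver throughout: every
system in scope has at most a few thousand amplitudes, where the dense solve
is faster, free of subspace-collapse failure modes near degeneracies, and
returns the complete spectrum needed for root classification.  A hard cap
(5000 amplitudes) makes the intended scale explicit.

**Eigenpair processing.**  Left/right eigenvectors are matched by eigenvalue,
grouped into degeneracy clusters (tolerance 1e-9), and biorthonormalized
blockwise by solving the left-right overlap system; a singular overlap block
is reported as a defective (non-diagonalizable) pair rather than silently
regularized.  Right vectors are 2-normalized; at standalone solves the sign
gauge fixes the largest-magnitude component positive, while during scans the
overlap-alignment rule below takes precedence.  Complex pairs are kept as
adjacent conjugate pairs with flags, never realified.

**Root selection and spin classification.**  A spin-orbital Jacobian carries
triplet and spin-flip roots that spin-adapted implementations never see, and
exactly degenerate multiplets mix arbitrarily in the eigensolver, so naive
overlap homing can drift when the tracked root crosses them.  Each root is
therefore classified by (i) the fraction of its weight on spin-conserving
excitations and (ii) its parity under α↔β relabeling: singlet-type roots have
both ≈ +1.  The selection mode `roots="singlet"` re-applies this
gauge-independent criterion at every eigenpair refresh (and is the right
choice for same-spin intersections with a closed-shell ground state);
index-based selections fall back to overlap homing.  The extensivity harness
additionally requires the projected root to be localized on the designated
fragment (≥ 90% of its weight on that block).

**GCC solver.**  Macro/micro scheme: micro-iterations relax the restricted
amplitudes with frozen eigenpairs (quasi-Newton steps Ω̃/Δε with
orbital-energy denominators, DIIS of subspace size 8 with restart on
ill-conditioned overlap, purging after every update); each macro-iteration
re-solves the *full* Jacobian A(t) at the current amplitudes, re-selects and
re-biorthonormalizes the k projected pairs, and sign-aligns them with the
previous macro-iterate.  Joint convergence requires the projected residual
norm, every |l_n·t| and the eigenpair residuals below the tolerance (default
1e-10 on 2-norms).  k = 0 short-circuits to the plain CCSD solver.

**Reduced and full space.**  The full-space matrix is assembled from the
exact H̄ block over {|HF⟩, |μ⟩}: [[E0, η],[Ω, E0·1 + A + Γ]], where
η_ν = ∂E0/∂t_ν and Γ is the doubles-by-singles block generated by products
of two single excitations acting on the reference with the singles residual
as one factor.  Γ vanishes at a plain CCSD solution but not under GCC, and
is required for the exact-limit property; the assembled block is verified
against the determinant-space H̄.  The reduced matrix is the exact leading
(k+1)×(k+1) block of the full-space matrix in the {⟨HF|,⟨L_n|}/{|HF⟩,|R_n⟩}
biorthogonal basis; its diagonal equals e0 + ω_n exactly whenever l_n·Ω = 0
and acquires a small Γ-induced correction otherwise.  The generalized
full-space problem has exactly k structural zero modes of the metric that
are simultaneously null for the Hamiltonian matrix (the redundant directions
of the over-complete basis); because both matrices factor through the same
rectangular basis map with an injective left factor, the problem is deflated
exactly — finite eigenpairs are those of the underlying H̄ block, mapped
back through the basis pseudoinverse — instead of trusting QZ to resolve
0/0 eigenvalues.

**Scans and phase tracking.**  All drivers warm-start each point from the
previous converged amplitudes and projection; eigenvector and reduced-space
eigenvector signs are aligned by maximal signed overlap with the previous
point and never re-fixed per point, so an accumulated sign flip after a
closed 2π loop is observable.  Closure errors compare the wrap point (same
geometry as the start) directly.  Branch diagnostics label points
non-converged, complex-pair, flipped (negative S0/S1 gap), or
phase-mismatch; the mismatch detector flags adjacent ground-state energy
jumps that exceed both an absolute threshold (default 0.02 Hartree) and
three times the neighboring jumps, plus any energy difference across the
wrap pair.  The absolute threshold should be raised for coarsely sampled
paths.

## Study conditions (packaged fixtures)

Fixtures are pre-generated FCIDUMP files (Molpro dialect, chemist-order
integrals, 1-based indices on disk); `scripts/dev/generate_fixtures.py`
regenerates them with the in-repo McMurchie–Davidson s/p Gaussian integral
engine and a tightly converged RHF (orbital-gradient DIIS, max |FDS−SDF| <
1e-11).  The engine reproduces literature RHF energies for H2/STO-3G
(−1.116684) and LiH/STO-3G (−7.862027) at their standard geometries.

* **H2**: 0.7414 Å in STO-3G and 6-31G — the two-electron exact-limit
  systems.
* **H2 monomers A/B/C**: 0.80/0.74/0.70 Å (STO-3G), similar but distinct
  geometries for the size-extensivity harness; noninteraction is realized
  exactly by direct-sum composites (all cross-fragment integrals are
  identically zero, equivalent to infinite separation).
* **LiH/STO-3G**: bond lengths 1.0–4.0 Å in 0.5 Å steps for warm-started
  scans.
* **H4 family**: a square of side 1.0 Å hosts a singlet–singlet conical
  intersection in the plane of rectangular (u) and rhombic (v) distortions.
  FCI exploration located the crossing at (u, v) = (0, 0.18925 Å): the
  shipped center geometry has an FCI S0/S1 gap of 3.6e-5 Hartree, the gap
  grows linearly in both directions (slopes ≈ 0.96/Å along v, ≈ 2.4/Å along
  u), and the FCI ground state acquires a Berry sign of −1 around the loop —
  a genuine conical intersection.  The 16-point loop has radius 0.08 Å: at
  tighter radii (e.g. 0.05 Å) the traversal enters a small defective arc
  where the Jacobian's singlet pair becomes a complex conjugate pair, the
  expected small defect of a non-Hermitian theory near an intersection;
  0.08 Å routes outside it while still encircling the crossing.  A square
  and a strongly distorted reference point (v + 0.30 Å) are also shipped.

What these fixtures emulate: quasi-degenerate electronic structure, an exact
same-spin conical intersection, exact noninteracting fragmentation.  What
they do not: realistic basis-set sizes, dynamic-correlation regimes where
the coupled-cluster hierarchy is accurate (minimal-basis H4 near a CI is
*strongly* correlated), vibronic/geometric effects beyond a 2D branching
plane, or systems large enough that iterative eigensolvers matter.  Passing
tests therefore demonstrate the mathematical contracts of the framework, not
chemical accuracy on application-scale molecules.

## Known limitations and observed regime effects

* The reduced-space eigenvalues agree with the full-space ones to machine
  precision whenever the residual coupling l_n·Ω vanishes (by spatial
  symmetry on H2 and at the symmetric H4 points), but differ by up to
  ~1e-4 Hartree at the strongly coupled fixtures (‖Ω‖ ~ 1e-2–3e-2 at
  generic H4 loop points, ~1e-2 for LiH).  The difference is carried by the
  coupling of the projected block to the complement manifold (the Γ(Ω) and
  η̃ blocks) and shrinks quadratically with ‖Ω‖; weakly correlated
  application-scale systems sit in the regime where the reduced space is an
  excellent approximation, desk-scale minimal-basis models near a conical
  intersection do not.
* Projection requires real eigenpairs; inside a defective region (complex
  projected pair) the solver raises and scan drivers flag the point instead
  of continuing silently.  No similarity-constrained defect removal is
  implemented.
* No spin adaptation: triplet and spin-flip roots are present and must be
  handled by the root-selection rules above; there is no Ŝ² operator, the
  spin classification is by Δm_s weight and relabeling parity only.
* The determinant-space oracle is capped at 16 spin orbitals / 20000
  determinants; dense Jacobians at 400 amplitudes (oracle) and 5000
  (implementation).
* Frozen-core is an orbital mask applied at spin-orbital construction
  (default off); orbital symmetry labels are parsed but ignored.
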