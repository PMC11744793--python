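"""Generalized coupled cluster: projected amplitude equations, reduced- and
full-space eigenproblems.

Near a ground/excited-state conical intersection the CC Jacobian acquires a
near-zero eigenvalue and the amplitude equations bifurcate.  GCC removes the
offending eigenvector components from the cluster amplitudes,

    <L_n|t> = 0,   n = 1..k,

and solves the amplitude equations only in the complementary projection
manifold <mu~| = <mu|(1 - sum_n |R_n><L_n|), so the restricted problem is
convex.  The removed components are recovered afterwards by diagonalizing the
similarity-transformed Hamiltonian either in the (k+1)-dimensional reduced
space {HF, R_1..R_k} or in the full space {HF, R_n, nu~} with its
non-identity metric — the latter restores the exact (FCI) limit.

The coupled equations are solved by a macro/micro scheme: micro-iterations
relax the restricted amplitudes with frozen eigenpairs (DIIS, purging after
every update); each macro-iteration then refreshes the k lowest Jacobian
eigenpairs at the current amplitudes, re-biorthonormalizes, and re-aligns
them with the previous macro-iterate by maximal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .cc_ground import (
    AmplitudeVector,
    DIIS,
    cc_energy,
    cc_residual,
    energy_gradient,
    orbital_denominators,
    residual_flat_batch,
    solve_cc,
    _pair_indices,
)
from .hamiltonian_io import SpinOrbitalIntegrals
from .jacobian_eom import EigenpairSet, dense_jacobian_matrix, solve_eigenpairs

__all__ = [
    "ProjectionSet",
    "GCCState",
    "ReducedMatrix",
    "FullSpaceProblem",
    "FullSpaceSolution",
    "GCCError",
    "projected_residual",
    "purge_components",
    "solve_gcc",
    "reduced_matrix",
    "full_space_matrix",
    "solve_full_space",
    "match_full_space_states",
    "hbar_matrix",
]


class GCCError(RuntimeError):
    """Raised when the coupled GCC equations cannot be solved as posed."""


# ---------------------------------------------------------------------------
# projection set
# ---------------------------------------------------------------------------

@dataclass
class ProjectionSet:
    """The k projected Jacobian eigenpairs (omega_n, r_n, l_n), biorthonormal.

    k = 0 is a valid empty projection, in which case GCC reduces to plain
    CCSD.  Rows of ``rights``/``lefts`` are flat amplitude-space vectors.
    """

    omegas: np.ndarray
    rights: np.ndarray
    lefts: np.ndarray

    @classmethod
    def empty(cls, dim: int) -> "ProjectionSet":
        return cls(np.zeros(0), np.zeros((0, dim)), np.zeros((0, dim)))

    @classmethod
    def from_eigenpairs(cls, pairs: EigenpairSet, indices) -> "ProjectionSet":
        idx = list(indices)
        if any(pairs.complex_flags[i] for i in idx):
            raise GCCError(
                "a projected eigenpair is complex; the projection manifold "
                "must be spanned by real eigenvectors"
            )
        return cls(
            pairs.omegas[idx].real.copy(),
            pairs.rights[idx].real.copy(),
            pairs.lefts[idx].real.copy(),
        )

    @property
    def k(self) -> int:
        return len(self.omegas)

    def biorthonormality_error(self) -> float:
        if self.k == 0:
            return 0.0
        return float(np.abs(self.lefts @ self.rights.T - np.eye(self.k)).max())

    def purge_flat(self, flat: np.ndarray) -> np.ndarray:
        """Apply 1 - sum_n r_n l_n^T."""
        if self.k == 0:
            return flat.copy()
        return flat - self.rights.T @ (self.lefts @ flat)


# ---------------------------------------------------------------------------
# projected residual and amplitude constraint
# ---------------------------------------------------------------------------

def purge_components(t: AmplitudeVector, projection: ProjectionSet) -> AmplitudeVector:
    """Remove the projected eigenvector components: t' = t - sum_n r_n (l_n.t)."""
    return AmplitudeVector.from_flat(projection.purge_flat(t.flat), t.nocc, t.nvir)


def projected_residual(
    t: AmplitudeVector, projection: ProjectionSet, so: SpinOrbitalIntegrals
) -> AmplitudeVector:
    """Residual in the modified manifold: Om~_mu = <mu~|Hbar|HF>.

    Equals Om_mu - sum_n r_mu,n (l_n . Om); by construction l_n . Om~ = 0 for
    every n and any t.
    """
    om = cc_residual(t, so)
    return AmplitudeVector.from_flat(projection.purge_flat(om.flat), t.nocc, t.nvir)


# ---------------------------------------------------------------------------
# GCC state and solver
# ---------------------------------------------------------------------------

@dataclass
class GCCState:
    """Converged (or diagnostic) solution of the coupled GCC equations."""

    amplitudes: AmplitudeVector
    projection: ProjectionSet
    e0: float
    omega_full: AmplitudeVector
    projected_residual_norm: float
    constraint_norms: np.ndarray
    eigenpair_residual: float
    macro_iterations: int
    converged: bool

    @property
    def k(self) -> int:
        return self.projection.k


def _select_roots(
    pairs: EigenpairSet,
    k: int,
    roots,
    previous: ProjectionSet | None,
) -> list[int]:
    """Which eigenpairs to project: overlap homing, explicit roots, or lowest k.

    ``roots`` may be a list of eigenpair indices, the string ``"singlet"``
    (k lowest spin-pure singlet roots — the states that can actually form a
    same-spin intersection with the closed-shell ground state), or None for
    the k lowest by real part.  The singlet criterion is re-applied at every
    refresh: it is gauge-independent, whereas overlap homing can drift when
    the tracked root passes exactly degenerate spin-flip multiplets whose
    eigenvectors mix arbitrarily.  For index-based selections, overlap homing
    takes over once a projection exists.
    """
    if isinstance(roots, str):
        if roots == "singlet":
            from .jacobian_eom import select_singlet_roots

            return select_singlet_roots(pairs, k)
        raise ValueError(f"unknown root selection {roots!r}")
    if callable(roots):
        # gauge-independent selection rules are re-applied at every refresh
        return list(roots(pairs))
    if previous is not None and previous.k == k and k > 0:
        # root homing: follow the previously projected states by right-vector
        # overlap, guarding against eigenvalue-order swaps across iterations
        chosen: list[int] = []
        for n in range(k):
            ov = np.abs(pairs.rights.real @ previous.rights[n])
            for i in chosen:
                ov[i] = -1.0
            chosen.append(int(np.argmax(ov)))
        return chosen
    if roots is not None:
        return list(roots)
    return list(range(k))


def _align_signs(projection: ProjectionSet, previous: ProjectionSet | None) -> ProjectionSet:
    """Flip (r_n, l_n) jointly so r_n overlaps positively with the previous r_n."""
    if previous is None or previous.k != projection.k:
        return projection
    for n in range(projection.k):
        if projection.rights[n] @ previous.rights[n] < 0.0:
            projection.rights[n] = -projection.rights[n]
            projection.lefts[n] = -projection.lefts[n]
    return projection


def solve_gcc(
    so: SpinOrbitalIntegrals,
    k: int = 1,
    tol: float = 1e-10,
    max_macro: int = 50,
    max_micro: int = 100,
    guess: AmplitudeVector | None = None,
    initial_projection: ProjectionSet | None = None,
    roots=None,
    diis_size: int = 8,
) -> GCCState:
    """Solve the coupled GCC equations for k projected states.

    Macro-iteration: (i) micro-solve Om~ = 0 with frozen (l_n, r_n), purging
    after every update; (ii) re-solve the k lowest eigenpairs of the *full*
    Jacobian A(t); (iii) re-biorthonormalize and align with the previous
    macro-iterate by maximal overlap.  Joint convergence requires the
    projected residual norm, every |<L_n|t>|, and the eigenpair residuals all
    below ``tol``.  k = 0 reduces to plain CCSD.
    """
    no, nv = so.nocc, so.nvir
    dim = AmplitudeVector.dimension(no, nv)
    if not 0 <= k < dim:
        raise ValueError(f"k={k} outside 0..{dim - 1}")

    if k == 0:
        res = solve_cc(so, guess=guess, tol=tol, max_iter=max_macro * max_micro)
        om = cc_residual(res.amplitudes, so)
        return GCCState(
            amplitudes=res.amplitudes,
            projection=ProjectionSet.empty(dim),
            e0=res.e0,
            omega_full=om,
            projected_residual_norm=res.residual_norm,
            constraint_norms=np.zeros(0),
            eigenpair_residual=0.0,
            macro_iterations=res.iterations,
            converged=res.converged,
        )

    flat = (guess.flat if guess is not None else np.zeros(dim))
    D = orbital_denominators(so)
    projection = initial_projection
    pair_resid = np.inf

    macro = 0
    for macro in range(1, max_macro + 1):
        # (ii/iii) eigenpairs of the full Jacobian at the current amplitudes
        t_cur = AmplitudeVector.from_flat(flat, no, nv)
        pairs = solve_eigenpairs(t_cur, so, k=None, fix_sign=projection is None)
        idx = _select_roots(pairs, k, roots, projection)
        new_proj = ProjectionSet.from_eigenpairs(pairs, idx)
        projection = _align_signs(new_proj, projection)
        pair_resid = float(pairs.residual_norms[idx].max())

        # joint convergence check with the refreshed pairs
        flat = projection.purge_flat(flat)
        om = residual_flat_batch(flat, so)
        om_proj = projection.purge_flat(om)
        cons = np.abs(projection.lefts @ flat) if projection.k else np.zeros(0)
        if (
            np.linalg.norm(om_proj) <= tol
            and (cons <= tol).all()
            and pair_resid <= tol
        ):
            t_fin = AmplitudeVector.from_flat(flat, no, nv)
            return GCCState(
                amplitudes=t_fin,
                projection=projection,
                e0=cc_energy(t_fin, so),
                omega_full=AmplitudeVector.from_flat(om, no, nv),
                projected_residual_norm=float(np.linalg.norm(om_proj)),
                constraint_norms=cons,
                eigenpair_residual=pair_resid,
                macro_iterations=macro - 1,
                converged=True,
            )

        # (i) micro-iterations with frozen eigenpairs
        diis = DIIS(diis_size)
        for _ in range(max_micro):
            om = residual_flat_batch(flat, so)
            om_proj = projection.purge_flat(om)
            if np.linalg.norm(om_proj) <= 0.1 * tol:
                break
            step = projection.purge_flat(om_proj / D)
            flat = projection.purge_flat(diis.extrapolate(flat + step, step))

    t_fin = AmplitudeVector.from_flat(flat, no, nv)
    om = residual_flat_batch(flat, so)
    om_proj = projection.purge_flat(om)
    cons = np.abs(projection.lefts @ flat)
    return GCCState(
        amplitudes=t_fin,
        projection=projection,
        e0=cc_energy(t_fin, so),
        omega_full=AmplitudeVector.from_flat(om, no, nv),
        projected_residual_norm=float(np.linalg.norm(om_proj)),
        constraint_norms=cons,
        eigenpair_residual=pair_resid,
        macro_iterations=macro,
        converged=False,
    )


# ---------------------------------------------------------------------------
# reduced-space matrix
# ---------------------------------------------------------------------------

@dataclass
class ReducedMatrix:
    """(k+1)x(k+1) representation of Hbar in the {HF, R_1..R_k} basis.

    Entries are the exact biorthogonal matrix elements:
    entries[0,0] = e0, entries[0,n] = <HF|Hbar|R_n> (the eta-type coupling),
    entries[n,0] = <L_n|Hbar|HF> = l_n.Om, and entries[m,n] =
    delta_mn (e0 + omega_n) + <L_m|tau-product(Om)|R_n>.  The last term is the
    residual-induced correction that vanishes at a plain CCSD solution (and in
    any noninteracting-fragment limit where l_n.Om = 0); without it the
    diagonal is exactly e0 + omega_n by the Jacobian eigenpair identity.
    """

    entries: np.ndarray
    eigenvalues: np.ndarray
    eigvecs: np.ndarray
    complex_flags: np.ndarray

    @property
    def dim(self) -> int:
        return self.entries.shape[0]


def reduced_matrix(
    state: GCCState, so: SpinOrbitalIntegrals, require_converged: bool = True
) -> ReducedMatrix:
    if require_converged and not state.converged:
        raise GCCError("reduced matrix requested for an unconverged GCC state")
    k = state.k
    t = state.amplitudes
    no, nv = t.nocc, t.nvir
    ns = no * nv
    eta = energy_gradient(t, so)
    om = state.omega_full.flat
    H = np.zeros((k + 1, k + 1))
    H[0, 0] = state.e0
    if k:
        gamma_block = _pair_product_block(state.omega_full.t1, no, nv)
    for n in range(k):
        r_n = state.projection.rights[n]
        H[0, n + 1] = eta @ r_n
        H[n + 1, 0] = state.projection.lefts[n] @ om
        gamma_r = gamma_block @ r_n[:ns]  # doubles-space vector
        for m in range(k):
            l_m = state.projection.lefts[m]
            H[m + 1, n + 1] = (
                (state.e0 + state.projection.omegas[n]) * (1.0 if m == n else 0.0)
                + l_m[ns:] @ gamma_r
            )
    w, v = scipy.linalg.eig(H)
    order = np.lexsort((np.abs(w.imag), w.real))
    w, v = w[order], v[:, order]
    flags = np.abs(w.imag) > 1e-10
    if not flags.any():
        w, v = w.real, v.real
    return ReducedMatrix(H, w, v, flags)


# ---------------------------------------------------------------------------
# full-space problem
# ---------------------------------------------------------------------------

def _pair_product_block(w1: np.ndarray, no: int, nv: int) -> np.ndarray:
    """Doubles-by-singles block of <mu|tau_nu |w1-state>: the coefficient of
    the product of two single excitations (u at nu, w1 given) on the unique
    double (i<j, a<b) is u_ia w_jb + u_jb w_ia - u_ib w_ja - u_ja w_ib.
    """
    Io = np.eye(no)
    Iv = np.eye(nv)
    G = (
        np.einsum("ik,ac,jb->ijabkc", Io, Iv, w1)
        + np.einsum("jk,bc,ia->ijabkc", Io, Iv, w1)
        - np.einsum("ik,bc,ja->ijabkc", Io, Iv, w1)
        - np.einsum("jk,ac,ib->ijabkc", Io, Iv, w1)
    )
    oi, oj = _pair_indices(no)
    ai, bj = _pair_indices(nv)
    blk = G[oi, oj][:, ai, bj]  # (npair_o, npair_v, no, nv)
    return blk.reshape(len(oi) * len(ai), no * nv)


def hbar_matrix(t: AmplitudeVector, so: SpinOrbitalIntegrals) -> np.ndarray:
    """Dense Hbar over {|HF>, |mu>}: [[E0, eta], [Om, E0 + A + Gamma]].

    The Gamma block (doubles rows, singles columns, built from the singles
    residual) accounts for <mu|tau_nu Hbar|HF> beyond the reference term; it
    vanishes at a plain CCSD solution but not under GCC, and is required for
    the exact-limit property of the full-space problem.
    """
    no, nv = t.nocc, t.nvir
    dim = AmplitudeVector.dimension(no, nv)
    e0 = cc_energy(t, so)
    om = cc_residual(t, so)
    eta = energy_gradient(t, so)
    A = dense_jacobian_matrix(t, so)
    M = np.empty((dim + 1, dim + 1))
    M[0, 0] = e0
    M[0, 1:] = eta
    M[1:, 0] = om.flat
    M[1:, 1:] = A + e0 * np.eye(dim)
    ns = no * nv
    M[1 + ns:, 1:1 + ns] += _pair_product_block(om.t1, no, nv)
    return M


@dataclass
class FullSpaceProblem:
    """Generalized eigenproblem (H^FS, S^FS) over {HF, R_n, mu~} bases.

    The metric is the identity except in the projected-manifold block,
    <mu~|nu~> = delta_munu - sum_n <mu|R_n><L_n|nu>, which carries k exact
    zero modes (the directions removed from the manifold).
    """

    h_fs: np.ndarray
    s_fs: np.ndarray
    k: int
    # factorization H^FS = BL @ M @ BR, S^FS = BL @ BR used for exact deflation
    hbar: np.ndarray | None = None
    basis_right: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.h_fs.shape[0]


def full_space_matrix(
    state: GCCState, so: SpinOrbitalIntegrals, require_converged: bool = True
) -> FullSpaceProblem:
    if require_converged and not state.converged:
        raise GCCError("full-space matrix requested for an unconverged GCC state")
    t = state.amplitudes
    no, nv = t.nocc, t.nvir
    dim = AmplitudeVector.dimension(no, nv)
    k = state.k
    M = hbar_matrix(t, so)
    R = state.projection.rights
    L = state.projection.lefts
    Q = np.eye(dim) - (R.T @ L if k else 0.0)
    BL = np.zeros((1 + k + dim, 1 + dim))
    BL[0, 0] = 1.0
    if k:
        BL[1:1 + k, 1:] = L
    BL[1 + k:, 1:] = Q
    BR = np.zeros((1 + dim, 1 + k + dim))
    BR[0, 0] = 1.0
    if k:
        BR[1:, 1:1 + k] = R.T
    BR[1:, 1 + k:] = Q
    return FullSpaceProblem(
        h_fs=BL @ M @ BR, s_fs=BL @ BR, k=k, hbar=M, basis_right=BR
    )


@dataclass
class FullSpaceSolution:
    energies: np.ndarray
    complex_flags: np.ndarray
    vectors: np.ndarray
    n_spurious: int


def solve_full_space(problem: FullSpaceProblem, nroots: int | None = None) -> FullSpaceSolution:
    """Solve H^FS x = E S^FS x; roots sorted by real part, conjugate pairs
    flagged and both members returned.

    The redundant basis gives the metric exactly k structural zero modes that
    are simultaneously null for H^FS; metric degeneracy beyond those is an
    error.  Both matrices factor through the rectangular basis map BR (with an
    injective left factor), so x is a finite-eigenvalue solution iff
    y = BR x is an eigenvector of the underlying Hbar matrix — the problem is
    deflated exactly that way, mapping vectors back by least squares.
    """
    sv = np.linalg.svd(problem.s_fs, compute_uv=False)
    n_spurious = int((sv < 1e-10 * max(sv.max(), 1.0)).sum())
    if n_spurious != problem.k:
        raise GCCError(
            f"metric is singular beyond its {problem.k} structural zero modes "
            f"({n_spurious} null directions found)"
        )
    if problem.hbar is None or problem.basis_right is None:
        raise GCCError("full-space problem lacks its basis factorization")
    w, y = scipy.linalg.eig(problem.hbar)
    vr = np.linalg.lstsq(problem.basis_right, y, rcond=None)[0]
    order = np.lexsort((np.abs(w.imag), w.real))
    w, vr = w[order], vr[:, order]
    if nroots is not None:
        w, vr = w[:nroots], vr[:, :nroots]
    flags = np.abs(w.imag) > 1e-10
    if not flags.any():
        w, vr = w.real, vr.real
    return FullSpaceSolution(w, flags, vr, n_spurious)


def match_full_space_states(solution: FullSpaceSolution, k: int) -> list[int]:
    """Indices of the full-space roots corresponding to the reduced basis.

    Root m is matched to basis coordinate m (HF, then R_1..R_k) by maximal
    relative eigenvector weight on that coordinate, greedily and without
    repetition — the full-space spectrum also contains every root of the
    projected manifold (e.g. triplets below the projected singlet), so plain
    energy ordering does not identify the reduced-space partners.
    """
    V = np.abs(solution.vectors) ** 2
    tot = V.sum(axis=0)
    tot[tot == 0] = 1.0
    chosen: list[int] = []
    for m in range(k + 1):
        w = V[m, :] / tot
        for i in chosen:
            w[i] = -1.0
        chosen.append(int(np.argmax(w)))
    return chosen
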