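"""Brute-force determinant-space engine: FCI, dense Hbar, dense Jacobians.

Everything here works with explicit Slater determinants stored as orbital
bitmasks, so each contracted-tensor quantity in the CC modules has an
independent dense twin: the Hamiltonian via Slater–Condon rules, exp(T) as a
terminating matrix power series, the similarity transform as dense matrix
algebra, and the Jacobian by finite differences of the determinant-space
residual.  Intended for systems with at most ~16 spin orbitals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cc_ground import AmplitudeVector
from .hamiltonian_io import SpinOrbitalIntegrals

__all__ = [
    "DeterminantSpace",
    "FCIResult",
    "enumerate_space",
    "build_dense_hamiltonian",
    "fci_solve",
    "cc_wavefunction_expand",
    "dense_jacobian",
    "residual_determinant_route",
    "hbar_matrix_mu_basis",
]

_MAX_SPINORB = 16
_MAX_DETS = 20_000


# ---------------------------------------------------------------------------
# determinant bookkeeping
# ---------------------------------------------------------------------------

def _popcount_below(det: int, p: int) -> int:
    return bin(det & ((1 << p) - 1)).count("1")


def _annihilate(det: int, p: int):
    if not det & (1 << p):
        return None, 0
    return det ^ (1 << p), (-1) ** _popcount_below(det, p)


def _create(det: int, p: int):
    if det & (1 << p):
        return None, 0
    return det | (1 << p), (-1) ** _popcount_below(det, p)


def _ms2_of(det: int) -> int:
    ms = 0
    p = 0
    d = det
    while d:
        if d & 1:
            ms += 1 if p % 2 == 0 else -1
        d >>= 1
        p += 1
    return ms


def _orbs(det: int):
    out = []
    p = 0
    while det:
        if det & 1:
            out.append(p)
        det >>= 1
        p += 1
    return out


@dataclass
class DeterminantSpace:
    """An ordered list of determinants with a bidirectional index.

    The reference determinant sits at position 0; the rest are ordered by
    excitation rank relative to the reference, then lexicographically by
    occupied-orbital tuple.
    """

    determinants: list[int]
    reference: int
    n_spinorb: int
    index: dict[int, int]

    def __len__(self) -> int:
        return len(self.determinants)


def enumerate_space(
    so: SpinOrbitalIntegrals,
    max_excitation: int | None = None,
    ms2: int | None = 0,
) -> DeterminantSpace:
    """All determinants at the reference electron count, optionally capped.

    ``ms2=None`` keeps every spin projection (needed when comparing with the
    spin-orbital excitation manifold, which contains spin-flip operators).
    """
    nso = so.n_spinorb
    if nso > _MAX_SPINORB:
        raise ValueError(f"{nso} spin orbitals exceed the oracle cap of {_MAX_SPINORB}")
    nelec = so.nocc
    ref = (1 << nelec) - 1
    from itertools import combinations

    dets = []
    for occ in combinations(range(nso), nelec):
        d = 0
        for p in occ:
            d |= 1 << p
        if ms2 is not None and _ms2_of(d) != ms2:
            continue
        rank = bin(d & ~ref).count("1")
        if max_excitation is not None and rank > max_excitation:
            continue
        dets.append((rank, tuple(_orbs(d)), d))
    dets.sort()
    ordered = [d for _, _, d in dets]
    if ref in ordered and ordered[0] != ref:
        raise AssertionError("reference determinant not first")
    if len(ordered) > _MAX_DETS:
        raise ValueError(f"{len(ordered)} determinants exceed the oracle cap of {_MAX_DETS}")
    return DeterminantSpace(ordered, ref, nso, {d: i for i, d in enumerate(ordered)})


# ---------------------------------------------------------------------------
# Slater-Condon Hamiltonian
# ---------------------------------------------------------------------------

def _sc_element(d1: int, d2: int, h: np.ndarray, g: np.ndarray, e_nuc: float) -> float:
    """<d1|H|d2> with antisymmetrized physicist-order g."""
    diff = d1 ^ d2
    ndiff = bin(diff).count("1")
    if ndiff == 0:
        occ = _orbs(d1)
        val = sum(h[p, p] for p in occ) + e_nuc
        for a in range(len(occ)):
            for b in range(a):
                val += g[occ[a], occ[b], occ[a], occ[b]]
        return val
    if ndiff == 2:
        m = _orbs(d1 & diff)[0]
        p = _orbs(d2 & diff)[0]
        sign = (-1) ** _popcount_below(d1, m) * (-1) ** _popcount_below(d2, p)
        common = _orbs(d1 & d2)
        val = h[m, p] + sum(g[m, k, p, k] for k in common)
        return sign * val
    if ndiff == 4:
        m, n = _orbs(d1 & diff)
        p, q = _orbs(d2 & diff)
        s1, _ = _annihilate(d1, m)
        sgn = (-1) ** _popcount_below(d1, m) * (-1) ** _popcount_below(s1, n)
        s2, _ = _annihilate(d2, p)
        sgn *= (-1) ** _popcount_below(d2, p) * (-1) ** _popcount_below(s2, q)
        return sgn * g[m, n, p, q]
    return 0.0


def build_dense_hamiltonian(space: DeterminantSpace, so: SpinOrbitalIntegrals) -> np.ndarray:
    n = len(space)
    H = np.zeros((n, n))
    for i, di in enumerate(space.determinants):
        for j in range(i + 1):
            H[i, j] = H[j, i] = _sc_element(di, space.determinants[j], so.h_so, so.g_anti, so.e_nuc)
    return H


@dataclass
class FCIResult:
    energies: np.ndarray
    vectors: np.ndarray
    space: DeterminantSpace


def fci_solve(so: SpinOrbitalIntegrals, nroots: int | None = None, ms2: int | None = 0) -> FCIResult:
    """Dense full CI: eigenvalues/vectors of H in the determinant space."""
    space = enumerate_space(so, max_excitation=None, ms2=ms2)
    H = build_dense_hamiltonian(space, so)
    w, v = np.linalg.eigh(H)
    if nroots is not None:
        w, v = w[:nroots], v[:, :nroots]
    return FCIResult(w, v, space)


# ---------------------------------------------------------------------------
# excitation operators and exp(T)
# ---------------------------------------------------------------------------

def mu_excitations(nocc: int, nvir: int):
    """The canonical mu list with absolute spin-orbital labels."""
    from .cc_ground import mu_orbital_labels

    return mu_orbital_labels(nocc, nvir)


def _apply_ops(det: int, ops):
    """Apply (kind, orbital) operator string right-to-left; kind in {'a','c'}."""
    sign = 1
    for kind, p in reversed(ops):
        det, s = (_annihilate if kind == "a" else _create)(det, p)
        if det is None:
            return None, 0
        sign *= s
    return det, sign


def mu_determinants(space: DeterminantSpace, nocc: int, nvir: int):
    """Map each mu to (determinant index, sign) for |mu> = tau_mu |HF>."""
    singles, doubles = mu_excitations(nocc, nvir)
    out = []
    for i, a in singles:
        d, s = _apply_ops(space.reference, [("c", a), ("a", i)])
        out.append((space.index[d], s))
    for i, j, a, b in doubles:
        d, s = _apply_ops(space.reference, [("c", a), ("c", b), ("a", j), ("a", i)])
        out.append((space.index[d], s))
    return out


def excitation_matrix(mu_idx: int, space: DeterminantSpace, nocc: int, nvir: int) -> np.ndarray:
    """Dense matrix of tau_mu acting within the determinant space."""
    singles, doubles = mu_excitations(nocc, nvir)
    if mu_idx < len(singles):
        i, a = singles[mu_idx]
        ops = [("c", a), ("a", i)]
    else:
        i, j, a, b = doubles[mu_idx - len(singles)]
        ops = [("c", a), ("c", b), ("a", j), ("a", i)]
    n = len(space)
    M = np.zeros((n, n))
    for col, det in enumerate(space.determinants):
        d, s = _apply_ops(det, ops)
        if d is not None and d in space.index:
            M[space.index[d], col] = s
    return M


def cluster_matrix(t: AmplitudeVector, space: DeterminantSpace) -> np.ndarray:
    """Dense matrix of T = sum_mu t_mu tau_mu in the determinant space."""
    flat = t.flat
    n = len(space)
    T = np.zeros((n, n))
    for mu, coef in enumerate(flat):
        if coef == 0.0:
            continue
        T += coef * excitation_matrix(mu, space, t.nocc, t.nvir)
    return T


def cc_wavefunction_expand(t: AmplitudeVector, space: DeterminantSpace) -> np.ndarray:
    """Coefficient vector of exp(T)|HF> over the determinant space."""
    T = cluster_matrix(t, space)
    vec = np.zeros(len(space))
    vec[0] = 1.0
    out = vec.copy()
    term = vec.copy()
    k = 1
    while True:
        term = T @ term / k
        if not np.any(term):
            break
        out += term
        k += 1
        if k > len(space):
            raise RuntimeError("exp(T) series did not terminate (truncated space?)")
    return out


def hbar_dense(t: AmplitudeVector, space: DeterminantSpace, so: SpinOrbitalIntegrals) -> np.ndarray:
    """Dense exp(-T) H exp(T) over the determinant space."""
    H = build_dense_hamiltonian(space, so)
    T = cluster_matrix(t, space)
    # exp(±T) via terminating series (T raises excitation rank: nilpotent)
    def expm(M):
        out = np.eye(M.shape[0])
        term = np.eye(M.shape[0])
        k = 1
        while True:
            term = term @ M / k
            if not np.any(np.abs(term) > 0.0):
                break
            out += term
            k += 1
            if k > M.shape[0] + 1:
                raise RuntimeError("matrix exponential series did not terminate")
        return out
    return expm(-T) @ H @ expm(T)


def residual_determinant_route(t: AmplitudeVector, so: SpinOrbitalIntegrals) -> np.ndarray:
    """Omega_mu = <mu|Hbar|HF> computed densely; flat over the mu ordering."""
    space = enumerate_space(so, ms2=None)
    hbar = hbar_dense(t, space, so)
    maps = mu_determinants(space, t.nocc, t.nvir)
    return np.array([s * hbar[idx, 0] for idx, s in maps])


def hbar_matrix_mu_basis(t: AmplitudeVector, so: SpinOrbitalIntegrals) -> np.ndarray:
    """Dense Hbar over the basis {|HF>, |mu>}: the independent full-space twin."""
    space = enumerate_space(so, ms2=None)
    hbar = hbar_dense(t, space, so)
    maps = [(0, 1)] + mu_determinants(space, t.nocc, t.nvir)
    n = len(maps)
    M = np.empty((n, n))
    for r, (ri, rs) in enumerate(maps):
        for c, (ci, cs) in enumerate(maps):
            M[r, c] = rs * cs * hbar[ri, ci]
    return M


# ---------------------------------------------------------------------------
# dense Jacobian (dual route)
# ---------------------------------------------------------------------------

def dense_jacobian(
    t: AmplitudeVector,
    so: SpinOrbitalIntegrals,
    step: float = 1e-5,
    check_tol: float = 1e-6,
) -> np.ndarray:
    """Dense CC Jacobian A(t) built by two independent routes.

    Columns come from the analytic transform of the jacobian module applied to
    unit vectors AND from central finite differences of the contracted
    residual; disagreement above ``check_tol`` (after one Richardson
    refinement) is an error.  Returns the analytic-route matrix.
    """
    from .jacobian_eom import dense_jacobian_matrix
    from .cc_ground import residual_flat_batch

    no, nv = t.nocc, t.nvir
    dim = AmplitudeVector.dimension(no, nv)
    if dim > 400:
        raise ValueError(f"{dim} amplitudes exceed the dense-oracle cap of 400")
    A = dense_jacobian_matrix(t, so)

    flat = t.flat
    eye = np.eye(dim)
    def fd(h):
        plus = residual_flat_batch(flat[None, :] + h * eye, so)
        minus = residual_flat_batch(flat[None, :] - h * eye, so)
        return ((plus - minus) / (2 * h)).T

    A_fd = fd(step)
    if np.abs(A - A_fd).max() > check_tol:
        # Richardson refinement: eliminate the O(h^2) error term
        A_fd2 = fd(step / 2.0)
        A_fd = (4.0 * A_fd2 - A_fd) / 3.0
        if np.abs(A - A_fd).max() > check_tol:
            raise RuntimeError(
                f"Jacobian routes disagree by {np.abs(A - A_fd).max():.3e}"
            )
    return A
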