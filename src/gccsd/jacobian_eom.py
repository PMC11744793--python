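"""The CC Jacobian A(t), its eigenpairs and the eigenbasis decomposition.

A_mu_nu = <mu|[Hbar, tau_nu]|HF> is the derivative of the amplitude residual
with respect to the amplitudes; its eigenvalues are the EOM excitation
energies, and its left/right eigenvectors l_n, r_n are biorthonormal,
l_m . r_n = delta_mn.

The transform A(t)·v is evaluated as an exact directional derivative of the
contracted residual: Omega(t + eps v) is a quartic polynomial in eps for
CCSD, so a 4-point central stencil differentiates it *exactly* (up to
roundoff) — no truncation error, no hand-transcribed sigma equations.  Left
transforms and eigensolves go through a dense Jacobian assembled column-wise
from that action; every target system here has at most a few thousand
amplitudes, where dense non-Hermitian eigensolves are both cheaper and more
robust than iterative subspace methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .cc_ground import AmplitudeVector, residual_flat_batch
from .hamiltonian_io import SpinOrbitalIntegrals

__all__ = [
    "EigenpairSet",
    "EigenbasisComponents",
    "jacobian_apply_right",
    "jacobian_apply_left",
    "dense_jacobian_matrix",
    "solve_eigenpairs",
    "biorthonormalize",
    "amplitude_components",
    "flip_spin_flat",
    "delta_ms_vector",
    "classify_root",
    "select_singlet_roots",
]

# differentiation scale for the exact stencil; any O(1) value works since the
# stencil has zero truncation error on a quartic — this balances roundoff
_STENCIL_H = 0.25
_DENSE_CAP = 5000


# ---------------------------------------------------------------------------
# matrix-free transforms (exact polynomial differentiation)
# ---------------------------------------------------------------------------

def _apply_right_flat(t_flat: np.ndarray, v_flat: np.ndarray, so: SpinOrbitalIntegrals, h: float = _STENCIL_H) -> np.ndarray:
    """Exact directional derivative dOmega(t + eps v)/deps at eps=0.

    (8[Omega(t+h v) - Omega(t-h v)] - [Omega(t+2h v) - Omega(t-2h v)]) / 12h
    annihilates every term of the quartic except the linear one.
    """
    vs = np.stack([t_flat + h * v_flat, t_flat - h * v_flat,
                   t_flat + 2 * h * v_flat, t_flat - 2 * h * v_flat])
    om = residual_flat_batch(vs, so)
    return (8.0 * (om[0] - om[1]) - (om[2] - om[3])) / (12.0 * h)


def jacobian_apply_right(t: AmplitudeVector, v: AmplitudeVector, so: SpinOrbitalIntegrals) -> AmplitudeVector:
    """A(t) · v, matrix-free."""
    if t.t1.shape != v.t1.shape:
        raise ValueError("t and v are dimensioned differently")
    out = _apply_right_flat(t.flat, v.flat, so)
    return AmplitudeVector.from_flat(out, t.nocc, t.nvir)


def dense_jacobian_matrix(t: AmplitudeVector, so: SpinOrbitalIntegrals, chunk: int = 64) -> np.ndarray:
    """Dense A(t) assembled from the exact transform, column block at a time."""
    no, nv = t.nocc, t.nvir
    dim = AmplitudeVector.dimension(no, nv)
    if dim > _DENSE_CAP:
        raise ValueError(f"{dim} amplitudes exceed the dense-assembly cap {_DENSE_CAP}")
    flat = t.flat
    h = _STENCIL_H
    A = np.empty((dim, dim))
    eye = np.eye(dim)
    for start in range(0, dim, chunk):
        V = eye[start:start + chunk]
        pts = np.concatenate([flat + h * V, flat - h * V, flat + 2 * h * V, flat - 2 * h * V])
        om = residual_flat_batch(pts, so)
        b = V.shape[0]
        cols = (8.0 * (om[:b] - om[b:2 * b]) - (om[2 * b:3 * b] - om[3 * b:])) / (12.0 * h)
        A[:, start:start + chunk] = cols.T
    return A


class _JacobianCache:
    """Memoize the dense Jacobian on the current (t, so) pair."""

    def __init__(self):
        self.key = None
        self.value = None

    def get(self, t: AmplitudeVector, so: SpinOrbitalIntegrals) -> np.ndarray:
        key = (id(so), t.flat.tobytes())
        if key != self.key:
            self.value = dense_jacobian_matrix(t, so)
            self.key = key
        return self.value


_cache = _JacobianCache()


def jacobian_apply_left(t: AmplitudeVector, v: AmplitudeVector, so: SpinOrbitalIntegrals) -> AmplitudeVector:
    """A(t)^T · v (the left transform), via the cached dense Jacobian."""
    if t.t1.shape != v.t1.shape:
        raise ValueError("t and v are dimensioned differently")
    A = _cache.get(t, so)
    return AmplitudeVector.from_flat(A.T @ v.flat, t.nocc, t.nvir)


# ---------------------------------------------------------------------------
# eigenpairs
# ---------------------------------------------------------------------------

@dataclass
class EigenpairSet:
    """Biorthonormal left/right Jacobian eigenpairs, ascending by Re(omega).

    Complex conjugate pairs are kept adjacent and flagged; their vectors are
    stored as complex arrays (never silently realified).
    """

    omegas: np.ndarray
    rights: np.ndarray  # (k, dim) rows
    lefts: np.ndarray   # (k, dim) rows
    residual_norms: np.ndarray
    complex_flags: np.ndarray
    nocc: int = 0
    nvir: int = 0

    @property
    def k(self) -> int:
        return len(self.omegas)

    def right_vector(self, n: int) -> AmplitudeVector:
        return AmplitudeVector.from_flat(self.rights[n].real, self.nocc, self.nvir)

    def left_vector(self, n: int) -> AmplitudeVector:
        return AmplitudeVector.from_flat(self.lefts[n].real, self.nocc, self.nvir)

    def biorthonormality_error(self) -> float:
        k = self.k
        if k == 0:
            return 0.0
        ov = self.lefts @ self.rights.T
        return float(np.abs(ov - np.eye(k)).max())


def solve_eigenpairs(
    t: AmplitudeVector,
    so: SpinOrbitalIntegrals,
    k: int | None = None,
    side: str = "both",
    fix_sign: bool = True,
) -> EigenpairSet:
    """The k lowest (by real part) eigenpairs of the Jacobian A(t).

    Solved densely; pairs are matched left/right by eigenvalue, then
    biorthonormalized.  Real eigenpairs carry real vectors; complex pairs are
    reported as adjacent conjugate pairs with a flag.
    """
    dim = AmplitudeVector.dimension(t.nocc, t.nvir)
    if k is None:
        k = dim
    if not 1 <= k <= dim:
        raise ValueError(f"k={k} outside 1..{dim}")
    A = _cache.get(t, so)
    w, vl, vr = scipy.linalg.eig(A, left=True, right=True)
    # scipy returns vl with vl^H A = w vl^H, so rows of vl.conj().T are lefts
    order = np.lexsort((np.abs(w.imag), w.real))
    w = w[order]
    vr = vr[:, order]
    vl = vl[:, order].conj()
    w, rights, lefts = _pair_and_biorthonormalize(w, vr.T, vl.T, fix_sign=fix_sign)
    sel = slice(0, k)
    omegas = w[sel]
    R = rights[sel]
    L = lefts[sel]
    resid = np.array([
        np.linalg.norm(A @ R[n] - omegas[n] * R[n]) + np.linalg.norm(L[n] @ A - omegas[n] * L[n])
        for n in range(len(omegas))
    ]).real
    flags = np.abs(omegas.imag) > 1e-10
    if not flags.any():
        omegas, R, L = omegas.real, R.real, L.real
    return EigenpairSet(omegas, R, L, resid, flags, nocc=t.nocc, nvir=t.nvir)


def _pair_and_biorthonormalize(w, rights, lefts, fix_sign=True, degeneracy_tol=1e-9):
    """Match left/right rows by eigenvalue, biorthonormalize blockwise."""
    n = len(w)
    # left eigenvalues from the same matrix coincide with the right ones;
    # scipy already returns them in matching order after the common sort
    used = np.zeros(n, dtype=bool)
    perm = np.empty(n, dtype=int)
    for i in range(n):
        cand = np.where(~used)[0]
        j = cand[np.argmin(np.abs(w[cand] - w[i]))]
        perm[i] = j
        used[j] = True
    lefts = lefts[perm]
    # group degenerate clusters and invert the overlap blockwise
    groups = []
    start = 0
    for i in range(1, n + 1):
        if i == n or abs(w[i] - w[start]) > degeneracy_tol:
            groups.append((start, i))
            start = i
    R = rights.copy()
    L = lefts.copy()
    for a, b in groups:
        blk = L[a:b] @ R[a:b].T
        if abs(np.linalg.det(blk)) < 1e-12:
            raise np.linalg.LinAlgError(
                f"defective (non-diagonalizable) eigenvalue cluster at omega={w[a]:.6g}: "
                "left/right overlap is singular"
            )
        # normalize rights to unit 2-norm, optionally fix sign, then solve for lefts
        for idx in range(a, b):
            nrm = np.linalg.norm(R[idx])
            R[idx] = R[idx] / nrm
            if fix_sign:
                big = np.argmax(np.abs(R[idx]))
                phase = R[idx][big]
                if np.abs(phase) > 0:
                    R[idx] = R[idx] * (np.abs(phase) / phase)
        blk = L[a:b] @ R[a:b].T
        L[a:b] = np.linalg.solve(blk, L[a:b])
    return w, R, L


def biorthonormalize(lefts: np.ndarray, rights: np.ndarray, fix_sign: bool = True):
    """Biorthonormalize row-stacked left/right vectors: l_m . r_n = delta_mn.

    Right vectors come out 2-normalized with their largest-magnitude component
    positive (unless ``fix_sign`` is off, as during phase-tracked scans); the
    left vectors absorb the scaling.  A near-singular overlap signals a defect.
    """
    L = np.array(lefts, dtype=float, copy=True)
    R = np.array(rights, dtype=float, copy=True)
    if L.shape != R.shape:
        raise ValueError("left/right counts differ")
    for idx in range(len(R)):
        R[idx] /= np.linalg.norm(R[idx])
        if fix_sign:
            big = np.argmax(np.abs(R[idx]))
            if R[idx][big] < 0:
                R[idx] = -R[idx]
    ov = L @ R.T
    if abs(np.linalg.det(ov)) < 1e-12:
        raise np.linalg.LinAlgError("near-singular left/right overlap: defective pair")
    L = np.linalg.solve(ov, L)
    return L, R


# ---------------------------------------------------------------------------
# spin classification of amplitude-space vectors
# ---------------------------------------------------------------------------

def flip_spin_flat(flat: np.ndarray, no: int, nv: int) -> np.ndarray:
    """Image of a flat amplitude vector under the alpha<->beta relabeling.

    With interleaved spin orbitals the spin partner of index p is p XOR 1;
    the full antisymmetric t2 storage absorbs any reordering signs.
    """
    from .cc_ground import pack, unpack

    t1, t2 = unpack(flat, no, nv)
    po = np.arange(no) ^ 1
    pv = np.arange(nv) ^ 1
    t1f = t1[..., po, :][..., :, pv]
    t2f = t2[..., po, :, :, :][..., :, po, :, :][..., :, :, pv, :][..., :, :, :, pv]
    return pack(t1f, t2f)


def delta_ms_vector(no: int, nv: int) -> np.ndarray:
    """Spin-projection change (in units of ms2) of each mu excitation."""
    ms = lambda p: 1 if p % 2 == 0 else -1
    out = []
    for i in range(no):
        for a in range(nv):
            out.append(ms(a) - ms(i))
    oi, oj = np.triu_indices(no, k=1)
    ai, bj = np.triu_indices(nv, k=1)
    for i, j in zip(oi, oj):
        for a, b in zip(ai, bj):
            out.append(ms(a) + ms(b) - ms(i) - ms(j))
    return np.array(out)


def classify_root(r_flat: np.ndarray, no: int, nv: int):
    """(ms0_weight, spin_parity) of an amplitude-space vector.

    ``ms0_weight`` is the fraction of the vector living on spin-conserving
    (delta_ms = 0) excitations; ``spin_parity`` is its overlap with its own
    alpha<->beta relabeling.  A singlet-type root has both close to +1; an
    ms = 0 triplet has weight 1 but parity -1, and vectors from degenerate
    spin-flip multiplets carry weight away from the delta_ms = 0 block.
    """
    r = np.asarray(r_flat).real
    w = r * r
    tot = w.sum()
    if tot == 0:
        return 0.0, 0.0
    dms_all = delta_ms_vector(no, nv)
    ms0_weight = float(w[dms_all == 0].sum() / tot)
    parity = float(r @ flip_spin_flat(r, no, nv) / tot)
    return ms0_weight, parity


def select_singlet_roots(pairs: "EigenpairSet", k: int, threshold: float = 0.9) -> list[int]:
    """Indices of the k lowest spin-pure singlet-type real eigenpairs.

    These are the roots that can form a same-spin intersection with the
    closed-shell ground state; triplet and spin-flip roots are spectators.
    """
    chosen = []
    for n in range(pairs.k):
        if pairs.complex_flags[n]:
            continue
        ms0_weight, parity = classify_root(pairs.rights[n].real, pairs.nocc, pairs.nvir)
        if ms0_weight >= threshold and parity >= threshold:
            chosen.append(n)
        if len(chosen) == k:
            return chosen
    raise ValueError(f"only {len(chosen)} singlet-type roots found, need {k}")


@dataclass
class EigenbasisComponents:
    """Expansion of amplitudes in the Jacobian eigenbasis: c_n = <L_n|t>."""

    coefficients: dict = field(default_factory=dict)
    remainder: np.ndarray | None = None

    @property
    def remainder_norm(self) -> float:
        return float(np.linalg.norm(self.remainder))


def amplitude_components(t: AmplitudeVector, pairs: EigenpairSet) -> EigenbasisComponents:
    """Coefficients <L_n|t> and the residual outside the eigenpair span."""
    flat = t.flat
    coeffs = {}
    rem = flat.astype(complex) if np.iscomplexobj(pairs.lefts) else flat.copy()
    for n in range(pairs.k):
        c = pairs.lefts[n] @ flat
        coeffs[n] = c
        rem = rem - pairs.rights[n] * c
    return EigenbasisComponents(coeffs, rem)
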