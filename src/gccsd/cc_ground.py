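"""Ground-state CCSD in the spin-orbital basis.

The cluster operator T = T1 + T2 is parametrized by an
:class:`AmplitudeVector`; the energy and residual follow the standard
similarity-transformed projections

    E0   = <HF| exp(-T) H exp(T) |HF>,
    Om_mu = <mu| exp(-T) H exp(T) |HF>,

with mu running over all singles and unique (i<j, a<b) doubles.  The residual
uses the factorized one/two-particle intermediates of Stanton, Gauss, Watts
and Bartlett, written so that it is the *true* residual (full Fock matrix, no
denominator bookkeeping).  The solver is quasi-Newton with orbital-energy
denominators, accelerated by DIIS on the flattened amplitudes.

All contractions carry a numpy ellipsis so that a leading batch axis can be
pushed through the residual — the Jacobian module exploits this to evaluate
many directional derivatives at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hamiltonian_io import SpinOrbitalIntegrals

__all__ = ["AmplitudeVector", "CCResult", "cc_energy", "cc_residual", "solve_cc"]


# ---------------------------------------------------------------------------
# amplitude vectors and the canonical mu ordering
# ---------------------------------------------------------------------------

def _pair_indices(n: int):
    return np.triu_indices(n, k=1)


def mu_orbital_labels(no: int, nv: int):
    """Absolute spin-orbital labels of every mu excitation, in flat order.

    Singles come as (i, no+a) row-major; unique doubles as (i, j, no+a, no+b)
    with i<j, a<b lexicographic — the ordering every module shares.
    """
    singles = [(i, no + a) for i in range(no) for a in range(nv)]
    oi, oj = _pair_indices(no)
    ai, bj = _pair_indices(nv)
    doubles = [
        (int(i), int(j), no + int(a), no + int(b))
        for i, j in zip(oi, oj)
        for a, b in zip(ai, bj)
    ]
    return singles, doubles


@dataclass
class AmplitudeVector:
    """Cluster amplitudes (t1, t2) with a fixed flat ordering.

    ``t2`` is stored in its full antisymmetrized form (nocc, nocc, nvir, nvir);
    the flat linearization holds all singles in row-major (i, a) order followed
    by the unique doubles in lexicographic (i<j, a<b) order.  The same mu
    ordering is shared by every module (residuals, Jacobian eigenvectors,
    projectors).
    """

    t1: np.ndarray
    t2: np.ndarray

    @property
    def nocc(self) -> int:
        return self.t1.shape[0]

    @property
    def nvir(self) -> int:
        return self.t1.shape[1]

    @classmethod
    def zeros(cls, nocc: int, nvir: int) -> "AmplitudeVector":
        return cls(np.zeros((nocc, nvir)), np.zeros((nocc, nocc, nvir, nvir)))

    @classmethod
    def dimension(cls, nocc: int, nvir: int) -> int:
        return nocc * nvir + (nocc * (nocc - 1) // 2) * (nvir * (nvir - 1) // 2)

    @property
    def flat(self) -> np.ndarray:
        return pack(self.t1, self.t2)

    @classmethod
    def from_flat(cls, flat: np.ndarray, nocc: int, nvir: int) -> "AmplitudeVector":
        t1, t2 = unpack(np.asarray(flat, dtype=float), nocc, nvir)
        return cls(t1, t2)

    def copy(self) -> "AmplitudeVector":
        return AmplitudeVector(self.t1.copy(), self.t2.copy())

    def antisymmetry_error(self) -> float:
        t2 = self.t2
        return float(
            max(np.abs(t2 + t2.transpose(1, 0, 2, 3)).max(initial=0.0),
                np.abs(t2 + t2.transpose(0, 1, 3, 2)).max(initial=0.0))
        )


def pack(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """(t1, t2) -> flat vector over the canonical mu ordering (batch-safe)."""
    no, nv = t1.shape[-2], t1.shape[-1]
    oi, oj = _pair_indices(no)
    ai, bj = _pair_indices(nv)
    d = t2[..., oi, oj, :, :][..., :, ai, bj]
    lead = t1.shape[:-2]
    return np.concatenate(
        [t1.reshape(lead + (no * nv,)), d.reshape(lead + (len(oi) * len(ai),))], axis=-1
    )


def unpack(flat: np.ndarray, no: int, nv: int):
    """Inverse of :func:`pack`; rebuilds the full antisymmetric t2 (batch-safe)."""
    flat = np.asarray(flat)
    lead = flat.shape[:-1]
    ns = no * nv
    t1 = flat[..., :ns].reshape(lead + (no, nv))
    oi, oj = _pair_indices(no)
    ai, bj = _pair_indices(nv)
    du = flat[..., ns:].reshape(lead + (len(oi), len(ai)))
    tmp = np.zeros(lead + (len(oi), nv, nv), dtype=flat.dtype)
    tmp[..., ai, bj] = du
    tmp[..., bj, ai] = -du
    t2 = np.zeros(lead + (no, no, nv, nv), dtype=flat.dtype)
    t2[..., oi, oj, :, :] = tmp
    t2[..., oj, oi, :, :] = -tmp
    return t1, t2


@dataclass
class CCResult:
    amplitudes: AmplitudeVector
    e0: float
    residual_norm: float
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# energy and residual
# ---------------------------------------------------------------------------

def _slices(so: SpinOrbitalIntegrals):
    o, v = so.occ, so.vir
    f = so.fock
    g = so.g_anti
    ix = np.ix_
    return {
        "foo": f[ix(o, o)], "fov": f[ix(o, v)], "fvv": f[ix(v, v)],
        "oooo": g[ix(o, o, o, o)], "ooov": g[ix(o, o, o, v)],
        "oovv": g[ix(o, o, v, v)], "ovov": g[ix(o, v, o, v)],
        "ovvo": g[ix(o, v, v, o)], "ovoo": g[ix(o, v, o, o)],
        "ovvv": g[ix(o, v, v, v)], "vvvo": g[ix(v, v, v, o)],
        "vvvv": g[ix(v, v, v, v)],
    }


def cc_energy(t: AmplitudeVector, so: SpinOrbitalIntegrals) -> float:
    """CCSD energy <HF|exp(-T) H exp(T)|HF> including nuclear repulsion."""
    if t.t1.shape != (so.nocc, so.nvir):
        raise ValueError("amplitude dimensions do not match the integral set")
    s = _slices(so)
    e = so.reference_energy()
    e += np.einsum("ia,ia->", s["fov"], t.t1)
    e += 0.25 * np.einsum("ijab,ijab->", s["oovv"], t.t2)
    e += 0.5 * np.einsum("ijab,ia,jb->", s["oovv"], t.t1, t.t1)
    return float(e)


def energy_gradient(t: AmplitudeVector, so: SpinOrbitalIntegrals) -> np.ndarray:
    """eta_nu = <HF| Hbar |nu> = dE0/dt_nu, flat over the mu ordering."""
    s = _slices(so)
    g1 = s["fov"] + np.einsum("ijab,jb->ia", s["oovv"], t.t1)
    # unique-doubles derivative: the quarter sum over the antisymmetric tensor
    # contributes <ij||ab> once per unique (i<j, a<b) index
    g2 = s["oovv"]
    return pack(g1, g2)


def _residual_arrays(t1, t2, s):
    """SGWB residual; t1/t2 may carry leading batch axes."""
    e = np.einsum
    foo, fov, fvv = s["foo"], s["fov"], s["fvv"]
    tau = t2 + e("...ia,...jb->...ijab", t1, t1) - e("...ib,...ja->...ijab", t1, t1)
    taut = t2 + 0.5 * (e("...ia,...jb->...ijab", t1, t1) - e("...ib,...ja->...ijab", t1, t1))

    Fae = (
        fvv
        - 0.5 * e("me,...ma->...ae", fov, t1)
        + e("...mf,mafe->...ae", t1, s["ovvv"])
        - 0.5 * e("...mnaf,mnef->...ae", taut, s["oovv"])
    )
    Fmi = (
        foo
        + 0.5 * e("...ie,me->...mi", t1, fov)
        + e("...ne,mnie->...mi", t1, s["ooov"])
        + 0.5 * e("...inef,mnef->...mi", taut, s["oovv"])
    )
    Fme = fov + e("...nf,mnef->...me", t1, s["oovv"])

    Wmnij = (
        s["oooo"]
        + e("...je,mnie->...mnij", t1, s["ooov"])
        - e("...ie,mnje->...mnij", t1, s["ooov"])
        + 0.25 * e("...ijef,mnef->...mnij", tau, s["oovv"])
    )
    vovv = _vovv(s)
    Wabef = (
        s["vvvv"]
        - e("...mb,amef->...abef", t1, vovv)
        + e("...ma,bmef->...abef", t1, vovv)
        + 0.25 * e("...mnab,mnef->...abef", tau, s["oovv"])
    )
    Wmbej = (
        s["ovvo"]
        + e("...jf,mbef->...mbej", t1, s["ovvv"])
        - e("...nb,mnej->...mbej", t1, _oovo(s))
        - e("...jnfb,mnef->...mbej", 0.5 * t2 + e("...jf,...nb->...jnfb", t1, t1), s["oovv"])
    )

    r1 = (
        fov
        + e("...ie,...ae->...ia", t1, Fae)
        - e("...ma,...mi->...ia", t1, Fmi)
        + e("...imae,...me->...ia", t2, Fme)
        - e("...nf,naif->...ia", t1, s["ovov"])
        - 0.5 * e("...imef,maef->...ia", t2, s["ovvv"])
        - 0.5 * e("...mnae,nmei->...ia", t2, _oovo(s))
    )

    # P(ab) t2_ijae (Fbe - 1/2 t1_mb Fme) and the P(ij) counterpart
    Xbe = Fae - 0.5 * e("...mb,...me->...be", t1, Fme)
    Xmj = Fmi + 0.5 * e("...je,...me->...mj", t1, Fme)

    r2 = s["oovv"] + 0.0 * t2
    tmp = e("...ijae,...be->...ijab", t2, Xbe)
    r2 = r2 + tmp - tmp.swapaxes(-2, -1)
    tmp = e("...imab,...mj->...ijab", t2, Xmj)
    r2 = r2 - (tmp - tmp.swapaxes(-4, -3))
    r2 = r2 + 0.5 * e("...mnab,...mnij->...ijab", tau, Wmnij)
    r2 = r2 + 0.5 * e("...ijef,...abef->...ijab", tau, Wabef)
    tmp = e("...imae,...mbej->...ijab", t2, Wmbej) - e(
        "...ie,...ma,mbej->...ijab", t1, t1, s["ovvo"]
    )
    r2 = r2 + (
        tmp
        - tmp.swapaxes(-4, -3)
        - tmp.swapaxes(-2, -1)
        + tmp.swapaxes(-4, -3).swapaxes(-2, -1)
    )
    tmp = e("...ie,abej->...ijab", t1, s["vvvo"])
    r2 = r2 + tmp - tmp.swapaxes(-4, -3)
    tmp = e("...ma,mbij->...ijab", t1, s["ovoo"])
    r2 = r2 - (tmp - tmp.swapaxes(-2, -1))
    return r1, r2


def _vovv(s):
    # <am||ef> = -<ma||ef> with a transposed to the front
    return -s["ovvv"].swapaxes(0, 1)


def _oovo(s):
    # <nm||ei> = -<nm||ie> transposed on the last two axes
    return -s["ooov"].swapaxes(2, 3)


def cc_residual(t: AmplitudeVector, so: SpinOrbitalIntegrals) -> AmplitudeVector:
    """Residual Omega_mu = <mu|exp(-T) H exp(T)|HF> as an AmplitudeVector."""
    if t.t1.shape != (so.nocc, so.nvir):
        raise ValueError("amplitude dimensions do not match the integral set")
    r1, r2 = _residual_arrays(t.t1, t.t2, _slices(so))
    return AmplitudeVector(r1, r2)


def residual_flat_batch(flat: np.ndarray, so: SpinOrbitalIntegrals) -> np.ndarray:
    """Residual of a batch of flat amplitude vectors (leading axes arbitrary)."""
    t1, t2 = unpack(flat, so.nocc, so.nvir)
    r1, r2 = _residual_arrays(t1, t2, _slices(so))
    return pack(r1, r2)


# ---------------------------------------------------------------------------
# DIIS-accelerated quasi-Newton solver
# ---------------------------------------------------------------------------

class DIIS:
    """Direct inversion in the iterative subspace over flat vectors."""

    def __init__(self, max_vec: int = 8):
        self.max_vec = max_vec
        self.ts: list[np.ndarray] = []
        self.errs: list[np.ndarray] = []

    def extrapolate(self, t: np.ndarray, err: np.ndarray) -> np.ndarray:
        self.ts.append(t.copy())
        self.errs.append(err.copy())
        if len(self.ts) > self.max_vec:
            self.ts.pop(0)
            self.errs.pop(0)
        n = len(self.ts)
        if n < 2:
            return t
        B = np.empty((n + 1, n + 1))
        B[-1, :] = -1.0
        B[:, -1] = -1.0
        B[-1, -1] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = self.errs[i] @ self.errs[j]
        rhs = np.zeros(n + 1)
        rhs[-1] = -1.0
        # restart on ill-conditioned overlap
        if np.linalg.cond(B[:-1, :-1]) > 1e14:
            self.ts = [self.ts[-1]]
            self.errs = [self.errs[-1]]
            return t
        try:
            c = np.linalg.solve(B, rhs)[:-1]
        except np.linalg.LinAlgError:
            self.ts = [self.ts[-1]]
            self.errs = [self.errs[-1]]
            return t
        return sum(ci * ti for ci, ti in zip(c, self.ts))


def orbital_denominators(so: SpinOrbitalIntegrals) -> np.ndarray:
    """Flat vector of eps_i - eps_a (singles) and eps_i+eps_j-eps_a-eps_b (doubles)."""
    eps = so.orbital_energies()
    eo, ev = eps[so.occ], eps[so.vir]
    d1 = eo[:, None] - ev[None, :]
    d2 = (
        eo[:, None, None, None] + eo[None, :, None, None]
        - ev[None, None, :, None] - ev[None, None, None, :]
    )
    return pack(d1, d2)


def solve_cc(
    so: SpinOrbitalIntegrals,
    guess: AmplitudeVector | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
    diis_size: int = 8,
) -> CCResult:
    """Solve the CCSD amplitude equations Omega(t) = 0.

    Quasi-Newton updates t <- t + Omega/D with orbital-energy denominators D,
    DIIS-accelerated; converged when the flat residual 2-norm is <= tol.  On
    non-convergence the last iterate is returned flagged, for diagnosis near
    bifurcation points.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    no, nv = so.nocc, so.nvir
    t = (guess.copy() if guess is not None else AmplitudeVector.zeros(no, nv))
    D = orbital_denominators(so)
    diis = DIIS(diis_size)
    flat = t.flat
    norm = np.inf
    for it in range(1, max_iter + 1):
        om = residual_flat_batch(flat, so)
        norm = float(np.linalg.norm(om))
        if norm <= tol:
            amps = AmplitudeVector.from_flat(flat, no, nv)
            return CCResult(amps, cc_energy(amps, so), norm, it - 1, True)
        step = om / D
        flat = diis.extrapolate(flat + step, step)
    amps = AmplitudeVector.from_flat(flat, no, nv)
    return CCResult(amps, cc_energy(amps, so), norm, max_iter, False)
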