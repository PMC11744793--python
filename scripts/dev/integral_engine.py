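"""Minimal Gaussian-integral engine + RHF for fixture (re)generation.

Dev tool only — the installed package never imports this.  Supports s and p
contracted Cartesian Gaussians (enough for H and Li in STO-3G/6-31G) via the
McMurchie–Davidson scheme, runs closed-shell RHF, and transforms to the MO
basis for FCIDUMP export.  Energies are Hartree, input geometries Å.
"""

from __future__ import annotations

import numpy as np
from scipy.special import hyp1f1
from scipy.linalg import eigh

ANG2BOHR = 1.0 / 0.529177210903

# --- basis set data (exponents, contraction coefficients) -------------------

BASES = {
    "sto-3g": {
        "H": [("s", [3.42525091, 0.62391373, 0.16885540],
               [0.15432897, 0.53532814, 0.44463454])],
        "Li": [
            ("s", [16.1195750, 2.9362007, 0.7946505],
             [0.15432897, 0.53532814, 0.44463454]),
            ("s", [0.6362897, 0.1478601, 0.0480887],
             [-0.09996723, 0.39951283, 0.70011547]),
            ("p", [0.6362897, 0.1478601, 0.0480887],
             [0.15591627, 0.60768372, 0.39195739]),
        ],
    },
    "6-31g": {
        "H": [
            ("s", [18.7311370, 2.8253937, 0.6401217],
             [0.03349460, 0.23472695, 0.81375733]),
            ("s", [0.1612778], [1.0]),
        ],
    },
}

CHARGES = {"H": 1, "Li": 3}


def boys(n, T):
    return hyp1f1(n + 0.5, n + 1.5, -T) / (2.0 * n + 1.0)


def E(i, j, t, Qx, a, b):
    """Hermite expansion coefficient."""
    p = a + b
    q = a * b / p
    if t < 0 or t > (i + j):
        return 0.0
    if i == j == t == 0:
        return np.exp(-q * Qx * Qx)
    if j == 0:
        return (
            (1.0 / (2 * p)) * E(i - 1, j, t - 1, Qx, a, b)
            - (q * Qx / a) * E(i - 1, j, t, Qx, a, b)
            + (t + 1) * E(i - 1, j, t + 1, Qx, a, b)
        )
    return (
        (1.0 / (2 * p)) * E(i, j - 1, t - 1, Qx, a, b)
        + (q * Qx / b) * E(i, j - 1, t, Qx, a, b)
        + (t + 1) * E(i, j - 1, t + 1, Qx, a, b)
    )


def overlap_prim(a, lmn1, A, b, lmn2, B):
    l1, m1, n1 = lmn1
    l2, m2, n2 = lmn2
    s1 = E(l1, l2, 0, A[0] - B[0], a, b)
    s2 = E(m1, m2, 0, A[1] - B[1], a, b)
    s3 = E(n1, n2, 0, A[2] - B[2], a, b)
    return s1 * s2 * s3 * (np.pi / (a + b)) ** 1.5


def kinetic_prim(a, lmn1, A, b, lmn2, B):
    l2, m2, n2 = lmn2
    term0 = b * (2 * (l2 + m2 + n2) + 3) * overlap_prim(a, lmn1, A, b, lmn2, B)
    term1 = -2 * b ** 2 * (
        overlap_prim(a, lmn1, A, b, (l2 + 2, m2, n2), B)
        + overlap_prim(a, lmn1, A, b, (l2, m2 + 2, n2), B)
        + overlap_prim(a, lmn1, A, b, (l2, m2, n2 + 2), B)
    )
    term2 = -0.5 * (
        l2 * (l2 - 1) * overlap_prim(a, lmn1, A, b, (l2 - 2, m2, n2), B)
        + m2 * (m2 - 1) * overlap_prim(a, lmn1, A, b, (l2, m2 - 2, n2), B)
        + n2 * (n2 - 1) * overlap_prim(a, lmn1, A, b, (l2, m2, n2 - 2), B)
    )
    return term0 + term1 + term2


def R(t, u, v, n, p, PCx, PCy, PCz, RPC):
    """Hermite Coulomb auxiliary integral."""
    if t == u == v == 0:
        return (-2.0 * p) ** n * boys(n, p * RPC * RPC)
    if t == 0 and u == 0:
        val = 0.0
        if v > 1:
            val += (v - 1) * R(t, u, v - 2, n + 1, p, PCx, PCy, PCz, RPC)
        val += PCz * R(t, u, v - 1, n + 1, p, PCx, PCy, PCz, RPC)
        return val
    if t == 0:
        val = 0.0
        if u > 1:
            val += (u - 1) * R(t, u - 2, v, n + 1, p, PCx, PCy, PCz, RPC)
        val += PCy * R(t, u - 1, v, n + 1, p, PCx, PCy, PCz, RPC)
        return val
    val = 0.0
    if t > 1:
        val += (t - 1) * R(t - 2, u, v, n + 1, p, PCx, PCy, PCz, RPC)
    val += PCx * R(t - 1, u, v, n + 1, p, PCx, PCy, PCz, RPC)
    return val


def nuclear_prim(a, lmn1, A, b, lmn2, B, C):
    l1, m1, n1 = lmn1
    l2, m2, n2 = lmn2
    p = a + b
    P = (a * np.asarray(A) + b * np.asarray(B)) / p
    RPC = np.linalg.norm(P - C)
    val = 0.0
    for t in range(l1 + l2 + 1):
        for u in range(m1 + m2 + 1):
            for v in range(n1 + n2 + 1):
                val += (
                    E(l1, l2, t, A[0] - B[0], a, b)
                    * E(m1, m2, u, A[1] - B[1], a, b)
                    * E(n1, n2, v, A[2] - B[2], a, b)
                    * R(t, u, v, 0, p, P[0] - C[0], P[1] - C[1], P[2] - C[2], RPC)
                )
    return 2 * np.pi / p * val


def eri_prim(a, lmn1, A, b, lmn2, B, c, lmn3, Cc, d, lmn4, D):
    l1, m1, n1 = lmn1
    l2, m2, n2 = lmn2
    l3, m3, n3 = lmn3
    l4, m4, n4 = lmn4
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    P = (a * np.asarray(A) + b * np.asarray(B)) / p
    Q = (c * np.asarray(Cc) + d * np.asarray(D)) / q
    RPQ = np.linalg.norm(P - Q)
    val = 0.0
    for t in range(l1 + l2 + 1):
        for u in range(m1 + m2 + 1):
            for v in range(n1 + n2 + 1):
                e1 = (
                    E(l1, l2, t, A[0] - B[0], a, b)
                    * E(m1, m2, u, A[1] - B[1], a, b)
                    * E(n1, n2, v, A[2] - B[2], a, b)
                )
                if e1 == 0.0:
                    continue
                for tau in range(l3 + l4 + 1):
                    for nu in range(m3 + m4 + 1):
                        for phi in range(n3 + n4 + 1):
                            e2 = (
                                E(l3, l4, tau, Cc[0] - D[0], c, d)
                                * E(m3, m4, nu, Cc[1] - D[1], c, d)
                                * E(n3, n4, phi, Cc[2] - D[2], c, d)
                            )
                            if e2 == 0.0:
                                continue
                            val += (
                                e1 * e2 * (-1) ** (tau + nu + phi)
                                * R(t + tau, u + nu, v + phi, 0, alpha,
                                    P[0] - Q[0], P[1] - Q[1], P[2] - Q[2], RPQ)
                            )
    return val * 2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))


def _dfact(n):
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


class BasisFunction:
    def __init__(self, center, lmn, exps, coefs):
        self.center = np.asarray(center, dtype=float)
        self.lmn = tuple(lmn)
        self.exps = list(exps)
        l, m, n = lmn
        # primitive normalization
        norms = [
            (2 * a / np.pi) ** 0.75
            * (4 * a) ** ((l + m + n) / 2.0)
            / np.sqrt(_dfact(2 * l - 1) * _dfact(2 * m - 1) * _dfact(2 * n - 1))
            for a in exps
        ]
        self.coefs = [c * nrm for c, nrm in zip(coefs, norms)]
        # contracted normalization
        s = 0.0
        for a, ca in zip(self.exps, self.coefs):
            for b, cb in zip(self.exps, self.coefs):
                s += ca * cb * overlap_prim(a, self.lmn, self.center, b, self.lmn, self.center)
        self.coefs = [c / np.sqrt(s) for c in self.coefs]


def build_basis(atoms, basis_name):
    """atoms: list of (symbol, xyz in Å)."""
    bfs = []
    for sym, xyz in atoms:
        center = np.asarray(xyz, dtype=float) * ANG2BOHR
        for shell, exps, coefs in BASES[basis_name][sym]:
            if shell == "s":
                bfs.append(BasisFunction(center, (0, 0, 0), exps, coefs))
            elif shell == "p":
                for lmn in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
                    bfs.append(BasisFunction(center, lmn, exps, coefs))
            else:
                raise ValueError(shell)
    return bfs


def _contract2(f, b1, b2, *extra):
    val = 0.0
    for a, ca in zip(b1.exps, b1.coefs):
        for b, cb in zip(b2.exps, b2.coefs):
            val += ca * cb * f(a, b1.lmn, b1.center, b, b2.lmn, b2.center, *extra)
    return val


def ao_integrals(atoms, basis_name):
    bfs = build_basis(atoms, basis_name)
    n = len(bfs)
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    centers = [(CHARGES[sym], np.asarray(xyz, float) * ANG2BOHR) for sym, xyz in atoms]
    for i in range(n):
        for j in range(i + 1):
            S[i, j] = S[j, i] = _contract2(overlap_prim, bfs[i], bfs[j])
            T[i, j] = T[j, i] = _contract2(kinetic_prim, bfs[i], bfs[j])
            v = 0.0
            for Z, C in centers:
                v -= Z * _contract2(nuclear_prim, bfs[i], bfs[j], C)
            V[i, j] = V[j, i] = v
    eri = np.zeros((n, n, n, n))
    # chemist order (ij|kl), 8-fold symmetry
    for i in range(n):
        for j in range(i + 1):
            ij = i * (i + 1) // 2 + j
            for k in range(i + 1):
                for l in range(k + 1):
                    kl = k * (k + 1) // 2 + l
                    if kl > ij:
                        continue
                    val = 0.0
                    for a, ca in zip(bfs[i].exps, bfs[i].coefs):
                        for b, cb in zip(bfs[j].exps, bfs[j].coefs):
                            for c, cc in zip(bfs[k].exps, bfs[k].coefs):
                                for d, cd in zip(bfs[l].exps, bfs[l].coefs):
                                    val += ca * cb * cc * cd * eri_prim(
                                        a, bfs[i].lmn, bfs[i].center,
                                        b, bfs[j].lmn, bfs[j].center,
                                        c, bfs[k].lmn, bfs[k].center,
                                        d, bfs[l].lmn, bfs[l].center,
                                    )
                    for p, q, r, s in (
                        (i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
                        (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i),
                    ):
                        eri[p, q, r, s] = val
    e_nuc = 0.0
    for a in range(len(centers)):
        for b in range(a):
            Za, Ra = centers[a]
            Zb, Rb = centers[b]
            e_nuc += Za * Zb / np.linalg.norm(Ra - Rb)
    return S, T + V, eri, e_nuc


def rhf(atoms, basis_name, max_iter=300, tol=1e-11):
    """Closed-shell RHF (DIIS on the orbital gradient FDS - SDF);
    returns (E, eps, C, hcore_mo, eri_mo, e_nuc, nelec)."""
    S, hcore, eri, e_nuc = ao_integrals(atoms, basis_name)
    nelec = sum(CHARGES[sym] for sym, _ in atoms)
    assert nelec % 2 == 0
    no = nelec // 2
    eps, C = eigh(hcore, S)
    E = 0.0
    fock_list, err_list = [], []
    for it in range(max_iter):
        Cocc = C[:, :no]
        D = Cocc @ Cocc.T
        J = np.einsum("pqrs,rs->pq", eri, D)
        K = np.einsum("prqs,rs->pq", eri, D)
        F = hcore + 2 * J - K
        E = np.einsum("pq,pq->", hcore + F, D) + e_nuc
        err = F @ D @ S - S @ D @ F
        if np.abs(err).max() < tol and it > 1:
            break
        fock_list.append(F.copy())
        err_list.append(err.ravel())
        if len(fock_list) > 8:
            fock_list.pop(0)
            err_list.pop(0)
        n = len(fock_list)
        if n > 1:
            B = -np.ones((n + 1, n + 1))
            B[-1, -1] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = err_list[i] @ err_list[j]
            rhs = np.zeros(n + 1)
            rhs[-1] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:-1]
                F = sum(ci * Fi for ci, Fi in zip(c, fock_list))
            except np.linalg.LinAlgError:
                pass
        eps, C = eigh(F, S)
    else:
        raise RuntimeError("SCF not converged")
    h_mo = C.T @ hcore @ C
    eri_mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri, C, C, C, C, optimize=True)
    return E, eps, C, h_mo, eri_mo, e_nuc, nelec
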