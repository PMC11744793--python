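"""Oracle-equivalence checks: contracted implementation vs determinant space.

Each check pits a contracted-tensor quantity against its brute-force
determinant-space twin on one fixture.  Used by the ``verify`` CLI subcommand
and by the test suite; all randomness is fixed-seed.
"""

from __future__ import annotations

import numpy as np

from .cc_ground import AmplitudeVector, cc_energy, cc_residual, solve_cc
from .gcc_core import hbar_matrix
from .hamiltonian_io import load_fixture, to_spin_orbitals
from .jacobian_eom import solve_eigenpairs
from . import oracle_fci as ofc

__all__ = ["verify_fixture"]


def _check(report, name, value, tol):
    report["checks"][name] = {"value": float(value), "tol": tol,
                              "passed": bool(value <= tol)}


def verify_fixture(name: str, seed: int = 7) -> dict:
    """Run every oracle-equivalence check that fits the fixture's size."""
    fx = load_fixture(name)
    ints = fx.load()
    ints.validate()
    so = to_spin_orbitals(ints)
    no, nv = so.nocc, so.nvir
    dim = AmplitudeVector.dimension(no, nv)
    report = {"fixture": name, "n_spinorb": so.n_spinorb, "dim": dim, "checks": {}}

    # reference energy: spatial vs spin-orbital route
    _check(report, "reference_energy_routes",
           abs(ints.reference_energy() - so.reference_energy()), 1e-12)

    rng = np.random.default_rng(seed)
    t_rand = AmplitudeVector.from_flat(rng.normal(scale=0.05, size=dim), no, nv)

    res = solve_cc(so, tol=1e-10, max_iter=400)
    report["ccsd_e0"] = res.e0
    report["ccsd_converged"] = bool(res.converged)

    small = so.n_spinorb <= 16 and dim <= 400
    if small:
        # residual: contracted vs dense similarity transform, random and converged t
        om_det = ofc.residual_determinant_route(t_rand, so)
        _check(report, "residual_vs_determinant_random_t",
               np.abs(cc_residual(t_rand, so).flat - om_det).max(), 1e-9)
        if res.converged:
            om_det = ofc.residual_determinant_route(res.amplitudes, so)
            _check(report, "residual_vs_determinant_converged_t",
                   np.abs(cc_residual(res.amplitudes, so).flat - om_det).max(), 1e-9)

        # energy: contracted vs <HF|H exp(T)|HF> with dense matrices
        space = ofc.enumerate_space(so, ms2=None)
        vec = ofc.cc_wavefunction_expand(t_rand, space)
        H = ofc.build_dense_hamiltonian(space, so)
        _check(report, "energy_vs_determinant",
               abs(cc_energy(t_rand, so) - (H @ vec)[0]), 1e-10)

        # Jacobian: exact-stencil route vs finite differences (raises on
        # mismatch) and vs the determinant-space commutator route
        A = ofc.dense_jacobian(t_rand, so)
        hbar = ofc.hbar_dense(t_rand, space, so)
        maps = ofc.mu_determinants(space, no, nv)
        A_det = np.empty((dim, dim))
        for nu in range(dim):
            tau = ofc.excitation_matrix(nu, space, no, nv)
            comm = (hbar @ tau - tau @ hbar)[:, 0]
            A_det[:, nu] = [s * comm[i] for i, s in maps]
        _check(report, "jacobian_vs_determinant", np.abs(A - A_det).max(), 1e-9)

        # full Hbar matrix over {HF, mu} vs determinant twin
        _check(report, "hbar_matrix_vs_determinant",
               np.abs(hbar_matrix(t_rand, so) - ofc.hbar_matrix_mu_basis(t_rand, so)).max(),
               1e-9)

    # 2-electron fixtures: CCSD and EOM are exact
    if so.nocc == 2 and res.converged:
        fci_all = ofc.fci_solve(so, ms2=None)
        _check(report, "ccsd_equals_fci_ground",
               abs(res.e0 - fci_all.energies[0]), 1e-10)
        pairs = solve_eigenpairs(res.amplitudes, so, k=None)
        exc = np.sort(fci_all.energies[1:] - fci_all.energies[0])
        _check(report, "eom_equals_fci_gaps",
               np.abs(np.sort(pairs.omegas.real) - exc).max(), 1e-9)
        _check(report, "eigenpair_biorthonormality",
               pairs.biorthonormality_error(), 1e-10)

    return report
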