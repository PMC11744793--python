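import numpy as np
import pytest

from gccsd.cc_ground import AmplitudeVector, cc_residual, solve_cc
from gccsd.gcc_core import (
    GCCError,
    ProjectionSet,
    full_space_matrix,
    hbar_matrix,
    match_full_space_states,
    projected_residual,
    purge_components,
    reduced_matrix,
    solve_full_space,
    solve_gcc,
)
from gccsd.jacobian_eom import solve_eigenpairs
from gccsd.oracle_fci import fci_solve, hbar_matrix_mu_basis

from conftest import get_so, get_cc


@pytest.fixture(scope="module")
def gcc_h4_loop01():
    so = get_so("h4_loop_01")
    state = solve_gcc(so, k=1, tol=1e-10, roots="singlet")
    assert state.converged
    return so, state


@pytest.fixture(scope="module")
def pairs_h4(cc_h4_center_state=None):
    so = get_so("h4_center")
    t = get_cc("h4_center").amplitudes
    return so, t, solve_eigenpairs(t, so, k=None)


def test_purge_contracts(pairs_h4):
    so, t, pairs = pairs_h4
    proj = ProjectionSet.from_eigenpairs(pairs, [0])
    # t = r_1 purges to zero
    r = AmplitudeVector.from_flat(pairs.rights[0].real, t.nocc, t.nvir)
    assert np.abs(purge_components(r, proj).flat).max() < 1e-12
    # a vector already orthogonal to l_1 is unchanged
    v = t.flat - pairs.rights[0].real * (pairs.lefts[0].real @ t.flat)
    va = AmplitudeVector.from_flat(v, t.nocc, t.nvir)
    assert np.abs(purge_components(va, proj).flat - v).max() < 1e-12
    # idempotence and exact constraint
    p1 = purge_components(t, proj)
    p2 = purge_components(p1, proj)
    assert np.abs(p1.flat - p2.flat).max() < 1e-14
    assert abs(pairs.lefts[0].real @ p1.flat) < 1e-14


def test_projected_residual_contracts(pairs_h4, rng):
    so, t, pairs = pairs_h4
    dim = len(t.flat)
    # k = 0: projected residual is the plain residual
    empty = ProjectionSet.empty(dim)
    t_rand = AmplitudeVector.from_flat(rng.normal(scale=0.05, size=dim), t.nocc, t.nvir)
    assert np.array_equal(projected_residual(t_rand, empty, so).flat,
                          cc_residual(t_rand, so).flat)
    # l_n . Om~ = 0 for any amplitudes
    proj = ProjectionSet.from_eigenpairs(pairs, [0, 1])
    omp = projected_residual(t_rand, proj, so).flat
    assert np.abs(proj.lefts @ omp).max() < 1e-12


@pytest.mark.parametrize("name", ["h2_sto3g", "h4_center", "lih_sto3g_r2.00"])
def test_k0_reduces_to_ccsd(name):
    so = get_so(name)
    st = solve_gcc(so, k=0, tol=1e-11)
    cc = solve_cc(so, tol=1e-11)
    assert st.converged and cc.converged
    assert st.e0 == pytest.approx(cc.e0, abs=1e-12)
    assert np.abs(st.amplitudes.flat - cc.amplitudes.flat).max() < 1e-10


def test_gcc_joint_convergence_contract(gcc_h4_loop01):
    """Constraints and projected residual vanish while the full residual
    stays visibly nonzero near the degeneracy."""
    so, state = gcc_h4_loop01
    assert state.projected_residual_norm <= 1e-10
    assert state.constraint_norms.max() <= 1e-10
    assert state.eigenpair_residual <= 1e-10
    assert np.linalg.norm(state.omega_full.flat) > 1e-6
    assert state.projection.biorthonormality_error() < 1e-10
    # the projected state is the spin-symmetric singlet partner
    from gccsd.jacobian_eom import classify_root
    w, p = classify_root(state.projection.rights[0], so.nocc, so.nvir)
    assert w > 0.9 and p > 0.9


def test_hbar_matrix_matches_determinant_twin(so_h2, rng):
    dim = AmplitudeVector.dimension(so_h2.nocc, so_h2.nvir)
    t = AmplitudeVector.from_flat(rng.normal(scale=0.07, size=dim), so_h2.nocc, so_h2.nvir)
    M = hbar_matrix(t, so_h2)
    M_det = hbar_matrix_mu_basis(t, so_h2)
    assert np.abs(M - M_det).max() < 1e-12


def test_reduced_matrix_structure(gcc_h4_loop01):
    so, state = gcc_h4_loop01
    rs = reduced_matrix(state, so)
    assert rs.dim == 2
    assert rs.entries[0, 0] == pytest.approx(state.e0, abs=1e-12)
    assert rs.entries[1, 0] == pytest.approx(
        state.projection.lefts[0] @ state.omega_full.flat, abs=1e-12)


def test_reduced_matrix_triangular_when_uncoupled():
    """When l_1 . Omega = 0 (here by spatial symmetry on H2) the reduced
    matrix is upper triangular with eigenvalues exactly {e0, e0 + omega_1}."""
    so = get_so("h2_sto3g")
    state = solve_gcc(so, k=1, tol=1e-10, roots="singlet")
    rs = reduced_matrix(state, so)
    assert abs(rs.entries[1, 0]) < 1e-10
    ev = np.sort(rs.eigenvalues.real)
    expect = np.sort([state.e0, state.e0 + state.projection.omegas[0]])
    assert np.abs(ev - expect).max() < 1e-10


def test_full_space_k0_is_standard_eom(cc_h4_center, so_h4_center):
    st = solve_gcc(so_h4_center, k=0, tol=1e-10)
    prob = full_space_matrix(st, so_h4_center)
    assert prob.k == 0
    assert np.abs(prob.s_fs - np.eye(prob.dim)).max() < 1e-12
    assert np.abs(prob.h_fs - hbar_matrix(st.amplitudes, so_h4_center)).max() < 1e-10


def test_full_space_metric_structure(gcc_h4_loop01):
    so, state = gcc_h4_loop01
    prob = full_space_matrix(state, so)
    dim = len(state.amplitudes.flat)
    S = prob.s_fs
    k = state.k
    # identity outside the projected-manifold block
    assert np.abs(S[:1 + k, :1 + k] - np.eye(1 + k)).max() < 1e-12
    assert np.abs(S[:1 + k, 1 + k:]).max() < 1e-12
    assert np.abs(S[1 + k:, :1 + k]).max() < 1e-12
    # <mu~|nu~> = delta - <mu|R><L|nu>
    Q = np.eye(dim) - np.outer(state.projection.rights[0], state.projection.lefts[0])
    assert np.abs(S[1 + k:, 1 + k:] - Q).max() < 1e-12


@pytest.mark.parametrize("name", ["h2_sto3g", "h2_631g"])
def test_full_space_exact_limit(name):
    """For two electrons the full-space eigenvalues are the FCI energies."""
    so = get_so(name)
    state = solve_gcc(so, k=1, tol=1e-10, roots="singlet")
    sol = solve_full_space(full_space_matrix(state, so))
    fci = fci_solve(so, ms2=None)
    assert sol.n_spurious == 1
    assert len(sol.energies) == len(fci.energies)
    assert np.abs(np.sort(sol.energies.real) - fci.energies).max() < 1e-8


def test_generalized_eigenpair_residual(gcc_h4_loop01):
    so, state = gcc_h4_loop01
    prob = full_space_matrix(state, so)
    sol = solve_full_space(prob)
    for m in range(3):
        x = sol.vectors[:, m]
        r = prob.h_fs @ x - sol.energies[m] * (prob.s_fs @ x)
        assert np.linalg.norm(r) < 1e-8


def test_projector_scale_invariance(gcc_h4_loop01):
    """Rescaling r -> c r, l -> l/c leaves projected residual, reduced and
    full-space eigenvalues unchanged."""
    so, state = gcc_h4_loop01
    c = 3.7
    scaled = ProjectionSet(state.projection.omegas.copy(),
                           c * state.projection.rights,
                           state.projection.lefts / c)
    omp = projected_residual(state.amplitudes, state.projection, so).flat
    omp2 = projected_residual(state.amplitudes, scaled, so).flat
    assert np.abs(omp - omp2).max() < 1e-10

    import dataclasses
    st2 = dataclasses.replace(state, projection=scaled)
    rs1 = np.sort(reduced_matrix(state, so).eigenvalues.real)
    rs2 = np.sort(reduced_matrix(st2, so).eigenvalues.real)
    assert np.abs(rs1 - rs2).max() < 1e-10
    fs1 = np.sort(solve_full_space(full_space_matrix(state, so)).energies.real)
    fs2 = np.sort(solve_full_space(full_space_matrix(st2, so)).energies.real)
    assert np.abs(fs1 - fs2).max() < 1e-9


def test_state_matching_handles_reordered_spectra():
    """At a flipped-region point the projected state lies below the reference
    state; matching by eigenvector weight still pairs RS and FS roots."""
    so = get_so("h4_loop_12")
    state = solve_gcc(so, k=1, tol=1e-10, roots="singlet")
    assert state.projection.omegas[0] < 0  # the flipped region
    rs = reduced_matrix(state, so)
    sol = solve_full_space(full_space_matrix(state, so))
    idx = match_full_space_states(sol, 1)
    e_fs = sol.energies[idx].real
    # HF-dominated root above the projected-state root here
    assert e_fs[1] < e_fs[0]
    ev = rs.eigenvalues.real
    order = np.argsort(np.abs(rs.eigvecs[0, :]))[::-1]
    e_rs = ev[order]
    assert np.abs(e_rs - e_fs).max() < 1e-9


def test_unconverged_state_rejected(so_h4_center):
    st = solve_gcc(so_h4_center, k=1, tol=1e-14, max_macro=1, max_micro=1,
                   roots="singlet")
    assert not st.converged
    with pytest.raises(GCCError):
        reduced_matrix(st, so_h4_center)
    with pytest.raises(GCCError):
        full_space_matrix(st, so_h4_center)


def test_invalid_k_rejected(so_h2):
    with pytest.raises(ValueError):
        solve_gcc(so_h2, k=-1)
    with pytest.raises(ValueError):
        solve_gcc(so_h2, k=99)
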