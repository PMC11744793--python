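import numpy as np
import pytest

from gccsd.cc_ground import solve_cc
from gccsd.gcc_core import solve_gcc
from gccsd.hamiltonian_io import fixture_catalog, load_fixture
from gccsd.scans import (
    BranchingPlane,
    ScanPoint,
    ScanResult,
    amplitude_block_weights,
    branch_diagnostics,
    branching_grid,
    circle_scan,
    extensivity_experiment,
    h4_loop_provider,
    phase_report,
    warm_start_scan,
)



@pytest.fixture(scope="module")
def loop():
    provider, radius, n = h4_loop_provider()
    return provider, radius, n


@pytest.fixture(scope="module")
def gcc_loop_scan(loop):
    provider, radius, n = loop
    return circle_scan(provider, radius, n, turns=2, method="gcc", k=1,
                       roots="singlet")


def test_branching_plane_validation():
    atoms = [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 1.0))]
    g = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
    with pytest.raises(ValueError):
        BranchingPlane(atoms, g, np.zeros((2, 3)))
    bp = BranchingPlane(atoms, g, np.array([[0, 1.0, 0], [0, -1.0, 0]]))
    moved = bp.displace(0.5, 0.0)
    assert moved[0][1][0] == pytest.approx(0.5)
    assert moved[1][1][0] == pytest.approx(-0.5)


def test_single_point_path_equals_standalone(loop):
    provider, radius, n = loop
    so = provider(radius, 0.0)
    res = warm_start_scan([({"theta": 0.0}, so)], method="cc")
    direct = solve_cc(so, tol=1e-10)
    assert res.points[0].e0 == pytest.approx(direct.e0, abs=1e-12)
    resg = warm_start_scan([({"theta": 0.0}, so)], method="gcc", roots="singlet")
    stateg = solve_gcc(so, k=1, tol=1e-10, roots="singlet")
    assert resg.points[0].e0 == pytest.approx(stateg.e0, abs=1e-12)


def test_circle_ring_matches_grid_ring(loop):
    """A one-turn circle and a one-radius grid over the same angles visit the
    same geometries and produce identical energies."""
    provider, radius, n = loop
    angles = [2 * np.pi * j / n for j in range(n)]
    ring = branching_grid(provider, [radius], angles, method="cc")
    circ = circle_scan(provider, radius, n, turns=1, method="cc")
    for pg, pc in zip(ring.points, circ.points[:n]):
        assert pg.e0 == pytest.approx(pc.e0, abs=1e-12)
    # grid records average-relative energies
    ok = [p for p in ring.points if np.isfinite(p.s0)]
    for p in ok:
        assert p.params["s0_rel"] + p.params["s1_rel"] == pytest.approx(0.0, abs=1e-12)


def test_gcc_circle_phase_signature(gcc_loop_scan):
    """Amplitudes and Jacobian eigenvectors close after one full turn; the
    reduced-space eigenvectors flip sign at 2 pi and close at 4 pi."""
    rep = phase_report(gcc_loop_scan)
    assert rep["amplitudes"]["class"] == "2pi-periodic"
    assert rep["amplitudes"]["closure_2pi"] <= 1e-6
    assert rep["jacobian_eigvec"]["class"] == "2pi-periodic"
    assert rep["jacobian_eigvec"]["closure_2pi"] <= 1e-6
    for c in (0, 1):
        assert rep[f"rs_eigvec_{c}"]["class"] == "4pi-periodic"
        assert rep[f"rs_eigvec_{c}"]["sign_flip_2pi"] <= 1e-6
        assert rep[f"rs_eigvec_{c}"]["closure_4pi"] <= 1e-6


def test_gcc_circle_all_points_clean(gcc_loop_scan):
    diag = branch_diagnostics(gcc_loop_scan)
    assert set(diag["counts"]) <= {"OK", "complex-pair"}
    assert diag["counts"].get("complex-pair", 0) == 0
    assert all(p.converged for p in gcc_loop_scan.points)
    assert all(p.constraint_max <= 1e-10 for p in gcc_loop_scan.points)
    # positive reduced-space gap everywhere on the loop
    assert all(p.gap > 0 for p in gcc_loop_scan.points)


def test_cc_circle_exhibits_pathology(loop):
    """Plain CC around the intersection: at least one non-OK point (flipped
    solutions with negative excitation energy in the lower arc)."""
    provider, radius, n = loop
    scan = circle_scan(provider, radius, n, turns=1, method="cc")
    diag = branch_diagnostics(scan)
    non_ok = sum(v for k, v in diag["counts"].items() if k != "OK")
    assert non_ok >= 1
    assert min(p.gap for p in scan.points if np.isfinite(p.gap)) < 0


def test_phase_report_constant_scan():
    vec = np.array([1.0, 2.0, 3.0])
    pts = [ScanPoint(params={"step": s}, method="gcc", converged=True, e0=-1.0,
                     t_flat=vec.copy(), r1=vec.copy(),
                     rs_vecs=np.eye(2)) for s in range(9)]
    scan = ScanResult(points=pts, method="gcc", meta={"n_points": 4, "turns": 2})
    rep = phase_report(scan)
    for q in ("amplitudes", "jacobian_eigvec", "rs_eigvec_0", "rs_eigvec_1"):
        assert rep[q]["class"] == "2pi-periodic"
        assert rep[q]["closure_2pi"] == 0.0


def test_phase_report_requires_two_turns(loop):
    provider, radius, n = loop
    scan = circle_scan(provider, radius, n, turns=1, method="cc")
    with pytest.raises(ValueError):
        phase_report(scan)


def test_synthetic_branch_switch_flagged():
    pts = [ScanPoint(params={}, method="cc", converged=True,
                     e0=-1.0 - 0.001 * i + (0.1 if i >= 6 else 0.0), gap=0.1)
           for i in range(10)]
    diag = branch_diagnostics(ScanResult(points=pts, method="cc"))
    assert diag["labels"][6] == "phase-mismatch"
    assert diag["labels"].count("phase-mismatch") == 1


def test_lih_bond_scan_continuous():
    """Warm-started GCC along the LiH dissociation fixtures: every point
    converges and the curve is continuous at the fixture spacing."""
    lih = sorted((fx for fx in fixture_catalog()
                  if fx.parameters.get("scan_family") == "lih_bond"),
                 key=lambda f: f.parameters["bond_length"])
    path = [({"r": fx.parameters["bond_length"]}, fx.load()) for fx in lih[:4]]
    res = warm_start_scan(path, method="gcc", k=1, roots="singlet")
    assert all(p.converged for p in res.points)
    jumps = [abs(b.e0 - a.e0) for a, b in zip(res.points[:-1], res.points[1:])]
    assert max(jumps) < 0.15  # smooth at 0.5 Å fixture spacing
    assert all(p.gap > 0 for p in res.points)
    # backward traversal converges to the same curve on this path
    back = warm_start_scan(path, method="gcc", k=1, roots="singlet", direction=-1)
    assert back.points[-1].e0 == pytest.approx(res.points[0].e0, abs=1e-9)


def test_block_weights():
    blocks = [np.array([0, 1, 4, 5]), np.array([2, 3, 6, 7])]
    # no=4, nv=4 composite of two 2-spin-orbital fragments
    from gccsd.cc_ground import AmplitudeVector, mu_orbital_labels
    singles, doubles = mu_orbital_labels(4, 4)
    flat = np.zeros(AmplitudeVector.dimension(4, 4))
    flat[singles.index((0, 4))] = 1.0  # excitation within fragment 0
    w = amplitude_block_weights(flat, 4, 4, blocks)
    assert w[0] == pytest.approx(1.0)
    assert w[1] == 0.0 and w[2] == 0.0


def test_extensivity_pattern():
    """Monomer-A excitation energies are invariant across composites; the
    other monomers' energies shift at most marginally; ground-state energies
    are additive."""
    mono = [load_fixture(f"h2_monomer_{x}").load() for x in "abc"]
    res = extensivity_experiment(mono, k=1)
    labels = res["labels"]
    prefixes = res["prefixes"]
    ea_alone = prefixes["A"]["excitations"]["A"]
    for name in ("AB", "ABC"):
        for e_ref, e in zip(ea_alone, prefixes[name]["excitations"]["A"]):
            assert abs(e - e_ref) <= 1e-9
    # B energies barely perturbed relative to isolated CCSD
    for name in ("AB", "ABC"):
        for e_cc, e in zip(res["cc_reference"]["B"], prefixes[name]["excitations"]["B"]):
            assert abs(e - e_cc) <= 1e-6
    # adding C changes nothing for A and B above 1e-9
    for lab in ("A", "B"):
        for e2, e3 in zip(prefixes["AB"]["excitations"][lab],
                          prefixes["ABC"]["excitations"][lab]):
            assert abs(e3 - e2) <= 1e-9
    for name, err in res["additivity_error"].items():
        assert abs(err) <= 1e-9
    assert all(rec["constraint_max"] <= 1e-10 for rec in prefixes.values())
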