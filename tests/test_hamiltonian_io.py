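import numpy as np
import pytest

from gccsd.hamiltonian_io import (
    IntegralSet,
    direct_sum_composite,
    fixture_catalog,
    load_fixture,
    read_fcidump,
    to_spin_orbitals,
    write_fcidump,
)
from gccsd.cc_ground import solve_cc
from gccsd.oracle_fci import fci_solve

from conftest import get_so


def brute_force_reference_energy(ints):
    """<HF|H|HF> summed orbital by orbital from the field definitions."""
    no = ints.n_electrons // 2
    e = ints.e_nuc
    for i in range(no):
        e += 2 * ints.h[i, i]
    for i in range(no):
        for j in range(no):
            e += 2 * ints.g[i, i, j, j] - ints.g[i, j, j, i]
    return e


def test_minimal_one_element_file_roundtrip(tmp_path):
    """A two-orbital file holding a single h element parses to exactly that."""
    f = tmp_path / "minimal.fcidump"
    f.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n ORBSYM=1,1,\n ISYM=1,\n/\n"
                 " 0.5  1 1 0 0\n 0.0  0 0 0 0\n")
    ints = read_fcidump(f)
    assert ints.n_orbitals == 2 and ints.n_electrons == 2
    assert ints.h[0, 0] == 0.5
    assert np.count_nonzero(ints.h) == 1
    assert not ints.g.any()
    assert ints.e_nuc == 0.0


def test_malformed_inputs_rejected(tmp_path):
    bad_header = tmp_path / "bad1.fcidump"
    bad_header.write_text("NORB=2\n 0.5 1 1 0 0\n")
    with pytest.raises(ValueError, match="header"):
        read_fcidump(bad_header)
    bad_index = tmp_path / "bad2.fcidump"
    bad_index.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n/\n 0.5  3 1 0 0\n")
    with pytest.raises(ValueError, match="out of range"):
        read_fcidump(bad_index)
    odd = tmp_path / "bad3.fcidump"
    odd.write_text("&FCI NORB=2,NELEC=3,MS2=1,\n/\n 0.0 0 0 0 0\n")
    with pytest.raises(ValueError, match="odd"):
        read_fcidump(odd)


def test_empty_integral_set_writes_header_and_enuc_only(tmp_path):
    ints = IntegralSet(n_orbitals=2, n_electrons=2,
                       h=np.zeros((2, 2)), g=np.zeros((2, 2, 2, 2)), e_nuc=1.25)
    path = write_fcidump(ints, tmp_path / "empty.fcidump")
    body = [ln for ln in path.read_text().splitlines() if ln and not
            (ln.startswith("&") or ln.startswith(" ORBSYM") or ln.startswith(" ISYM") or ln == "/")]
    assert len(body) == 1
    assert body[0].split()[1:] == ["0", "0", "0", "0"]
    assert float(body[0].split()[0]) == 1.25


@pytest.mark.parametrize("name", ["h2_sto3g", "h2_631g", "lih_sto3g_r1.50", "h4_center"])
def test_fcidump_roundtrip(tmp_path, name):
    """write(read(f)) re-read preserves all integral tensors to 1e-14."""
    ints = load_fixture(name).load()
    path = write_fcidump(ints, tmp_path / "rt.fcidump")
    back = read_fcidump(path)
    assert np.abs(back.h - ints.h).max() < 1e-14
    assert np.abs(back.g - ints.g).max() < 1e-14
    assert abs(back.e_nuc - ints.e_nuc) < 1e-14
    assert back.n_electrons == ints.n_electrons


def test_reference_energy_matches_brute_force():
    ints = load_fixture("h2_sto3g").load()
    assert ints.reference_energy() == pytest.approx(
        brute_force_reference_energy(ints), abs=1e-12)
    # and the RHF energy the generator recorded
    e_rhf = load_fixture("h2_sto3g").parameters["e_rhf"]
    assert ints.reference_energy() == pytest.approx(e_rhf, abs=1e-9)


@pytest.mark.parametrize("name", ["h2_sto3g", "lih_sto3g_r2.00", "h4_loop_03"])
def test_spin_orbital_construction(name):
    ints = load_fixture(name).load()
    so = to_spin_orbitals(ints)
    # antisymmetry of the two-electron tensor
    g = so.g_anti
    assert np.abs(g + g.transpose(1, 0, 2, 3)).max() < 1e-12
    assert np.abs(g + g.transpose(0, 1, 3, 2)).max() < 1e-12
    # spatial and spin-orbital reference energies agree
    assert so.reference_energy() == pytest.approx(ints.reference_energy(), abs=1e-12)
    # Brillouin: occupied-virtual Fock block vanishes for canonical orbitals
    assert np.abs(so.fock[np.ix_(so.occ, so.vir)]).max() < 1e-8
    # Fock eigenvalues reproduce the engine-reported orbital energies
    eng = np.array(load_fixture(name).parameters["orbital_energies"])
    eps = np.unique(np.round(np.linalg.eigvalsh(so.fock), 8))
    assert np.allclose(np.sort(eng), np.sort(np.round(np.diag(so.fock)[::2], 8)), atol=1e-6)
    assert np.abs(np.sort(eps) - np.sort(np.unique(np.round(eng, 8)))).max() < 1e-6


def test_frozen_core_preserves_reference_energy():
    ints = load_fixture("lih_sto3g_r1.50").load()
    so_all = to_spin_orbitals(ints)
    so_fc = to_spin_orbitals(ints, frozen_core=1)
    assert so_fc.n_spinorb == so_all.n_spinorb - 2
    assert so_fc.reference_energy() == pytest.approx(so_all.reference_energy(), abs=1e-10)


def test_direct_sum_identity_and_block_structure():
    a = load_fixture("h2_monomer_a").load()
    b = load_fixture("h2_monomer_b").load()
    c = load_fixture("h2_monomer_c").load()

    comp1, maps1 = direct_sum_composite([a])
    assert np.abs(comp1.h - a.h).max() == 0.0
    assert np.abs(comp1.g - a.g).max() == 0.0

    comp, maps = direct_sum_composite([a, b])
    # all cross-fragment integrals exactly zero
    ma, mb = maps
    mask = np.zeros(comp.n_orbitals, dtype=int)
    mask[mb] = 1
    for idx in zip(*np.nonzero(comp.h)):
        assert len({mask[i] for i in idx}) == 1
    gnz = np.nonzero(comp.g)
    labels = mask[np.stack(gnz)]
    assert (labels.max(axis=0) == labels.min(axis=0)).all()
    assert comp.e_nuc == pytest.approx(a.e_nuc + b.e_nuc, abs=1e-14)
    # reference energy additive
    assert comp.reference_energy() == pytest.approx(
        a.reference_energy() + b.reference_energy(), abs=1e-12)

    # adding a third part leaves A- and B-block integrals bit-identical
    comp3, maps3 = direct_sum_composite([a, b, c])
    assert np.array_equal(comp.h[np.ix_(ma, ma)], comp3.h[np.ix_(maps3[0], maps3[0])])
    assert np.array_equal(comp.g[np.ix_(mb, mb, mb, mb)],
                          comp3.g[np.ix_(maps3[1], maps3[1], maps3[1], maps3[1])])


def test_composite_ccsd_energy_additive():
    """E_CCSD(A + B) = E_CCSD(A) + E_CCSD(B) for noninteracting fragments."""
    a = load_fixture("h2_monomer_a").load()
    b = load_fixture("h2_monomer_b").load()
    comp, _ = direct_sum_composite([a, b])
    e_a = solve_cc(to_spin_orbitals(a), tol=1e-11).e0
    e_b = solve_cc(to_spin_orbitals(b), tol=1e-11).e0
    e_ab = solve_cc(to_spin_orbitals(comp), tol=1e-11).e0
    assert e_ab == pytest.approx(e_a + e_b, abs=1e-9)


def test_shipped_dimer_equals_direct_sum():
    a = load_fixture("h2_monomer_a").load()
    b = load_fixture("h2_monomer_b").load()
    comp, _ = direct_sum_composite([a, b])
    shipped = load_fixture("h2_dimer_ab").load()
    assert np.abs(shipped.h - comp.h).max() < 1e-14
    assert np.abs(shipped.g - comp.g).max() < 1e-14


def test_fixture_catalog_integrity():
    cat = fixture_catalog()
    names = {fx.name for fx in cat}
    for required in ["h2_sto3g", "h2_631g", "lih_sto3g_r1.00", "h4_square",
                     "h4_center", "h4_loop_00", "h4_loop_15"]:
        assert required in names
    for fx in cat:
        ints = fx.load()
        ints.validate(tol=1e-9)
        assert ints.n_electrons % 2 == 0
        assert fx.geometry.strip()


def test_h4_loop_theta_periodicity():
    """The loop parametrization maps theta and theta+2pi onto one fixture."""
    loop = sorted((fx for fx in fixture_catalog()
                   if fx.parameters.get("family") == "h4_loop"),
                  key=lambda f: f.parameters["index"])
    assert len(loop) == 16
    thetas = np.array([fx.parameters["theta"] for fx in loop])
    assert np.allclose(thetas, 2 * np.pi * np.arange(16) / 16)
    from gccsd.scans import h4_loop_provider
    provider, radius, n = h4_loop_provider()
    so_a = provider(radius, thetas[3])
    so_b = provider(radius, thetas[3] + 2 * np.pi)
    assert np.array_equal(so_a.h_so, so_b.h_so)
    assert np.array_equal(so_a.g_anti, so_b.g_anti)


def test_h4_loop_fci_gaps_positive_and_bounded():
    """FCI S0/S1 gap strictly positive on every loop point and smaller than at
    the strongly distorted reference geometry."""
    def singlet_gap(so):
        e0 = fci_solve(so, ms2=0).energies
        e2 = fci_solve(so, ms2=2).energies
        singlets = [e for e in e0 if np.abs(e2 - e).min() > 1e-9][:2]
        return singlets[1] - singlets[0]

    ref = singlet_gap(get_so("h4_distorted"))
    for j in range(16):
        gap = singlet_gap(get_so(f"h4_loop_{j:02d}"))
        assert 0.0 < gap < ref
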