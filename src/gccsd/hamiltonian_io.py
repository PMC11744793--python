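"""Molecular-orbital integrals: FCIDUMP I/O, spin-orbital construction, composites.

The electronic Hamiltonian is carried as an :class:`IntegralSet` — one- and
two-electron integrals over spatial molecular orbitals in chemist (Mulliken)
index order, plus the nuclear repulsion.  All coupled-cluster work happens in
an interleaved spin-orbital basis (:class:`SpinOrbitalIntegrals`) with
antisymmetrized physicist-order two-electron integrals, built here once per
system.  Fixture molecules ship as plain-text FCIDUMP files inside the
package; :func:`fixture_catalog` enumerates them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "IntegralSet",
    "SpinOrbitalIntegrals",
    "MolecularFixture",
    "read_fcidump",
    "write_fcidump",
    "to_spin_orbitals",
    "direct_sum_composite",
    "fixture_catalog",
    "load_fixture",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IntegralSet:
    """Second-quantized Hamiltonian over spatial molecular orbitals.

    ``h`` is the one-electron matrix (Hartree), ``g`` the two-electron tensor
    in chemist order (pq|rs), ``e_nuc`` the nuclear repulsion.  A closed-shell
    reference is assumed throughout, so ``n_electrons`` must be even.
    """

    n_orbitals: int
    n_electrons: int
    h: np.ndarray
    g: np.ndarray
    e_nuc: float = 0.0
    ms2: int = 0
    orbsym: list[int] | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        n = self.n_orbitals
        if self.h.shape != (n, n):
            raise ValueError(f"h has shape {self.h.shape}, expected {(n, n)}")
        if self.g.shape != (n, n, n, n):
            raise ValueError(f"g has shape {self.g.shape}, expected rank-4 over {n} orbitals")
        if self.n_electrons % 2 != 0:
            raise ValueError(f"odd electron count {self.n_electrons}: closed-shell reference required")

    def validate(self, tol: float = 1e-10) -> None:
        """Check the permutational symmetries of real chemist-order integrals."""
        if not np.allclose(self.h, self.h.T, atol=tol):
            raise ValueError("h is not symmetric")
        g = self.g
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if not np.allclose(g, g.transpose(perm), atol=tol):
                raise ValueError(f"g violates chemist-notation symmetry under permutation {perm}")

    def reference_energy(self) -> float:
        """Closed-shell ⟨HF|H|HF⟩ with the lowest n_electrons/2 orbitals occupied."""
        no = self.n_electrons // 2
        o = slice(0, no)
        e = 2.0 * np.trace(self.h[o, o])
        e += 2.0 * np.einsum("iijj->", self.g[o, o, o, o])
        e -= np.einsum("ijji->", self.g[o, o, o, o])
        return float(e + self.e_nuc)


@dataclass
class SpinOrbitalIntegrals:
    """Interleaved spin-orbital Hamiltonian for the CC modules.

    Spin orbital 2p is the alpha and 2p+1 the beta component of spatial
    orbital p.  ``g_anti`` holds ⟨pq||rs⟩ = (pr|qs) − (ps|qr) in physicist
    order; ``fock`` is the closed-shell reference Fock matrix.  ``occ``/``vir``
    partition the spin orbitals of the reference determinant |HF⟩.
    """

    n_spinorb: int
    h_so: np.ndarray
    g_anti: np.ndarray
    fock: np.ndarray
    occ: np.ndarray
    vir: np.ndarray
    e_nuc: float = 0.0

    @property
    def nocc(self) -> int:
        return len(self.occ)

    @property
    def nvir(self) -> int:
        return len(self.vir)

    def reference_energy(self) -> float:
        o = self.occ
        e = self.h_so[o, o].sum()
        e += 0.5 * self.g_anti[np.ix_(o, o, o, o)].trace(axis1=0, axis2=2).trace()
        return float(e + self.e_nuc)

    def orbital_energies(self) -> np.ndarray:
        return np.diag(self.fock).copy()


@dataclass
class MolecularFixture:
    """A shipped test molecule: geometry, basis tag, FCIDUMP path, parameters."""

    name: str
    geometry: str
    basis_tag: str
    integral_path: Path
    parameters: dict = field(default_factory=dict)

    def load(self) -> IntegralSet:
        return read_fcidump(self.integral_path)


# ---------------------------------------------------------------------------
# FCIDUMP (Molpro dialect)
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"&FCI\b(.*?)(?:/|&END)", re.IGNORECASE | re.DOTALL)


def _parse_header(text: str, path) -> dict:
    m = _HEADER_RE.search(text)
    if m is None:
        raise ValueError(f"{path}: malformed FCIDUMP header (no &FCI ... / namelist)")
    body = m.group(1)
    fields: dict[str, str] = {}
    for key, val in re.findall(r"(\w+)\s*=\s*([^=]*?)(?=[,\s]\s*\w+\s*=|$)", body, re.DOTALL):
        fields[key.upper()] = val.strip().rstrip(",")
    out = {}
    for key in ("NORB", "NELEC", "MS2"):
        if key in fields:
            out[key] = int(fields[key])
    if "NORB" not in out or "NELEC" not in out:
        raise ValueError(f"{path}: FCIDUMP header missing NORB/NELEC")
    if "ORBSYM" in fields:
        out["ORBSYM"] = [int(x) for x in re.split(r"[,\s]+", fields["ORBSYM"].strip(", ")) if x]
    return out


def read_fcidump(path) -> IntegralSet:
    """Parse a Molpro-dialect FCIDUMP file into an :class:`IntegralSet`.

    Indices are 1-based in the file and converted to the internal 0-based
    convention; all permutation-symmetry-equivalent integral entries are
    populated from the unique values stored on disk.
    """
    path = Path(path)
    text = path.read_text()
    header = _parse_header(text, path)
    n = header["NORB"]
    nelec = header["NELEC"]
    if nelec % 2 != 0:
        raise ValueError(f"{path}: odd NELEC={nelec} not supported (closed-shell reference)")
    h = np.zeros((n, n))
    g = np.zeros((n, n, n, n))
    e_nuc = 0.0
    # integral body starts after the namelist terminator
    body_start = _HEADER_RE.search(text).end()
    for lineno, line in enumerate(text[body_start:].splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}: malformed integral line {lineno}: {line!r}")
        val = float(parts[0])
        i, j, k, l = (int(x) for x in parts[1:])
        for idx in (i, j, k, l):
            if idx < 0 or idx > n:
                raise ValueError(f"{path}: orbital index {idx} out of range on line {lineno}: {line!r}")
        if i == 0 and j == 0 and k == 0 and l == 0:
            e_nuc = val
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise ValueError(f"{path}: bad one-electron indices on line {lineno}: {line!r}")
            h[i - 1, j - 1] = val
            h[j - 1, i - 1] = val
        else:
            if 0 in (i, j, k, l):
                raise ValueError(f"{path}: bad two-electron indices on line {lineno}: {line!r}")
            p, q, r, s = i - 1, j - 1, k - 1, l - 1
            for a, b, c, d in (
                (p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
                (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p),
            ):
                g[a, b, c, d] = val
    return IntegralSet(
        n_orbitals=n, n_electrons=nelec, h=h, g=g, e_nuc=e_nuc,
        ms2=header.get("MS2", 0), orbsym=header.get("ORBSYM"),
    )


def write_fcidump(ints: IntegralSet, path, floor: float = 1e-16):
    """Write symmetry-unique integrals above ``floor`` in the Molpro dialect."""
    path = Path(path)
    n = ints.n_orbitals
    orbsym = ints.orbsym if ints.orbsym is not None else [1] * n
    lines = [
        f"&FCI NORB={n},NELEC={ints.n_electrons},MS2={ints.ms2},",
        " ORBSYM=" + ",".join(str(s) for s in orbsym) + ",",
        " ISYM=1,",
        "/",
    ]

    def emit(val, i, j, k, l):
        lines.append(f" {val: .16e} {i:4d} {j:4d} {k:4d} {l:4d}")

    # unique two-electron: pq and rs pair-canonical, pair index ordered
    for p in range(n):
        for q in range(p + 1):
            for r in range(p + 1):
                smax = q if r == p else r
                for s in range(smax + 1):
                    val = ints.g[p, q, r, s]
                    if abs(val) > floor:
                        emit(val, p + 1, q + 1, r + 1, s + 1)
    for p in range(n):
        for q in range(p + 1):
            if abs(ints.h[p, q]) > floor:
                emit(ints.h[p, q], p + 1, q + 1, 0, 0)
    emit(ints.e_nuc, 0, 0, 0, 0)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# spin orbitals
# ---------------------------------------------------------------------------

def to_spin_orbitals(ints: IntegralSet, frozen_core: int = 0) -> SpinOrbitalIntegrals:
    """Build interleaved spin-orbital tensors and the reference Fock matrix.

    ``frozen_core`` drops that many lowest *spatial* orbitals from the
    correlated space after folding their mean field into the one-electron part.
    """
    if ints.n_electrons % 2 != 0:
        raise ValueError("odd electron count")
    n = ints.n_orbitals
    nso = 2 * n
    # spin map: spin orbital P -> spatial P//2, spin P%2
    spat = np.arange(nso) // 2
    spin = np.arange(nso) % 2
    h_so = ints.h[np.ix_(spat, spat)] * (spin[:, None] == spin[None, :])
    # chemist spin integrals (PQ|RS), then physicist antisymmetrized
    g_spat = ints.g[np.ix_(spat, spat, spat, spat)]
    same12 = spin[:, None] == spin[None, :]
    g_chem = g_spat * same12[:, :, None, None] * same12[None, None, :, :]
    # <PQ|RS> = (PR|QS);  <PQ||RS> = <PQ|RS> - <PQ|SR>
    g_phys = g_chem.transpose(0, 2, 1, 3)
    g_anti = g_phys - g_phys.transpose(0, 1, 3, 2)

    nocc = ints.n_electrons
    occ = np.arange(nocc)
    vir = np.arange(nocc, nso)
    fock = h_so + np.einsum("pkqk->pq", g_anti[:, occ][:, :, :, occ])

    e_nuc = ints.e_nuc
    if frozen_core:
        ncore = 2 * frozen_core
        if ncore >= nocc:
            raise ValueError("frozen core exceeds occupied space")
        core = np.arange(ncore)
        keep = np.arange(ncore, nso)
        e_core = h_so[core, core].sum() + 0.5 * np.einsum(
            "ijij->", g_anti[np.ix_(core, core, core, core)]
        )
        h_eff = h_so + np.einsum("pkqk->pq", g_anti[:, core][:, :, :, core])
        h_so = h_eff[np.ix_(keep, keep)]
        g_anti = g_anti[np.ix_(keep, keep, keep, keep)]
        fock = fock[np.ix_(keep, keep)]
        e_nuc = e_nuc + float(e_core)
        nso -= ncore
        occ = np.arange(nocc - ncore)
        vir = np.arange(nocc - ncore, nso)
    return SpinOrbitalIntegrals(
        n_spinorb=nso, h_so=h_so, g_anti=g_anti, fock=fock,
        occ=occ, vir=vir, e_nuc=float(e_nuc),
    )


# ---------------------------------------------------------------------------
# noninteracting composites
# ---------------------------------------------------------------------------

def direct_sum_composite(parts: list[IntegralSet]):
    """Direct sum H = H_A + H_B + ... of noninteracting fragments.

    All cross-fragment integrals are exactly zero.  Orbitals are reordered
    occupied-first (fragment order preserved within each group) so that the
    closed-shell reference of the composite is again the lowest orbitals.
    Returns ``(composite, index_maps)`` where ``index_maps[p][i]`` is the
    composite orbital housing orbital ``i`` of part ``p``.
    """
    if not parts:
        raise ValueError("need at least one part")
    n_tot = sum(p.n_orbitals for p in parts)
    nelec = sum(p.n_electrons for p in parts)
    # assign composite indices: occupied of each part first, then virtuals
    index_maps: list[np.ndarray] = []
    occ_slot, vir_slot = 0, nelec // 2
    for p in parts:
        no = p.n_electrons // 2
        m = np.empty(p.n_orbitals, dtype=int)
        m[:no] = np.arange(occ_slot, occ_slot + no)
        m[no:] = np.arange(vir_slot, vir_slot + p.n_orbitals - no)
        occ_slot += no
        vir_slot += p.n_orbitals - no
        index_maps.append(m)
    h = np.zeros((n_tot, n_tot))
    g = np.zeros((n_tot, n_tot, n_tot, n_tot))
    e_nuc = 0.0
    for p, m in zip(parts, index_maps):
        h[np.ix_(m, m)] = p.h
        g[np.ix_(m, m, m, m)] = p.g
        e_nuc += p.e_nuc
    comp = IntegralSet(n_orbitals=n_tot, n_electrons=nelec, h=h, g=g, e_nuc=e_nuc)
    return comp, index_maps


def composite_spinorbital_blocks(index_maps) -> list[np.ndarray]:
    """Spin-orbital index blocks of each fragment in a composite."""
    blocks = []
    for m in index_maps:
        so = np.empty(2 * len(m), dtype=int)
        so[0::2] = 2 * m
        so[1::2] = 2 * m + 1
        blocks.append(so)
    return blocks


# ---------------------------------------------------------------------------
# fixture catalog
# ---------------------------------------------------------------------------

def _fixture_dir() -> Path:
    return Path(resources.files("gccsd") / "fixtures")


def fixture_catalog() -> list[MolecularFixture]:
    """All FCIDUMP fixtures shipped with the package.

    The manifest records, per fixture, the geometry (XYZ, Å), basis tag and
    any generator parameters (H4 loop angle theta and radius rho, bond
    lengths, RHF orbital energies).
    """
    root = _fixture_dir()
    manifest = json.loads((root / "manifest.json").read_text())
    out = []
    for entry in manifest:
        p = root / entry["file"]
        if not p.exists():
            raise FileNotFoundError(f"packaged fixture missing: {p}")
        out.append(
            MolecularFixture(
                name=entry["name"],
                geometry=entry["geometry"],
                basis_tag=entry["basis"],
                integral_path=p,
                parameters=entry.get("parameters", {}),
            )
        )
    return out


def load_fixture(name: str) -> MolecularFixture:
    for fx in fixture_catalog():
        if fx.name == name:
            return fx
    raise KeyError(f"no fixture named {name!r}")
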