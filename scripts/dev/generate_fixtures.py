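"""Regenerate the packaged FCIDUMP fixtures (dev tool).

Runs the in-repo Gaussian-integral engine + RHF for every fixture molecule
and writes MO-basis FCIDUMP files plus a manifest (geometry, basis tag,
generator parameters, RHF orbital energies) into src/gccsd/fixtures/.

Fixture families
----------------
* H2 at its STO-3G equilibrium-ish bond length (STO-3G and 6-31G), plus three
  "monomer" copies at distinct bond lengths for the size-extensivity harness,
  and a pre-built noninteracting dimer composite.
* LiH/STO-3G bond scan, 1.0-4.0 Å.
* The H4 loop family: a square of side 1.0 Å hosts a singlet-singlet conical
  intersection in the (rectangular u, rhombic v) distortion plane at
  (0, v* = 0.18925 Å); we ship the square, the intersection center, a
  strongly distorted reference point, and 16 points on the circle of radius
  rho = 0.08 Å around the center.

Run from the repository root:  python scripts/dev/generate_fixtures.py
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from integral_engine import rhf  # noqa: E402

ROOT = Path(__file__).resolve().parents[2]
sys.path.insert(0, str(ROOT / "src"))
from gccsd.hamiltonian_io import IntegralSet, write_fcidump, direct_sum_composite  # noqa: E402

OUT = ROOT / "src" / "gccsd" / "fixtures"

H4_SIDE = 1.0       # Å, square side
H4_VSTAR = 0.18925  # Å, rhombic coordinate of the S0/S1 intersection
H4_RHO = 0.08       # Å, loop radius
H4_NPTS = 16


def h4_atoms(u, v, d=H4_SIDE):
    """Square H4 distorted by rectangular (u) and rhombic (v) coordinates."""
    return [
        ("H", ( d/2 + u/2 + v/2,  d/2 - u/2 + v/2, 0.0)),
        ("H", (-d/2 - u/2 + v/2,  d/2 - u/2 - v/2, 0.0)),
        ("H", (-d/2 - u/2 - v/2, -d/2 + u/2 - v/2, 0.0)),
        ("H", ( d/2 + u/2 - v/2, -d/2 + u/2 + v/2, 0.0)),
    ]


def xyz_text(atoms, comment=""):
    lines = [str(len(atoms)), comment]
    for sym, (x, y, z) in atoms:
        lines.append(f"{sym} {x: .10f} {y: .10f} {z: .10f}")
    return "\n".join(lines) + "\n"


def generate(name, atoms, basis, parameters):
    E, eps, C, h_mo, g_mo, e_nuc, nelec = rhf(atoms, basis)
    ints = IntegralSet(n_orbitals=h_mo.shape[0], n_electrons=nelec,
                       h=h_mo, g=g_mo, e_nuc=e_nuc)
    ints.validate(tol=1e-9)
    fname = f"{name}.fcidump"
    write_fcidump(ints, OUT / fname)
    print(f"  {name:<22s} E_RHF = {E:+.10f}")
    return {
        "name": name,
        "file": fname,
        "geometry": xyz_text(atoms, name),
        "basis": basis,
        "parameters": {**parameters,
                       "e_rhf": E,
                       "orbital_energies": [float(x) for x in eps]},
    }, ints


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = []

    print("H2 fixtures")
    entry, _ = generate("h2_sto3g", [("H", (0, 0, 0)), ("H", (0, 0, 0.7414))],
                        "sto-3g", {"bond_length": 0.7414})
    manifest.append(entry)
    entry, _ = generate("h2_631g", [("H", (0, 0, 0)), ("H", (0, 0, 0.7414))],
                        "6-31g", {"bond_length": 0.7414})
    manifest.append(entry)

    monomers = {}
    for tag, r in (("a", 0.80), ("b", 0.74), ("c", 0.70)):
        entry, ints = generate(f"h2_monomer_{tag}",
                               [("H", (0, 0, 0)), ("H", (0, 0, r))],
                               "sto-3g", {"bond_length": r, "monomer": tag.upper()})
        manifest.append(entry)
        monomers[tag] = (entry, ints)

    # pre-built noninteracting dimer of monomers A and B
    comp, _maps = direct_sum_composite([monomers["a"][1], monomers["b"][1]])
    write_fcidump(comp, OUT / "h2_dimer_ab.fcidump")
    manifest.append({
        "name": "h2_dimer_ab",
        "file": "h2_dimer_ab.fcidump",
        "geometry": xyz_text([("H", (0, 0, 0)), ("H", (0, 0, 0.80)),
                              ("H", (1000.0, 0, 0)), ("H", (1000.0, 0, 0.74))],
                             "noninteracting H2 dimer (A 0.80 Å, B 0.74 Å)"),
        "basis": "sto-3g",
        "parameters": {"monomers": ["h2_monomer_a", "h2_monomer_b"],
                       "composite": True},
    })
    print("  h2_dimer_ab            (direct sum)")

    print("LiH bond scan")
    for r in (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0):
        entry, _ = generate(f"lih_sto3g_r{r:.2f}",
                            [("Li", (0, 0, 0)), ("H", (0, 0, r))],
                            "sto-3g", {"bond_length": r, "scan_family": "lih_bond"})
        manifest.append(entry)

    print("H4 loop family")
    entry, _ = generate("h4_square", h4_atoms(0.0, 0.0), "sto-3g",
                        {"u": 0.0, "v": 0.0, "side": H4_SIDE, "family": "h4"})
    manifest.append(entry)
    entry, _ = generate("h4_center", h4_atoms(0.0, H4_VSTAR), "sto-3g",
                        {"u": 0.0, "v": H4_VSTAR, "side": H4_SIDE, "family": "h4",
                         "loop_center": True})
    manifest.append(entry)
    entry, _ = generate("h4_distorted", h4_atoms(0.0, H4_VSTAR + 0.30), "sto-3g",
                        {"u": 0.0, "v": H4_VSTAR + 0.30, "side": H4_SIDE,
                         "family": "h4", "distorted_reference": True})
    manifest.append(entry)
    for j in range(H4_NPTS):
        theta = 2.0 * np.pi * j / H4_NPTS
        u = H4_RHO * np.cos(theta)
        v = H4_VSTAR + H4_RHO * np.sin(theta)
        entry, _ = generate(f"h4_loop_{j:02d}", h4_atoms(u, v), "sto-3g",
                            {"u": u, "v": v, "side": H4_SIDE, "family": "h4_loop",
                             "theta": theta, "rho": H4_RHO, "index": j,
                             "n_points": H4_NPTS,
                             "center_u": 0.0, "center_v": H4_VSTAR})
        manifest.append(entry)

    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"wrote {len(manifest)} fixtures to {OUT}")


if __name__ == "__main__":
    main()
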