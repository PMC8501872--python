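"""Worked example on the SERCA crystal-structure pair (requires network).

Downloads the Ca2+-ATPase structures 2ZBD (E1P-ADP-2Ca2+ analog) and 2ZBE
(E2P analog) from the PDB and computes the rotation of the A-domain
relative to the P-domain between the two states.  The A-domain rotates by
roughly 90 degrees during this transition.

Usage::

    python scripts/crystal_example.py [--workdir scratch/crystal]

Domain boundaries (SERCA1a residue numbering):
  A-domain: residues 1-43 and 124-235
  P-domain: residues 330-359 and 605-737
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

from pathsage.domains import domain_rotation
from pathsage.structure import read_pdb

A_DOMAIN = "( resid 1-43 or resid 124-235 ) and name CA and chain A"
P_DOMAIN = "( resid 330-359 or resid 605-737 ) and name CA and chain A"


def fetch(pdb_id: str, workdir: Path) -> Path:
    path = workdir / f"{pdb_id}.pdb"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
        print(f"downloading {url}")
        urllib.request.urlretrieve(url, path)
    return path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, default=Path("scratch/crystal"))
    args = parser.parse_args()
    args.workdir.mkdir(parents=True, exist_ok=True)

    e1p = read_pdb(fetch("2ZBD", args.workdir))
    e2p = read_pdb(fetch("2ZBE", args.workdir))

    # keep only residues resolved in both structures
    def resids(s, sel):
        return {r for _, r, _ in s.select(sel).atom_keys()}

    def restrict(sel):
        common = sorted(resids(e1p, sel) & resids(e2p, sel))
        ranges = ",".join(str(r) for r in common)
        return f"chain A and name CA and resid {ranges}"

    rot = domain_rotation(e1p, e2p, ref_selection=restrict(P_DOMAIN),
                          mobile_selection=restrict(A_DOMAIN))
    print(f"A-domain rotation relative to the P-domain: {rot.angle:.1f} deg")
    if rot.axis_defined:
        print(f"axis: [{rot.axis[0]:+.3f} {rot.axis[1]:+.3f} {rot.axis[2]:+.3f}]")
        print(f"translation along axis: {rot.translation_along_axis:.2f} A")
    print(f"P-domain post-fit RMSD: {rot.rmsd_ref:.2f} A; "
          f"A-domain internal RMSD after its own fit: {rot.rmsd_mobile:.2f} A")


if __name__ == "__main__":
    main()
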