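"""Shared fixtures: fixture tables, a tiny hand-written PDB, and synthetic
structure builders."""
from __future__ import annotations

import pytest

from rotamer_audit.fixtures import default_fixtures
from rotamer_audit.synthetic_data import GeneratorConfig, build_peptide


@pytest.fixture(scope="session")
def fx():
    return default_fixtures()


def pdb_atom_line(serial, name, resname, chain, seq, x, y, z,
                  occ=1.0, b=20.0, element=None, altloc=" ", icode=" ",
                  record="ATOM  "):
    element = element or name[0]
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (f"{record}{serial:5d} {name_field}{altloc}{resname:>3s} "
            f"{chain}{seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{b:6.2f}          {element:>2s}")


@pytest.fixture(scope="session")
def five_residue_pdb_text():
    """Five GLY/ALA residues, one water, one altloc-B atom, resolution 1.8."""
    lines = ["REMARK   2 RESOLUTION.    1.80 ANGSTROMS."]
    serial = 1
    for i in range(5):
        resname = "ALA" if i % 2 else "GLY"
        x0 = 3.8 * i
        for j, name in enumerate(["N", "CA", "C", "O"]):
            lines.append(pdb_atom_line(serial, name, resname, "A", i + 1,
                                       x0 + j, 0.0, 0.0, occ=0.5 if
                                       (i == 0 and name == "O") else 1.0))
            serial += 1
        if resname == "ALA":
            lines.append(pdb_atom_line(serial, "CB", resname, "A", i + 1,
                                       x0 + 1.0, 1.5, 0.0))
            serial += 1
    # altloc B copy of the last CB: must be dropped on reading
    lines.append(pdb_atom_line(serial, "CB", "ALA", "A", 4,
                               99.0, 99.0, 99.0, altloc="B"))
    serial += 1
    lines.append(pdb_atom_line(serial, "O", "HOH", "A", 101,
                               50.0, 50.0, 50.0, record="HETATM"))
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def make_structure(fx):
    """Factory for synthetic structures with ground truth."""
    def _make(**kwargs):
        kwargs.setdefault("seed", 0)
        return build_peptide(GeneratorConfig(**kwargs), fx)
    return _make
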