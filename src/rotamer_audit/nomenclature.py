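"""IUPAC-IUB symmetric-branch corrections for ASP, GLU, PHE and TYR.

The two branches of a planar symmetric side-chain terminus (OD1/OD2,
OE1/OE2, CD1/CD2+CE1/CE2) are chemically equivalent, so the terminal
torsion is only defined up to 180°; the convention assigns branch 1 so the
torsion lies in (-90°, +90°]. Angles in [-180°, -90°] or (+90°, +180°] are
rotated by 180°. For PHE/TYR the fix can be applied to the PDB record
itself by swapping the CD1/CD2 and CE1/CE2 atom names.

The symmetric branch is the *terminal* torsion: ASP chi2, GLU chi3, PHE and
TYR chi2. A verbatim-indices switch instead applies the rule at ASP chi1 /
GLU chi2 for parity with descriptions that number the rule that way.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .fixtures import FixtureSet
from .geometry import ChiAngles, compute_chis, wrap_angle
from .structure_io import Residue, Structure

__all__ = [
    "SYMMETRIC_AAS",
    "symmetric_chi_index",
    "symmetric_chi_invalid",
    "correct_symmetric_chi",
    "audit_and_fix_ring_names",
    "nomenclature_census",
    "NomenclatureReport",
]

SYMMETRIC_AAS = ("ASP", "GLU", "PHE", "TYR")
_TERMINAL_INDEX = {"ASP": 2, "GLU": 3, "PHE": 2, "TYR": 2}
_VERBATIM_INDEX = {"ASP": 1, "GLU": 2, "PHE": 2, "TYR": 2}
_RING_SWAP = (("CD1", "CD2"), ("CE1", "CE2"))


def symmetric_chi_index(aa: str, verbatim_indices: bool = False) -> int:
    """1-based chi index carrying the symmetric-branch torsion."""
    table = _VERBATIM_INDEX if verbatim_indices else _TERMINAL_INDEX
    return table[aa]


def _needs_rotation(angle: float) -> bool:
    # closed at -90 (corrected), open at +90 (kept)
    return angle <= -90.0 or angle > 90.0


def symmetric_chi_invalid(aa: str, chis: ChiAngles,
                          verbatim_indices: bool = False) -> bool | None:
    """True when the symmetric torsion violates (-90, +90]; None if that
    torsion is undefined or the residue has no symmetric branch."""
    if aa not in SYMMETRIC_AAS:
        return None
    idx = symmetric_chi_index(aa, verbatim_indices) - 1
    if idx >= len(chis) or not chis.defined_mask[idx]:
        return None
    return _needs_rotation(chis.values[idx])


def correct_symmetric_chi(aa: str, chis: ChiAngles,
                          verbatim_indices: bool = False) -> ChiAngles:
    """Map the symmetric-branch torsion into (-90, +90] by a 180° rotation.

    Other angles are untouched; the operation is idempotent. Residues
    outside {ASP, GLU, PHE, TYR} are returned unchanged (no-op).
    """
    if symmetric_chi_invalid(aa, chis, verbatim_indices) is not True:
        return chis
    idx = symmetric_chi_index(aa, verbatim_indices) - 1
    values = list(chis.values)
    values[idx] = wrap_angle(values[idx] + 180.0)
    return ChiAngles(aa=chis.aa, values=values,
                     defined_mask=list(chis.defined_mask))


def audit_and_fix_ring_names(residue: Residue,
                             fixtures: FixtureSet) -> tuple[Residue, bool]:
    """Swap CD1<->CD2 and CE1<->CE2 names on a PHE/TYR residue whose raw
    chi2 violates (-90, +90]; coordinates are untouched. Idempotent: after
    one application the recomputed chi2 is valid, so a second application
    does nothing. Residues with an undefined chi2 (missing ring atoms) are
    returned unswapped."""
    if residue.aa not in ("PHE", "TYR"):
        return residue, False
    chis = compute_chis(residue, fixtures.chi_definitions[residue.aa])
    if symmetric_chi_invalid(residue.aa, chis) is not True:
        return residue, False
    atoms = {}
    rename = {}
    for a, b in _RING_SWAP:
        rename[a], rename[b] = b, a
    for name, atom in residue.atoms.items():
        new_name = rename.get(name, name)
        atoms[new_name] = replace(atom, name=new_name,
                                  position=atom.position.copy())
    fixed = Residue(aa=residue.aa, seq_id=residue.seq_id,
                    insertion_code=residue.insertion_code, atoms=atoms)
    return fixed, True


@dataclass
class NomenclatureReport:
    per_aa: pd.DataFrame          # aa, n, invalid, pct_invalid
    per_residue: pd.DataFrame     # structure, chain, seq_id, aa, valid


def nomenclature_census(structures: list[Structure], fixtures: FixtureSet,
                        verbatim_indices: bool = False) -> NomenclatureReport:
    """Percent of ASP/GLU/PHE/TYR residues whose raw symmetric torsion
    violates (-90, +90], per residue type."""
    rows = []
    for structure in structures:
        for chain_id, res in structure.iter_residues():
            if res.aa not in SYMMETRIC_AAS:
                continue
            chis = compute_chis(res, fixtures.chi_definitions[res.aa])
            invalid = symmetric_chi_invalid(res.aa, chis, verbatim_indices)
            if invalid is None:
                continue
            rows.append({"structure": structure.id, "chain": chain_id,
                         "seq_id": res.seq_id, "aa": res.aa,
                         "valid": not invalid})
    per_residue = pd.DataFrame(
        rows, columns=["structure", "chain", "seq_id", "aa", "valid"])
    per_aa_rows = []
    for aa in SYMMETRIC_AAS:
        sub = per_residue[per_residue["aa"] == aa]
        n = len(sub)
        invalid = int((~sub["valid"]).sum()) if n else 0
        per_aa_rows.append({
            "aa": aa, "n": n, "invalid": invalid,
            "pct_invalid": 100.0 * invalid / n if n else float("nan"),
        })
    return NomenclatureReport(per_aa=pd.DataFrame(per_aa_rows),
                              per_residue=per_residue)
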