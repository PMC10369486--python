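"""Torsion geometry: dihedral measurement, chi extraction and NeRF placement.

All angles are in degrees. Signed torsions follow the right-hand IUPAC
convention (cis = 0, trans = 180) and are reported in (-180, +180]; the
-180 boundary is normalized to +180 so trans has a single representative.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChiDefinition",
    "ChiAngles",
    "GeometryError",
    "wrap_angle",
    "dihedral",
    "compute_chis",
    "place_atom",
]

_COLLINEAR_TOL = 1e-10


class GeometryError(ValueError):
    """Degenerate geometry: collinear reference frame or coincident points."""


def wrap_angle(x: float) -> float:
    """Normalize an angle in degrees to the interval (-180, +180]."""
    y = (np.asarray(x) + 180.0) % 360.0 - 180.0
    y = np.where(y == -180.0, 180.0, y)
    return float(y) if np.ndim(x) == 0 else y


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, +180].

    Looking down the p2->p3 axis, a clockwise rotation of the far bond
    relative to the near bond is positive (IUPAC right-hand rule).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.dot(n1, n1) < _COLLINEAR_TOL or np.dot(n2, n2) < _COLLINEAR_TOL:
        raise GeometryError("undefined torsion: collinear atom triple")
    b2n = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2n)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length: float, bond_angle: float,
               torsion: float) -> np.ndarray:
    """Place atom d bonded to c using internal coordinates (NeRF).

    The result satisfies |c-d| = bond_length, angle(b, c, d) = bond_angle
    and dihedral(a, b, c, d) = torsion.
    """
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    if not 0.0 < bond_angle < 180.0:
        raise ValueError("bond_angle must lie in (0, 180)")
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    ab = b - a
    n = np.cross(ab, bc)
    if np.dot(n, n) < _COLLINEAR_TOL or np.dot(bc, bc) < _COLLINEAR_TOL:
        raise GeometryError("collinear reference frame")
    bc_hat = bc / np.linalg.norm(bc)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    ang = np.radians(180.0 - bond_angle)
    tor = np.radians(torsion)
    d_local = bond_length * np.array([
        np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    frame = np.column_stack([bc_hat, m_hat, n_hat])
    return c + frame @ d_local


@dataclass(frozen=True)
class ChiDefinition:
    """Ordered chi torsion definitions (atom-name quadruples) for one residue
    type. ALA and GLY carry empty lists; ARG stops at chi4 (the chi5 guanidino
    torsion is excluded from the analysis)."""

    aa: str
    chis: tuple[tuple[str, str, str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.chis)

    def atom_names(self) -> set[str]:
        """All side-chain/backbone atom names participating in any chi."""
        return {name for quad in self.chis for name in quad}


@dataclass
class ChiAngles:
    """Per-residue chi vector in degrees with a per-index defined mask."""

    aa: str
    values: list[float] = field(default_factory=list)
    defined_mask: list[bool] = field(default_factory=list)

    def all_defined(self) -> bool:
        return all(self.defined_mask)

    def __len__(self) -> int:
        return len(self.values)


def compute_chis(residue, definition: ChiDefinition) -> ChiAngles:
    """Measure the chi torsions of ``residue`` from its atom coordinates.

    Missing atoms yield NaN with ``defined_mask`` False at that index rather
    than an error, so incomplete residues can still be reported and filtered.
    """
    if residue.aa != definition.aa:
        raise ValueError(
            f"residue type {residue.aa} does not match definition "
            f"{definition.aa}")
    values: list[float] = []
    mask: list[bool] = []
    for quad in definition.chis:
        atoms = [residue.atoms.get(name) for name in quad]
        if any(atom is None for atom in atoms):
            values.append(float("nan"))
            mask.append(False)
        else:
            values.append(dihedral(*(atom.position for atom in atoms)))
            mask.append(True)
    return ChiAngles(aa=residue.aa, values=values, defined_mask=mask)
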