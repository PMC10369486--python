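"""Discretized rotamer classification.

A chi vector belongs to a canonical class when every angle lies within
±30° (circular) of that class's mode vector; anything outside every
canonical bin is an "off" rotamer. Generic modes are p = +65°, t = 180°
(wrapping across ±180) and m = -65°; named modes (e.g. ASN "m-20°") use
the same ±30° halfwidth. PRO is classified on chi1 alone into the ring
puckers Cγ Endo (+30°) / Cγ Exo (-30°), with the chi1 = 0 boundary
assigned to Exo.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import FixtureSet, RotamerClassDef
from .geometry import ChiAngles

__all__ = [
    "OFF_LABEL",
    "RotamerBinModel",
    "RotamerClass",
    "circular_distance",
    "mode_distance",
    "classify",
    "classify_pro",
    "rotamer_census",
    "assign_group",
    "GROUPS",
]

# Terminal torsions of planar symmetric branches are only defined modulo
# 180° (the two branch atoms are equivalent), so bin membership for these
# indices is judged with a 180°-periodic distance. 0-based chi index.
_SYMMETRIC_TERMINAL = {"ASP": 1, "GLU": 2, "PHE": 1, "TYR": 1}

OFF_LABEL = "off"

GROUPS = {
    "I": ("CYS", "SER", "THR", "VAL"),
    "II": ("ASN", "ASP", "HIS", "ILE", "LEU", "PHE", "PRO", "TRP", "TYR"),
    "III": ("GLN", "GLU", "MET"),
    "IV": ("LYS", "ARG"),
}
_GROUP_OF = {aa: g for g, aas in GROUPS.items() for aa in aas}


@dataclass(frozen=True)
class RotamerBinModel:
    halfwidth: float = 30.0
    p_mode: float = 65.0
    t_mode: float = 180.0
    m_mode: float = -65.0
    pro_endo: float = 30.0
    pro_exo: float = -30.0

    @classmethod
    def from_fixture(cls, bin_model: dict) -> "RotamerBinModel":
        g = bin_model["generic_modes"]
        pro = bin_model.get("pro_modes", {})
        return cls(halfwidth=bin_model["halfwidth"],
                   p_mode=g["p"], t_mode=g["t"], m_mode=g["m"],
                   pro_endo=pro.get("Cγ Endo", 30.0),
                   pro_exo=pro.get("Cγ Exo", -30.0))


@dataclass(frozen=True)
class RotamerClass:
    aa: str
    label: str

    @property
    def is_off(self) -> bool:
        return self.label == OFF_LABEL


def circular_distance(x, y):
    """Unsigned circular difference of two angles in degrees, in [0, 180].

    Computed as 180 - |(|x - y| mod 360) - 180|; symmetric, zero iff the
    angles are congruent mod 360.
    """
    d = np.abs(np.asarray(x, dtype=float) - np.asarray(y, dtype=float)) % 360.0
    out = 180.0 - np.abs(d - 180.0)
    return float(out) if out.ndim == 0 else out


def mode_distance(aa: str, chi_index: int, x, y):
    """Deviation of chi value ``x`` from mode ``y`` at 0-based ``chi_index``.

    Ordinary circular distance (period 360°), except at the terminal
    symmetric-branch torsion of ASP/GLU/PHE/TYR where the conformation is
    180°-periodic and the distance is folded accordingly (range [0, 90]).
    """
    if _SYMMETRIC_TERMINAL.get(aa) == chi_index:
        d = np.abs(np.asarray(x, dtype=float)
                   - np.asarray(y, dtype=float)) % 180.0
        out = 90.0 - np.abs(d - 90.0)
        return float(out) if out.ndim == 0 else out
    return circular_distance(x, y)


def classify(aa: str, chis: ChiAngles, fixtures: FixtureSet,
             bins: RotamerBinModel | None = None) -> RotamerClass | None:
    """Assign the canonical class of a fully defined chi vector, or "off".

    A class qualifies when every per-angle circular deviation from its mode
    is <= the bin halfwidth; among qualifying classes the one with the
    smallest maximum deviation wins (ties: smallest deviation sum, then
    inventory order). Returns None (classification refused) when any chi is
    undefined, and raises for residues without chi angles.
    """
    if bins is None:
        bins = RotamerBinModel.from_fixture(fixtures.bin_model)
    if aa == "PRO":
        return classify_pro(chis, bins)
    classes = fixtures.inventory.get(aa)
    if not classes:
        raise ValueError(f"{aa} has no rotamer classes (no chi angles)")
    if len(chis) == 0 or not chis.all_defined():
        return None
    values = np.asarray(chis.values, dtype=float)
    best: tuple[float, float, int] | None = None
    best_class: RotamerClassDef | None = None
    for order, cdef in enumerate(classes):
        dev = np.array([mode_distance(aa, i, values[i], cdef.modes[i])
                        for i in range(len(values))])
        if np.all(dev <= bins.halfwidth):
            key = (float(np.max(dev)), float(np.sum(dev)), order)
            if best is None or key < best:
                best, best_class = key, cdef
    if best_class is None:
        return RotamerClass(aa, OFF_LABEL)
    return RotamerClass(aa, best_class.label)


def classify_pro(chis: ChiAngles,
                 bins: RotamerBinModel | None = None) -> RotamerClass | None:
    """PRO ring pucker from chi1: Endo within 30° of +30°, Exo within 30°
    of -30°, boundary chi1 = 0 assigned Exo, otherwise off."""
    if bins is None:
        bins = RotamerBinModel()
    if len(chis) == 0 or not chis.defined_mask[0]:
        return None
    chi1 = chis.values[0]
    d_endo = circular_distance(chi1, bins.pro_endo)
    d_exo = circular_distance(chi1, bins.pro_exo)
    endo_ok = d_endo <= bins.halfwidth
    exo_ok = d_exo <= bins.halfwidth
    if endo_ok and (not exo_ok or d_endo < d_exo):
        return RotamerClass("PRO", "Cγ Endo")
    if exo_ok:
        return RotamerClass("PRO", "Cγ Exo")
    return RotamerClass("PRO", OFF_LABEL)


def assign_group(aa: str) -> str:
    """Side-chain-length group: I (1 chi) .. IV (4 chis); ALA/GLY -> none."""
    if aa in ("ALA", "GLY"):
        return "none"
    try:
        return _GROUP_OF[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid code {aa!r}") from None


def rotamer_census(records) -> pd.DataFrame:
    """Per-residue-type census of canonical vs off rotamers.

    ``records`` is an iterable of objects with ``aa`` and ``rotamer``
    attributes (rotamer None for ALA/GLY or refused classifications).
    ALA/GLY contribute to the totals only. Returns one row per residue type
    plus a TOTAL row; percentages are over classified residues.
    """
    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        aa, rot = rec.aa, rec.rotamer
        row = counts.setdefault(aa, {"canonical": 0, "off": 0, "all": 0})
        row["all"] += 1
        if rot is not None:
            if rot.is_off:
                row["off"] += 1
            else:
                row["canonical"] += 1
    if not counts:
        return pd.DataFrame(
            columns=["aa", "canonical", "off", "all",
                     "pct_canonical", "pct_off"])
    rows = []
    for aa in sorted(counts):
        c = counts[aa]
        classified = c["canonical"] + c["off"]
        rows.append({
            "aa": aa, "canonical": c["canonical"], "off": c["off"],
            "all": c["all"],
            "pct_canonical": (100.0 * c["canonical"] / classified
                              if classified else np.nan),
            "pct_off": (100.0 * c["off"] / classified
                        if classified else np.nan),
        })
    total_can = sum(r["canonical"] for r in rows)
    total_off = sum(r["off"] for r in rows)
    classified = total_can + total_off
    rows.append({
        "aa": "TOTAL", "canonical": total_can, "off": total_off,
        "all": sum(r["all"] for r in rows),
        "pct_canonical": (100.0 * total_can / classified
                          if classified else np.nan),
        "pct_off": (100.0 * total_off / classified
                    if classified else np.nan),
    })
    return pd.DataFrame(rows)
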