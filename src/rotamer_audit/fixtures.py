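"""Versioned data tables: chi definitions, rotamer inventory, bin model,
vdW radii and side-chain construction templates.

Rotamer class labels concatenate one symbol per chi (p/t/m for the generic
+65/180/-65 modes) with a trailing number when the final chi sits at a named
mode, e.g. LEU "mt", ASN "m-20°", ARG "mtm105°". PRO uses the ring-pucker
labels "Cγ Endo"/"Cγ Exo" classified on chi1 alone.
"""
from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .geometry import ChiDefinition

__all__ = [
    "FixtureError",
    "RotamerClassDef",
    "TemplateAtom",
    "FixtureSet",
    "parse_label",
    "load_fixtures",
    "default_fixtures",
]

_GENERIC = {"m": -65.0, "p": 65.0, "t": 180.0}
_PRO_MODES = {"Cγ Endo": 30.0, "Cγ Exo": -30.0}
_LABEL_RE = re.compile(r"([mpt]+)(-?\d+)?°?")


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class RotamerClassDef:
    aa: str
    label: str
    modes: tuple[float, ...]


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    refs: tuple[str, str, str]
    length: float
    angle: float
    tor_type: str           # const | chi | chioff | prochi2
    tor_value: float | tuple[int, float]


@dataclass
class FixtureSet:
    chi_definitions: dict[str, ChiDefinition]
    inventory: dict[str, list[RotamerClassDef]]
    bin_model: dict
    radii: dict[str, float]
    templates: dict[str, list[TemplateAtom]]
    hashes: dict[str, str]

    def n_chi(self, aa: str) -> int:
        return len(self.chi_definitions[aa])

    def labels(self, aa: str) -> list[str]:
        return [c.label for c in self.inventory.get(aa, [])]


def parse_label(aa: str, label: str) -> tuple[float, ...]:
    """Expand a class label into its per-chi mode vector (degrees)."""
    if aa == "PRO":
        if label not in _PRO_MODES:
            raise FixtureError(f"unknown PRO pucker label {label!r}")
        return (_PRO_MODES[label],)
    m = _LABEL_RE.fullmatch(label)
    if m is None:
        raise FixtureError(f"unparseable rotamer label {label!r} for {aa}")
    modes = [_GENERIC[s] for s in m.group(1)]
    if m.group(2) is not None:
        modes.append(float(m.group(2)))
    return tuple(modes)


def _read_tsv(path: Path) -> tuple[list[str], list[list[str]]]:
    header: list[str] = []
    rows: list[list[str]] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header:
            header = fields
        else:
            rows.append(fields)
    return header, rows


def load_fixtures(directory: str | Path | None = None) -> FixtureSet:
    """Load and cross-validate the fixture tables.

    Validation: every inventory label must parse into a mode vector that
    matches both the stored mode columns and the chi arity of its residue
    type (PRO: one mode); template torsion rules must reference existing
    chi indices.
    """
    if directory is None:
        directory = resources.files("rotamer_audit") / "data"
    directory = Path(str(directory))

    hashes = {}
    for name in ("chi_definitions.tsv", "rotamer_inventory.tsv",
                 "bin_model.json", "radii.tsv", "sidechain_templates.tsv"):
        path = directory / name
        if not path.exists():
            raise FixtureError(f"missing fixture file {name}")
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    # chi definitions
    _, rows = _read_tsv(directory / "chi_definitions.tsv")
    quads: dict[str, dict[int, tuple[str, ...]]] = {}
    for aa, idx, *atoms in rows:
        quads.setdefault(aa, {})[int(idx)] = tuple(atoms)
    chi_definitions = {"ALA": ChiDefinition("ALA"), "GLY": ChiDefinition("GLY")}
    for aa, by_idx in quads.items():
        if sorted(by_idx) != list(range(1, len(by_idx) + 1)):
            raise FixtureError(f"non-contiguous chi indices for {aa}")
        chi_definitions[aa] = ChiDefinition(
            aa, tuple(by_idx[i] for i in sorted(by_idx)))
    if len(chi_definitions.get("ARG", ())) != 4:
        raise FixtureError("ARG must define exactly chi1..chi4 (chi5 excluded)")

    # inventory
    _, rows = _read_tsv(directory / "rotamer_inventory.tsv")
    inventory: dict[str, list[RotamerClassDef]] = {}
    for aa, label, *mode_cols in rows:
        if aa not in chi_definitions:
            raise FixtureError(f"inventory row for unknown residue {aa!r}")
        stored = tuple(float(v) for v in mode_cols if v != "")
        parsed = parse_label(aa, label)
        if parsed != stored:
            raise FixtureError(
                f"inventory row {aa} {label!r}: stored modes {stored} "
                f"disagree with label parse {parsed}")
        expected = 1 if aa == "PRO" else len(chi_definitions[aa])
        if len(stored) != expected:
            raise FixtureError(
                f"inventory row {aa} {label!r}: {len(stored)} modes for a "
                f"{expected}-chi residue")
        inventory.setdefault(aa, []).append(RotamerClassDef(aa, label, stored))

    bin_model = json.loads((directory / "bin_model.json").read_text("utf-8"))

    _, rows = _read_tsv(directory / "radii.tsv")
    radii = {el: float(r) for el, r in rows}

    _, rows = _read_tsv(directory / "sidechain_templates.tsv")
    templates: dict[str, list[TemplateAtom]] = {}
    for aa, atom, r1, r2, r3, length, angle, ttype, tval in rows:
        if aa not in chi_definitions:
            raise FixtureError(f"template row for unknown residue {aa!r}")
        if ttype in ("const", "prochi2"):
            value: float | tuple[int, float] = float(tval)
        elif ttype == "chi":
            value = (int(tval), 0.0)
        elif ttype == "chioff":
            m = re.fullmatch(r"(\d)([+-]\d+)", tval)
            if m is None:
                raise FixtureError(f"bad chioff value {tval!r} ({aa} {atom})")
            value = (int(m.group(1)), float(m.group(2)))
        else:
            raise FixtureError(f"unknown torsion type {ttype!r} ({aa} {atom})")
        if ttype in ("chi", "chioff"):
            if value[0] > max(1, len(chi_definitions[aa])):
                raise FixtureError(
                    f"template {aa} {atom} references chi{value[0]} but "
                    f"{aa} has {len(chi_definitions[aa])} chi angles")
        templates.setdefault(aa, []).append(TemplateAtom(
            atom, (r1, r2, r3), float(length), float(angle), ttype, value))

    return FixtureSet(chi_definitions, inventory, bin_model, radii,
                      templates, hashes)


_DEFAULT: FixtureSet | None = None


def default_fixtures() -> FixtureSet:
    """Cached fixtures shipped with the package."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_fixtures()
    return _DEFAULT
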