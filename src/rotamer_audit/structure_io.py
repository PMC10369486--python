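"""PDB structure model, reading/writing and quality filters.

Parsing is delegated to gemmi; the internal model keeps exactly the fields
the audit needs (names verbatim, coordinates, occupancy, B-factor, altloc,
resolution). Only ATOM records of the 20 canonical residues are retained:
crystallized water, ions and ligands (HETATM) are excluded from the
analysis. Alternate locations other than blank/'A' are dropped (the
occupancy == 1 residue filter makes them irrelevant downstream). Only the
first MODEL is read.
"""
from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "FilterReason",
    "ResidueFlag",
    "FilterReport",
    "PDBParseError",
    "AA3",
    "read_pdb",
    "write_pdb",
    "filter_structure",
    "filter_residues",
]

AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


class PDBParseError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy outside [0, 1] for atom {self.name}")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")


@dataclass
class Residue:
    aa: str
    seq_id: int
    insertion_code: str = ""
    atoms: dict[str, Atom] = field(default_factory=dict)

    def __post_init__(self):
        if self.aa not in AA3:
            raise ValueError(f"non-canonical residue type {self.aa!r}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)


@dataclass
class Structure:
    id: str
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    resolution: float | None = None

    def n_residues(self) -> int:
        return sum(len(res) for _, res in self.chains)

    def iter_residues(self):
        for chain_id, residues in self.chains:
            for res in residues:
                yield chain_id, res


class FilterReason(str, enum.Enum):
    KEPT = "kept"
    MULTI_CHAIN = "multi_chain"
    LOW_RESOLUTION = "low_resolution"


class ResidueFlag(str, enum.Enum):
    RETAINED = "retained"
    BAD_BFACTOR = "bad_bfactor"
    BAD_OCCUPANCY = "bad_occupancy"
    MISSING_ATOMS = "missing_atoms"


@dataclass
class FilterReport:
    structure_id: str
    structure_kept: bool
    reason: FilterReason
    residues_total: int
    residues_retained: int
    per_residue_flags: dict[tuple[str, int, str], ResidueFlag] = field(
        default_factory=dict)


def _precheck_atom_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(
                    f"line {lineno}: truncated ATOM/HETATM record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: unparseable coordinates") from None


def read_pdb(source) -> Structure:
    """Read a PDB file (path, text or binary stream) into a Structure."""
    if hasattr(source, "read"):
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode("ascii", errors="replace")
        name = getattr(source, "name", "stream")
    else:
        with open(source, "rb") as fh:
            text = fh.read().decode("ascii", errors="replace")
        name = str(source)
    if not text.strip():
        raise PDBParseError(f"{name}: empty PDB input")
    _precheck_atom_lines(text)

    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    if len(st) == 0:
        raise PDBParseError(f"{name}: no models in PDB input")
    resolution = st.resolution if st.resolution > 0 else None
    sid = st.name if st.name else name

    structure = Structure(id=sid, resolution=resolution)
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.het_flag != "A" or res.name not in AA3:
                continue
            atoms: dict[str, Atom] = {}
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                if atom.name in atoms:
                    continue
                atoms[atom.name] = Atom(
                    name=atom.name,
                    element=atom.element.name.upper(),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    b_factor=max(atom.b_iso, 0.0),
                    alt_loc="" if atom.altloc in ("", "\0") else atom.altloc,
                )
            residues.append(Residue(
                aa=res.name,
                seq_id=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                atoms=atoms,
            ))
        if residues:
            residues.sort(key=lambda r: (r.seq_id, r.insertion_code))
            structure.chains.append((chain.name, residues))
    return structure


def write_pdb(structure: Structure, sink) -> None:
    """Write fixed-column ATOM records (plus REMARK 2 when resolution is
    known). Atom names are emitted verbatim so that deliberate or erroneous
    CD1/CD2 swaps survive a round trip."""
    lines: list[str] = []
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for chain_id, residues in structure.chains:
        for res in residues:
            for atom in res.atoms.values():
                if len(atom.name) > 4:
                    raise ValueError(
                        f"atom name {atom.name!r} exceeds 4 characters")
                # column alignment: names of atoms with 1-letter elements
                # start in column 14 unless 4 characters long
                if len(atom.name) < 4 and len(atom.element) == 1:
                    name_field = f" {atom.name:<3s}"
                else:
                    name_field = f"{atom.name:<4s}"
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{atom.alt_loc or ' '}"
                    f"{res.aa:>3s} {chain_id:1s}{res.seq_id:4d}"
                    f"{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.b_factor:6.2f}          "
                    f"{atom.element:>2s}")
                serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1].aa:>3s} "
                     f"{chain_id:1s}{residues[-1].seq_id:4d}")
        serial += 1
    lines.append("END")
    payload = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        if isinstance(sink, io.TextIOBase):
            sink.write(payload)
        else:
            sink.write(payload.encode("ascii"))
    else:
        with open(sink, "w") as fh:
            fh.write(payload)


def filter_structure(structure: Structure, max_resolution: float = 2.0,
                     require_single_chain: bool = True,
                     require_resolution: bool = True) -> FilterReport:
    """Dataset-level filter: single chain and resolution strictly below
    ``max_resolution``. Structures without recorded resolution fail the
    resolution criterion unless ``require_resolution`` is disabled (synthetic
    inputs carry an explicit resolution so they pass by default)."""
    total = structure.n_residues()
    kept = True
    reason = FilterReason.KEPT
    if require_single_chain and len(structure.chains) > 1:
        kept, reason = False, FilterReason.MULTI_CHAIN
    elif require_resolution and (structure.resolution is None
                                 or structure.resolution >= max_resolution):
        kept, reason = False, FilterReason.LOW_RESOLUTION
    return FilterReport(
        structure_id=structure.id,
        structure_kept=kept,
        reason=reason,
        residues_total=total,
        residues_retained=total if kept else 0,
    )


def filter_residues(structure: Structure,
                    torsion_atom_sets: dict[str, set[str]],
                    max_bfactor: float = 40.0,
                    required_occupancy: float = 1.0) -> FilterReport:
    """Residue-level quality filter.

    A residue is retained iff every atom participating in its torsion
    calculations (its chi atoms plus the backbone torsion atoms N, CA, C)
    is present, has B-factor <= ``max_bfactor`` and occupancy >=
    ``required_occupancy``. A missing required atom wins over metadata
    problems when assigning the flag.
    """
    flags: dict[tuple[str, int, str], ResidueFlag] = {}
    retained = 0
    for chain_id, res in structure.iter_residues():
        required = {"N", "CA", "C"} | set(torsion_atom_sets.get(res.aa, ()))
        key = (chain_id, res.seq_id, res.insertion_code)
        missing = [name for name in required if name not in res.atoms]
        if missing:
            flags[key] = ResidueFlag.MISSING_ATOMS
            continue
        atoms = [res.atoms[name] for name in required]
        if any(a.b_factor > max_bfactor for a in atoms):
            flags[key] = ResidueFlag.BAD_BFACTOR
        elif any(a.occupancy < required_occupancy for a in atoms):
            flags[key] = ResidueFlag.BAD_OCCUPANCY
        else:
            flags[key] = ResidueFlag.RETAINED
            retained += 1
    return FilterReport(
        structure_id=structure.id,
        structure_kept=True,
        reason=FilterReason.KEPT,
        residues_total=len(flags),
        residues_retained=retained,
        per_residue_flags=flags,
    )
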