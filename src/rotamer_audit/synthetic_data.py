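"""Synthetic single-chain all-atom structures with known rotamer ground
truth, plus a mock side-chain predictor with a controlled confusion process.

The builder places backbone and side-chain heavy atoms by sequential
internal-coordinate (NeRF) construction using ideal bond lengths/angles.
True rotamer classes are sampled from the canonical inventory (chi angles
uniform within ±15° of the class mode); "off" residues get exactly one chi
drawn uniformly from the complement of every canonical bin at that index.
No steric relaxation is performed — the downstream analysis is purely
geometric, and determinism is worth more than physical realism here.

The mock predictor stands in for external packing programs: it keeps the
backbone, and with probability eps = logistic(logit(eps0) + acc_slope*ACC)
rebuilds a residue's side chain at a different (uniformly chosen) canonical
class, recording every action in the truth ledger.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accessibility import shrake_rupley_acc
from .fixtures import FixtureSet, default_fixtures
from .geometry import place_atom, wrap_angle
from .rotamer_model import OFF_LABEL, RotamerBinModel, mode_distance
from .structure_io import Atom, Residue, Structure, write_pdb

__all__ = [
    "GeneratorConfig",
    "build_peptide",
    "mock_predict",
    "make_paired_fixture",
]

# ideal backbone internal coordinates
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0

_BACKBONE_PRESETS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
    "coil": (-80.0, 150.0),
}

_CHI_AAS = ("ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE", "LEU",
            "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL")


@dataclass
class GeneratorConfig:
    n_residues: int = 100
    seed: int = 0
    aa_weights: dict[str, float] | None = None   # default: uniform, 20 types
    backbone: str = "mixed"                      # helix | strand | coil | mixed
    off_fraction: float = 0.0
    class_weights: dict[str, dict[str, float]] | None = None
    chi_jitter: float = 15.0                     # degrees around the mode
    b_factor_mean: float = 20.0
    b_factor_sd: float = 5.0
    bfactor_corruption: float = 0.0              # P(residue gets one B=60 atom)
    occupancy_corruption: float = 0.0            # P(residue gets one occ=0.5)
    resolution: float = 1.5
    structure_id: str = ""

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.backbone not in (*_BACKBONE_PRESETS, "mixed"):
            raise ValueError(f"unknown backbone preset {self.backbone!r}")
        for rate in (self.off_fraction, self.bfactor_corruption,
                     self.occupancy_corruption):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _sample_sequence(config: GeneratorConfig, rng) -> list[str]:
    if config.aa_weights:
        aas = sorted(config.aa_weights)
        w = np.array([config.aa_weights[a] for a in aas], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("aa weights must be non-negative, normalizable")
        p = w / w.sum()
    else:
        from .structure_io import AA3
        aas, p = list(AA3), None
    return [str(a) for a in rng.choice(aas, size=config.n_residues, p=p)]


def _off_complement_sample(aa: str, chi_index: int, fixtures: FixtureSet,
                           halfwidth: float, rng) -> float | None:
    """Uniform angle more than ``halfwidth`` away (bin metric) from every
    class mode at ``chi_index``; None when the complement is empty."""
    grid = np.arange(-179.9, 180.1, 0.2)
    ok = np.ones_like(grid, dtype=bool)
    for cdef in fixtures.inventory[aa]:
        if chi_index < len(cdef.modes):
            ok &= mode_distance(aa, chi_index, grid,
                                cdef.modes[chi_index]) > halfwidth
    if not ok.any():
        return None
    return float(rng.choice(grid[ok]) + rng.uniform(-0.1, 0.1))


def _sample_chis(aa: str, label: str, fixtures: FixtureSet,
                 bins: RotamerBinModel, jitter: float, rng) -> list[float]:
    """Chi values realizing ``label`` (canonical: uniform within ±jitter of
    the mode vector; off: one index in the complement of all bins)."""
    classes = fixtures.inventory[aa]
    if label != OFF_LABEL:
        modes = next(c.modes for c in classes if c.label == label)
        return [wrap_angle(m + rng.uniform(-jitter, jitter)) for m in modes]
    n_chi = len(classes[0].modes)
    order = list(rng.permutation(n_chi))
    for idx in order:
        value = _off_complement_sample(aa, idx, fixtures, bins.halfwidth, rng)
        if value is not None:
            base = classes[rng.integers(len(classes))]
            chis = [wrap_angle(m + rng.uniform(-jitter, jitter))
                    for m in base.modes]
            chis[idx] = value
            return chis
    raise RuntimeError(f"no off-bin complement available for {aa}")


def _build_sidechain(res: Residue, aa: str, chis: list[float],
                     fixtures: FixtureSet, b_factors, rng) -> None:
    """Attach side-chain heavy atoms to a residue that already has N/CA/C."""
    for i, tmpl in enumerate(fixtures.templates.get(aa, ())):
        refs = [res.atoms[r].position for r in tmpl.refs]
        if tmpl.tor_type == "const":
            torsion = float(tmpl.tor_value)
        elif tmpl.tor_type == "prochi2":
            torsion = float(tmpl.tor_value) * chis[0]
        else:
            k, off = tmpl.tor_value
            torsion = wrap_angle(chis[k - 1] + off)
        pos = place_atom(*refs, tmpl.length, tmpl.angle, torsion)
        element = tmpl.name[0] if tmpl.name[0] in "CNOS" else "C"
        res.atoms[tmpl.name] = Atom(name=tmpl.name, element=element,
                                    position=pos, occupancy=1.0,
                                    b_factor=b_factors(rng))


def build_peptide(config: GeneratorConfig,
                  fixtures: FixtureSet | None = None
                  ) -> tuple[Structure, pd.DataFrame]:
    """Build a single-chain peptide with known per-residue rotamer truth.

    Returns the structure and a truth ledger (one row per residue: true
    class label, prescribed chi values, backbone preset, any metadata
    corruption applied).
    """
    if fixtures is None:
        fixtures = default_fixtures()
    bins = RotamerBinModel.from_fixture(fixtures.bin_model)
    rng = np.random.default_rng(config.seed)
    sequence = _sample_sequence(config, rng)

    def bf(r) -> float:
        return float(np.clip(r.normal(config.b_factor_mean,
                                      config.b_factor_sd), 1.0, 39.9))

    residues: list[Residue] = []
    ledger_rows = []
    prev = None  # (N, CA, C) of previous residue
    for i, aa in enumerate(sequence):
        preset = (config.backbone if config.backbone != "mixed"
                  else str(rng.choice(["helix", "strand", "coil"],
                                      p=[0.45, 0.35, 0.20])))
        phi, psi = _BACKBONE_PRESETS[preset]
        if prev is None:
            n = np.zeros(3)
            ca = np.array([_N_CA, 0.0, 0.0])
            ang = math.radians(180.0 - _ANG_N_CA_C)
            c = ca + _CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
        else:
            pn, pca, pc = prev
            n = place_atom(pn, pca, pc, _C_N, _ANG_CA_C_N, prev_psi)
            ca = place_atom(pca, pc, n, _N_CA, _ANG_C_N_CA, _OMEGA)
            c = place_atom(pc, n, ca, _CA_C, _ANG_N_CA_C, phi)
        o = place_atom(n, ca, c, _C_O, _ANG_CA_C_O, wrap_angle(psi + 180.0))
        res = Residue(aa=aa, seq_id=i + 1, atoms={})
        for name, pos in (("N", n), ("CA", ca), ("C", c), ("O", o)):
            element = name[0]
            res.atoms[name] = Atom(name=name, element=element, position=pos,
                                   occupancy=1.0, b_factor=bf(rng))

        if aa in _CHI_AAS:
            if config.class_weights and aa in config.class_weights:
                labels = sorted(config.class_weights[aa])
                w = np.array([config.class_weights[aa][l] for l in labels])
                label = str(rng.choice(labels, p=w / w.sum()))
            elif rng.uniform() < config.off_fraction:
                label = OFF_LABEL
            else:
                label = str(rng.choice(fixtures.labels(aa)))
            chis = _sample_chis(aa, label, fixtures, bins,
                                config.chi_jitter, rng)
        else:
            label, chis = "", []
            _build_sidechain(res, aa, chis, fixtures, bf, rng)  # ALA CB
        if aa in _CHI_AAS:
            _build_sidechain(res, aa, chis, fixtures, bf, rng)

        corrupted = ""
        sidechain_names = [t.name for t in fixtures.templates.get(aa, ())]
        if sidechain_names and rng.uniform() < config.bfactor_corruption:
            victim = str(rng.choice(sidechain_names))
            res.atoms[victim].b_factor = 60.0
            corrupted = "bfactor"
        elif sidechain_names and rng.uniform() < config.occupancy_corruption:
            victim = str(rng.choice(sidechain_names))
            res.atoms[victim].occupancy = 0.5
            corrupted = "occupancy"

        padded = list(chis) + [float("nan")] * (4 - len(chis))
        ledger_rows.append({
            "chain": "A", "seq_id": i + 1, "aa": aa, "true_label": label,
            "chi1": padded[0], "chi2": padded[1], "chi3": padded[2],
            "chi4": padded[3], "backbone": preset, "corrupted": corrupted,
        })
        residues.append(res)
        prev, prev_psi = (n, ca, c), psi

    sid = config.structure_id or f"synth-{config.seed}"
    structure = Structure(id=sid, chains=[("A", residues)],
                          resolution=config.resolution)
    return structure, pd.DataFrame(ledger_rows)


def _logistic_rate(epsilon0: float, acc_slope: float, acc: float) -> float:
    if epsilon0 <= 0.0:
        return 0.0
    if epsilon0 >= 1.0:
        return 1.0
    z = math.log(epsilon0 / (1.0 - epsilon0)) + acc_slope * acc
    return 1.0 / (1.0 + math.exp(-z))


def mock_predict(structure: Structure, ledger: pd.DataFrame,
                 epsilon0: float, acc_slope: float = 0.0, seed: int = 0,
                 fixtures: FixtureSet | None = None,
                 acc_profile=None) -> tuple[Structure, pd.DataFrame]:
    """Repack side chains with a known confusion process.

    Per chi-bearing residue, with probability eps (constant ``epsilon0`` or
    logistic in ACC when ``acc_slope`` is nonzero) the side chain is rebuilt
    at a canonical class different from the true one; otherwise it is kept
    verbatim. The backbone is never touched. Returns a new structure and
    the ledger extended with predicted_label/action columns.
    """
    if fixtures is None:
        fixtures = default_fixtures()
    bins = RotamerBinModel.from_fixture(fixtures.bin_model)
    rng = np.random.default_rng(seed)
    acc = acc_profile
    if acc is None and acc_slope != 0.0:
        acc = shrake_rupley_acc(structure, fixtures=fixtures)

    ledger = ledger.copy()
    ledger["predicted_label"] = ""
    ledger["action"] = ""
    by_key = {(row.chain, row.seq_id): idx
              for idx, row in enumerate(ledger.itertuples())}

    new_chains = []
    for chain_id, residues in structure.chains:
        new_residues = []
        for res in residues:
            new_res = Residue(
                aa=res.aa, seq_id=res.seq_id,
                insertion_code=res.insertion_code,
                atoms={name: Atom(name=a.name, element=a.element,
                                  position=a.position.copy(),
                                  occupancy=a.occupancy, b_factor=a.b_factor,
                                  alt_loc=a.alt_loc)
                       for name, a in res.atoms.items()})
            idx = by_key[(chain_id, res.seq_id)]
            true_label = ledger.at[idx, "true_label"]
            if res.aa not in _CHI_AAS:
                ledger.at[idx, "action"] = "n/a"
                new_residues.append(new_res)
                continue
            acc_value = acc.get((chain_id, res.seq_id,
                                 res.insertion_code)) if acc else 0.0
            eps = _logistic_rate(epsilon0, acc_slope, acc_value)
            if rng.uniform() < eps:
                alternatives = [l for l in fixtures.labels(res.aa)
                                if l != true_label]
                if alternatives:
                    target = str(rng.choice(alternatives))
                else:
                    target = OFF_LABEL  # forced off: single-class inventory
                chis = _sample_chis(res.aa, target, fixtures, bins,
                                    15.0, rng)
                _rebuild_sidechain(new_res, res.aa, chis, fixtures)
                ledger.at[idx, "predicted_label"] = target
                ledger.at[idx, "action"] = f"confused-to:{target}"
            else:
                ledger.at[idx, "predicted_label"] = true_label
                ledger.at[idx, "action"] = "kept"
            new_residues.append(new_res)
        new_chains.append((chain_id, new_residues))
    # same id as the original: predictions share the backbone and are
    # paired with their source structure residue-by-residue
    predicted = Structure(id=structure.id, chains=new_chains,
                          resolution=structure.resolution)
    return predicted, ledger


def _rebuild_sidechain(res: Residue, aa: str, chis: list[float],
                       fixtures: FixtureSet) -> None:
    """Recompute side-chain atom positions in place, keeping metadata."""
    for tmpl in fixtures.templates.get(aa, ()):
        refs = [res.atoms[r].position for r in tmpl.refs]
        if tmpl.tor_type == "const":
            torsion = float(tmpl.tor_value)
        elif tmpl.tor_type == "prochi2":
            torsion = float(tmpl.tor_value) * chis[0]
        else:
            k, off = tmpl.tor_value
            torsion = wrap_angle(chis[k - 1] + off)
        pos = place_atom(*refs, tmpl.length, tmpl.angle, torsion)
        old = res.atoms.get(tmpl.name)
        res.atoms[tmpl.name] = Atom(
            name=tmpl.name,
            element=old.element if old else
            (tmpl.name[0] if tmpl.name[0] in "CNOS" else "C"),
            position=pos,
            occupancy=old.occupancy if old else 1.0,
            b_factor=old.b_factor if old else 20.0)


def make_paired_fixture(config: GeneratorConfig, epsilon0: float,
                        acc_slope: float = 0.0, predictor_seed: int = 1,
                        outdir=None, fixtures: FixtureSet | None = None):
    """Generate an (original, predicted, truth) triple; optionally write
    original.pdb / predicted.pdb / truth.tsv under ``outdir``."""
    if fixtures is None:
        fixtures = default_fixtures()
    original, ledger = build_peptide(config, fixtures)
    predicted, ledger = mock_predict(original, ledger, epsilon0, acc_slope,
                                     predictor_seed, fixtures)
    if outdir is not None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pdb(original, outdir / "original.pdb")
        write_pdb(predicted, outdir / "predicted.pdb")
        ledger.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return original, predicted, ledger
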