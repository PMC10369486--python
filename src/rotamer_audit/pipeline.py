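"""End-to-end orchestration: filter → nomenclature → torsions → classify →
ACC/secondary structure → compare → summaries → statistics.

Every stage is a thin call into the corresponding module; this file owns
the record assembly, the TSV report layouts and the run manifest
(parameters, fixture hashes, seed) that makes reruns auditable. Reports
are deterministic given identical inputs and configuration.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .accessibility import AccProfile, ingest_secondary_structure, \
    shrake_rupley_acc
from .error_analysis import ComparisonRecord, ResidueRecord, \
    anova_acc_by_class, comparison_frame, confidence_by_class, \
    contribution_by_aa, error_rate_by_aa, error_rate_by_acc, \
    pair_structures, top_transitions, tukey_hsd
from .fixtures import FixtureSet, default_fixtures
from .geometry import compute_chis
from .nomenclature import audit_and_fix_ring_names, correct_symmetric_chi, \
    nomenclature_census
from .rotamer_model import assign_group, classify, rotamer_census
from .structure_io import FilterReport, Structure, filter_residues, \
    filter_structure, read_pdb

__all__ = [
    "RunConfig",
    "build_residue_records",
    "run_pipeline",
    "census_report",
    "write_tsv",
]


@dataclass
class RunConfig:
    original_paths: list = field(default_factory=list)
    predicted_paths: dict = field(default_factory=dict)   # tag -> [paths]
    max_resolution: float = 2.0
    require_resolution: bool = True
    require_single_chain: bool = True
    max_bfactor: float = 40.0
    required_occupancy: float = 1.0
    acc_method: str = "internal_sr"      # internal_sr | none
    acc_n_points: int = 960
    fix_ring_names: bool = True
    verbatim_indices: bool = False
    seed: int = 0
    output_dir: str = "audit-out"


def torsion_atom_sets(fixtures: FixtureSet) -> dict[str, set[str]]:
    """Per residue type, the atom names participating in its torsions
    (chi quadruples; backbone N/CA/C are added by the filter itself)."""
    return {aa: cd.atom_names()
            for aa, cd in fixtures.chi_definitions.items()}


def build_residue_records(structure: Structure,
                          fixtures: FixtureSet | None = None,
                          config: RunConfig | None = None,
                          acc_profile: AccProfile | None = None,
                          dssp_output: str | None = None
                          ) -> tuple[list[ResidueRecord], FilterReport]:
    """Classify one structure into analysis records.

    Applies the residue-level quality filter, the PHE/TYR ring-name audit,
    chi extraction with the IUPAC-IUB symmetric correction, discretized
    classification, ACC and secondary structure. Residues failing the
    filter are carried with retained=False and no classification.
    """
    if fixtures is None:
        fixtures = default_fixtures()
    if config is None:
        config = RunConfig()
    report = filter_residues(structure, torsion_atom_sets(fixtures),
                             max_bfactor=config.max_bfactor,
                             required_occupancy=config.required_occupancy)
    if acc_profile is None and config.acc_method == "internal_sr":
        acc_profile = shrake_rupley_acc(structure,
                                        n_points=config.acc_n_points,
                                        fixtures=fixtures)
    ss = ingest_secondary_structure(structure, dssp_output)

    records: list[ResidueRecord] = []
    for chain_id, res in structure.iter_residues():
        key = (chain_id, res.seq_id, res.insertion_code)
        retained = report.per_residue_flags[key].value == "retained"
        if config.fix_ring_names and res.aa in ("PHE", "TYR"):
            res, _ = audit_and_fix_ring_names(res, fixtures)
        defs = fixtures.chi_definitions[res.aa]
        chis = compute_chis(res, defs) if len(defs) else None
        rotamer = None
        if chis is not None:
            chis = correct_symmetric_chi(
                res.aa, chis, verbatim_indices=config.verbatim_indices)
            if retained and chis.all_defined():
                rotamer = classify(res.aa, chis, fixtures)
        acc = acc_profile.get(key) if acc_profile else float("nan")
        records.append(ResidueRecord(
            structure_id=structure.id, chain=chain_id, seq_id=res.seq_id,
            insertion_code=res.insertion_code, aa=res.aa, chis=chis,
            rotamer=rotamer, acc=acc, ss_code=ss.get(key),
            retained=retained, group=assign_group(res.aa)))
    return records, report


def census_report(records: list[ResidueRecord]) -> pd.DataFrame:
    """Rotamer census over retained residues (canonical/off counts and
    percents per residue type, ALA/GLY in totals only)."""
    return rotamer_census([r for r in records if r.retained])


def write_tsv(df: pd.DataFrame, path: Path, schema: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# rotamer-audit {__version__} schema={schema}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_structures(paths) -> list[Structure]:
    structures = []
    for path in paths:
        structures.append(read_pdb(path))
    return structures


def run_pipeline(config: RunConfig,
                 fixtures: FixtureSet | None = None) -> dict:
    """Run the full audit and write the report bundle under
    ``config.output_dir``. Returns a manifest dict (also written as JSON).

    Raises with the offending stage and structure id on any failure.
    """
    if fixtures is None:
        fixtures = default_fixtures()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.original_paths:
        raise ValueError("no original structures configured")

    stage = "read"
    originals = _load_structures(config.original_paths)

    stage = "structure-filter"
    kept: list[Structure] = []
    filter_rows = []
    for st in originals:
        rep = filter_structure(st, max_resolution=config.max_resolution,
                               require_single_chain=config.require_single_chain,
                               require_resolution=config.require_resolution)
        filter_rows.append({"structure": st.id, "kept": rep.structure_kept,
                            "reason": rep.reason.value,
                            "residues": rep.residues_total})
        if rep.structure_kept:
            kept.append(st)
    write_tsv(pd.DataFrame(filter_rows), outdir / "structure_filter.tsv",
              "structure_filter.v1")

    stage = "nomenclature"
    nom = nomenclature_census(kept, fixtures,
                              verbatim_indices=config.verbatim_indices)
    write_tsv(nom.per_aa, outdir / "nomenclature.tsv", "nomenclature.v1")

    stage = "classify"
    all_records: list[ResidueRecord] = []
    residue_filter_rows = []
    for st in kept:
        records, rep = build_residue_records(st, fixtures, config)
        all_records.extend(records)
        residue_filter_rows.append({
            "structure": st.id, "residues_total": rep.residues_total,
            "residues_retained": rep.residues_retained})
    write_tsv(pd.DataFrame(residue_filter_rows),
              outdir / "residue_filter.tsv", "residue_filter.v1")
    write_tsv(census_report(all_records), outdir / "census.tsv", "census.v1")

    stage = "compare"
    comparisons: list[ComparisonRecord] = []
    kept_ids = {st.id for st in kept}
    for tag, paths in config.predicted_paths.items():
        if len(paths) != len(config.original_paths):
            raise ValueError(
                f"stage compare: program {tag!r} has {len(paths)} predicted "
                f"structures for {len(config.original_paths)} originals "
                "(lists are paired positionally)")
        pred_records: list[ResidueRecord] = []
        for orig_st, path in zip(originals, paths):
            if orig_st.id not in kept_ids:
                continue
            st = read_pdb(path)
            st.id = orig_st.id           # predictions share the backbone
            records, _ = build_residue_records(st, fixtures, config)
            pred_records.extend(records)
        comps, unmatched = pair_structures(all_records, pred_records, tag)
        comparisons.extend(comps)
        if unmatched:
            write_tsv(pd.DataFrame({"key": [str(k) for k in unmatched]}),
                      outdir / f"unmatched_{tag}.tsv", "unmatched.v1")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "fixture_hashes": fixtures.hashes,
        "n_structures": len(kept),
        "n_records": len(all_records),
        "n_comparisons": len(comparisons),
        "config": {k: v for k, v in vars(config).items()
                   if not k.endswith("_paths") and k != "output_dir"},
    }

    if comparisons:
        stage = "summaries"
        write_tsv(comparison_frame(comparisons),
                  outdir / "comparisons.tsv", "comparisons.v1")
        write_tsv(error_rate_by_aa(comparisons),
                  outdir / "errors_by_aa.tsv", "errors_by_aa.v1")
        write_tsv(contribution_by_aa(comparisons),
                  outdir / "contribution_by_aa.tsv", "contribution.v1")
        by_bin, by_cat = error_rate_by_acc(comparisons)
        write_tsv(by_bin, outdir / "errors_by_acc_bin.tsv", "errors_acc.v1")
        write_tsv(by_cat, outdir / "errors_by_acc_category.tsv",
                  "errors_acc.v1")
        write_tsv(confidence_by_class(comparisons),
                  outdir / "confidence.tsv", "confidence.v1")
        transition_rows = []
        for aa in sorted({c.aa for c in comparisons}):
            for label, count in top_transitions(comparisons, aa):
                transition_rows.append(
                    {"aa": aa, "transition": label, "count": count})
        write_tsv(pd.DataFrame(transition_rows),
                  outdir / "transitions.tsv", "transitions.v1")

        stage = "statistics"
        tukey_rows = []
        for aa in sorted({r.aa for r in all_records
                          if r.rotamer is not None}):
            try:
                f_stat, p_value = anova_acc_by_class(all_records, aa)
            except ValueError:
                continue
            for res in tukey_hsd(all_records, aa):
                tukey_rows.append({
                    "aa": aa, "pair": res.pair,
                    "difference": res.difference, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                    "significant": res.significant,
                    "correlation": res.correlation_sign,
                    "anova_F": f_stat, "anova_p": p_value})
        if tukey_rows:
            write_tsv(pd.DataFrame(tukey_rows), outdir / "tukey.tsv",
                      "tukey.v1")
        else:
            (outdir / "tukey.tsv").write_text(
                "# rotamer-audit tukey.v1: no class pair had enough "
                "records for a post hoc comparison\n")

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
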