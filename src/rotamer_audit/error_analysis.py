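"""Residue-by-residue comparison of original vs repacked structures and
the error decompositions built on it.

A rotamer (class) error is any residue whose discretized class differs
between original and prediction — for long side chains one deviating
torsion is enough. Chi-angle errors treat each torsion independently:
the circular deviation 180 - |abs(x - y) - 180| is dichotomized at 30°.
Decompositions: per amino acid (rate and share of all errors), per ACC
category and 20 Å² ACC bin, per secondary structure / protein size /
side-chain-length group, per-class prediction confidence, ranked error
transitions, and ANOVA + Tukey HSD of ACC across rotamer classes with a
family-wise 963-fold p adjustment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accessibility import AccBinning, acc_bin, acc_category
from .geometry import ChiAngles
from .rotamer_model import RotamerClass, circular_distance

__all__ = [
    "CHI_ERROR_CUTOFF",
    "TUKEY_FAMILY_SIZE",
    "ResidueRecord",
    "ComparisonRecord",
    "TukeyResult",
    "pair_structures",
    "comparison_frame",
    "error_rate_by_aa",
    "contribution_by_aa",
    "error_rate_by_acc",
    "accuracy_by_stratum",
    "confidence_by_class",
    "top_transitions",
    "anova_acc_by_class",
    "tukey_hsd",
    "adjust_p",
]

CHI_ERROR_CUTOFF = 30.0       # deviation <= 30° counts as correct
TUKEY_FAMILY_SIZE = 963


@dataclass
class ResidueRecord:
    """One analysis row per residue of one structure."""

    structure_id: str
    chain: str
    seq_id: int
    aa: str
    insertion_code: str = ""
    chis: ChiAngles | None = None
    rotamer: RotamerClass | None = None
    acc: float = float("nan")
    ss_code: str = "unassigned"
    retained: bool = True
    group: str = "none"

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.structure_id, self.chain, self.seq_id,
                self.insertion_code)


@dataclass
class ComparisonRecord:
    key: tuple[str, str, int, str]
    aa: str
    original_label: str
    predicted_label: str
    chi_deviations: list[float] = field(default_factory=list)
    chi_errors: list[bool] = field(default_factory=list)
    program_tag: str = ""
    acc: float = float("nan")
    ss_code: str = "unassigned"
    group: str = "none"

    @property
    def class_error(self) -> bool:
        return self.original_label != self.predicted_label


class PairingError(ValueError):
    pass


def pair_structures(original: list[ResidueRecord],
                    predicted: list[ResidueRecord], program_tag: str = ""
                    ) -> tuple[list[ComparisonRecord], list[tuple]]:
    """Pair residues by (structure, chain, seq_id, icode).

    Only residues retained on the original side, classified on both sides
    and present in both sets are compared; unmatched retained residues are
    returned separately, not silently dropped. A residue-type mismatch at
    the same key is a hard error. Chi deviations use the circular formula
    on however many torsions both sides define.
    """
    pred_by_key = {}
    for rec in predicted:
        if rec.key in pred_by_key:
            raise PairingError(f"duplicate predicted residue key {rec.key}")
        pred_by_key[rec.key] = rec
    comparisons: list[ComparisonRecord] = []
    unmatched: list[tuple] = []
    for rec in original:
        if not rec.retained or rec.rotamer is None:
            continue
        other = pred_by_key.get(rec.key)
        if other is None:
            unmatched.append(rec.key)
            continue
        if other.aa != rec.aa:
            raise PairingError(
                f"residue type mismatch at {rec.key}: "
                f"{rec.aa} vs {other.aa}")
        if other.rotamer is None:
            unmatched.append(rec.key)
            continue
        deviations: list[float] = []
        errors: list[bool] = []
        if rec.chis is not None and other.chis is not None:
            for i in range(min(len(rec.chis), len(other.chis))):
                if rec.chis.defined_mask[i] and other.chis.defined_mask[i]:
                    d = circular_distance(rec.chis.values[i],
                                          other.chis.values[i])
                    deviations.append(d)
                    errors.append(d > CHI_ERROR_CUTOFF)
                else:
                    deviations.append(float("nan"))
                    errors.append(False)
        comparisons.append(ComparisonRecord(
            key=rec.key, aa=rec.aa,
            original_label=rec.rotamer.label,
            predicted_label=other.rotamer.label,
            chi_deviations=deviations, chi_errors=errors,
            program_tag=program_tag, acc=rec.acc, ss_code=rec.ss_code,
            group=rec.group))
    return comparisons, unmatched


def comparison_frame(comparisons: list[ComparisonRecord]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {
            "structure_id": c.key[0], "chain": c.key[1], "seq_id": c.key[2],
            "aa": c.aa, "original": c.original_label,
            "predicted": c.predicted_label, "class_error": c.class_error,
            "program_tag": c.program_tag, "acc": c.acc,
            "ss_code": c.ss_code, "group": c.group,
        }
        for i in range(4):
            row[f"chi{i+1}_dev"] = (c.chi_deviations[i]
                                    if i < len(c.chi_deviations)
                                    else float("nan"))
            row[f"chi{i+1}_err"] = (bool(c.chi_errors[i])
                                    if i < len(c.chi_errors) else None)
        rows.append(row)
    return pd.DataFrame(rows)


def error_rate_by_aa(comparisons: list[ComparisonRecord]) -> pd.DataFrame:
    """Percent class errors per residue type (errors / records × 100),
    plus an ALL row with the overall rate."""
    if not comparisons:
        raise ValueError("no comparisons")
    df = comparison_frame(comparisons)
    rows = []
    for aa, sub in df.groupby("aa"):
        rows.append({"aa": aa, "n": len(sub),
                     "errors": int(sub["class_error"].sum()),
                     "pct_errors": 100.0 * sub["class_error"].mean()})
    rows.append({"aa": "ALL", "n": len(df),
                 "errors": int(df["class_error"].sum()),
                 "pct_errors": 100.0 * df["class_error"].mean()})
    return pd.DataFrame(rows)


def contribution_by_aa(comparisons: list[ComparisonRecord]) -> pd.DataFrame:
    """Each residue type's share of all class errors (sums to 100%)."""
    df = comparison_frame(comparisons)
    total_errors = int(df["class_error"].sum())
    if total_errors == 0:
        return pd.DataFrame(columns=["aa", "errors", "pct_contribution"])
    rows = []
    for aa, sub in df.groupby("aa"):
        errors = int(sub["class_error"].sum())
        if errors:
            rows.append({"aa": aa, "errors": errors,
                         "pct_contribution": 100.0 * errors / total_errors})
    return pd.DataFrame(rows)


def error_rate_by_acc(comparisons: list[ComparisonRecord],
                      binning: AccBinning = AccBinning(),
                      per_chi: bool = False
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-error rates per 20 Å² ACC bin and per ACC category.

    Empty strata are absent rather than reported as zero; bins beyond
    220 Å² are flagged low_n (few cases, possibly unrepresentative). With
    ``per_chi`` the tables carry one row per (stratum, chi index) using the
    dichotomized per-torsion errors instead of class errors.
    """
    df = comparison_frame(comparisons)
    df = df[np.isfinite(df["acc"])]
    df["acc_bin"] = [acc_bin(a, binning) for a in df["acc"]]
    df["acc_cat"] = [acc_category(a, binning) for a in df["acc"]]

    def summarize(group_col: str) -> pd.DataFrame:
        rows = []
        for level, sub in df.groupby(group_col):
            if per_chi:
                for i in range(1, 5):
                    defined = sub[sub[f"chi{i}_dev"].notna()]
                    if len(defined) == 0:
                        continue
                    rows.append({
                        group_col: level, "chi_index": i, "n": len(defined),
                        "pct_errors":
                            100.0 * defined[f"chi{i}_err"].astype(bool).mean(),
                    })
            else:
                rows.append({group_col: level, "n": len(sub),
                             "pct_errors": 100.0 * sub["class_error"].mean()})
        out = pd.DataFrame(rows)
        if group_col == "acc_bin" and len(out):
            def lower(label: str) -> float:
                return (binning.cap if label.startswith(">")
                        else float(label))
            out["low_n_flag"] = [lower(b) > 220.0 for b in out["acc_bin"]]
            out = out.sort_values(
                ["acc_bin"], key=lambda s: s.map(lower)).reset_index(drop=True)
        return out

    return summarize("acc_bin"), summarize("acc_cat")


def accuracy_by_stratum(comparisons: list[ComparisonRecord],
                        records: list[ResidueRecord] | None = None,
                        stratum: str = "secondary_structure",
                        size_bin: int = 100) -> pd.DataFrame:
    """Percent correct per stratum level (secondary_structure,
    protein_size or group). Protein size is the residue count of the parent
    structure, binned by ``size_bin`` and labelled by lower limit."""
    df = comparison_frame(comparisons)
    if stratum == "secondary_structure":
        df["stratum"] = df["ss_code"]
    elif stratum == "group":
        df["stratum"] = df["group"]
    elif stratum == "protein_size":
        if records is None:
            raise ValueError("protein_size stratum needs residue records")
        sizes = pd.Series([r.structure_id for r in records]) \
            .value_counts().to_dict()
        df["stratum"] = [
            int(sizes[s] // size_bin * size_bin) for s in df["structure_id"]]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    rows = []
    for level, sub in df.groupby("stratum"):
        rows.append({"stratum": level, "n": len(sub),
                     "pct_correct": 100.0 * (~sub["class_error"]).mean()})
    return pd.DataFrame(rows)


def confidence_by_class(comparisons: list[ComparisonRecord]) -> pd.DataFrame:
    """Per (aa, original class): percent of originals predicted as the same
    class, per program tag plus a macro-average row across programs."""
    df = comparison_frame(comparisons)
    rows = []
    for (aa, label), sub in df.groupby(["aa", "original"]):
        per_program = []
        for tag, tsub in sub.groupby("program_tag"):
            conf = 100.0 * (tsub["predicted"] == label).mean()
            rows.append({"aa": aa, "class": label, "program_tag": tag,
                         "n": len(tsub), "confidence": conf})
            per_program.append(conf)
        rows.append({"aa": aa, "class": label, "program_tag": "macro_avg",
                     "n": len(sub),
                     "confidence": float(np.mean(per_program))})
    return pd.DataFrame(rows)


def top_transitions(comparisons: list[ComparisonRecord], aa: str,
                    n: int = 10) -> list[tuple[str, int]]:
    """Ranked "original to predicted" error transitions for one residue
    type; count-descending, ties broken lexicographically."""
    counts: dict[tuple[str, str], int] = {}
    for c in comparisons:
        if c.aa == aa and c.class_error:
            pair = (c.original_label, c.predicted_label)
            counts[pair] = counts.get(pair, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(f"{orig} to {pred}", count)
            for (orig, pred), count in ranked[:n]]


def _acc_groups(records: list[ResidueRecord], aa: str,
                min_size: int = 2) -> tuple[list[str], list[np.ndarray]]:
    by_label: dict[str, list[float]] = {}
    for rec in records:
        if rec.aa == aa and rec.rotamer is not None and np.isfinite(rec.acc):
            by_label.setdefault(rec.rotamer.label, []).append(rec.acc)
    labels = [l for l in sorted(by_label) if len(by_label[l]) >= min_size]
    return labels, [np.asarray(by_label[l]) for l in labels]


def anova_acc_by_class(records: list[ResidueRecord], aa: str
                       ) -> tuple[float, float]:
    """One-way ANOVA of ACC grouped by rotamer class (off included)."""
    labels, groups = _acc_groups(records, aa)
    if len(labels) < 2:
        raise ValueError(
            f"ANOVA needs >= 2 classes with >= 2 ACC records for {aa}")
    f_stat, p_value = stats.f_oneway(*groups)
    return float(f_stat), float(p_value)


def adjust_p(p_raw: float, family_size: int = TUKEY_FAMILY_SIZE) -> float:
    """Family-wise p adjustment: min(1, p_raw × family_size)."""
    return min(1.0, p_raw * family_size)


@dataclass
class TukeyResult:
    aa: str
    pair: str                 # "classA-classB"
    difference: float         # mean ACC(classA) - mean ACC(classB), Å²
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float
    significant: bool
    correlation_sign: str     # off_higher_acc | off_lower_acc | n/a


def tukey_hsd(records: list[ResidueRecord], aa: str,
              family_size: int = TUKEY_FAMILY_SIZE,
              alpha: float = 0.05) -> list[TukeyResult]:
    """All-pairs Tukey HSD on mean ACC across the rotamer classes of one
    residue type. Raw pair p-values come from the studentized-range
    distribution; adjusted p = min(1, raw × family_size); significance at
    adjusted p < alpha. Classes with fewer than two records are dropped."""
    labels, groups = _acc_groups(records, aa)
    if len(labels) < 2:
        raise ValueError(
            f"Tukey HSD needs >= 2 classes with >= 2 ACC records for {aa}")
    res = stats.tukey_hsd(*groups)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    means = [float(np.mean(g)) for g in groups]
    out: list[TukeyResult] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p_raw = float(res.pvalue[i, j])
            p_adj = adjust_p(p_raw, family_size)
            sign = "n/a"
            if labels[i] == "off" or labels[j] == "off":
                off_mean = means[i] if labels[i] == "off" else means[j]
                other = means[j] if labels[i] == "off" else means[i]
                sign = ("off_higher_acc" if off_mean > other
                        else "off_lower_acc")
            out.append(TukeyResult(
                aa=aa, pair=f"{labels[i]}-{labels[j]}",
                difference=float(res.statistic[i, j]),
                ci_low=float(ci.low[i, j]), ci_high=float(ci.high[i, j]),
                p_raw=p_raw, p_adjusted=p_adj,
                significant=p_adj < alpha, correlation_sign=sign))
    return out
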