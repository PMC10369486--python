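"""Generate the synthetic study cohort.

Builds 8 single-chain structures (150 residues each, 10% injected off
rotamers, 5% occupancy corruption for the quality filter to catch) and two
mock repackings per structure: a flat 25% confusion process ("mock-flat")
and an ACC-dependent one ("mock-acc", logistic slope 0.02 per A2 on a 15%
baseline). Structures go to scratch/cohort/ (regenerable, not part of the
deliverable); the combined truth ledger goes to scratch/cohort/truth.tsv.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from rotamer_audit.accessibility import shrake_rupley_acc  # noqa: E402
from rotamer_audit.fixtures import default_fixtures  # noqa: E402
from rotamer_audit.structure_io import write_pdb  # noqa: E402
from rotamer_audit.synthetic_data import (GeneratorConfig,  # noqa: E402
                                          build_peptide, mock_predict)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

N_STRUCTURES = 8
N_RESIDUES = 150
BASE_SEED = 20230


def main() -> None:
    fx = default_fixtures()
    COHORT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    ledgers = []
    for k in range(N_STRUCTURES):
        seed = BASE_SEED + k
        cfg = GeneratorConfig(n_residues=N_RESIDUES, seed=seed,
                              off_fraction=0.10, occupancy_corruption=0.05,
                              structure_id=f"synth{k:02d}")
        original, ledger = build_peptide(cfg, fx)
        acc = shrake_rupley_acc(original, fixtures=fx)
        flat, ledger_flat = mock_predict(original, ledger, epsilon0=0.25,
                                         seed=seed + 1000, fixtures=fx)
        accdep, ledger_acc = mock_predict(original, ledger, epsilon0=0.15,
                                          acc_slope=0.02, seed=seed + 2000,
                                          fixtures=fx, acc_profile=acc)
        write_pdb(original, COHORT / f"original_{k:02d}.pdb")
        write_pdb(flat, COHORT / f"mock-flat_{k:02d}.pdb")
        write_pdb(accdep, COHORT / f"mock-acc_{k:02d}.pdb")
        ledger_flat["program"] = "mock-flat"
        ledger_acc["program"] = "mock-acc"
        for led in (ledger_flat, ledger_acc):
            led["structure"] = f"synth{k:02d}"
            ledgers.append(led)
    truth = pd.concat(ledgers, ignore_index=True)
    truth.to_csv(COHORT / "truth.tsv", sep="\t", index=False)

    confused = truth["action"].str.startswith("confused")
    acted = truth["action"] != "n/a"
    print(f"wrote {N_STRUCTURES} originals + 2 mock repackings each "
          f"to {COHORT}")
    for prog, sub in truth[acted].groupby("program"):
        rate = sub["action"].str.startswith("confused").mean()
        print(f"  {prog}: injected confusion realized at "
              f"{100 * rate:.1f}% of {len(sub)} side chains")
    off = (truth[truth.program == "mock-flat"]["true_label"] == "off").mean()
    print(f"  off rotamers injected at {100 * off:.1f}% of residues")


if __name__ == "__main__":
    main()
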