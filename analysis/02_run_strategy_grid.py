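"""Run the full intratumoral/peritumoral strategy grid on the synthetic cohort.

Evaluates all 34 models — 4 intratumoral (PC/GRAY x OP/BB) plus the 6 valid
fusion strategies at each margin of 2, 4, 6, 8, 10 mm — on a 150/50
train/test split of the cohort written by 01_simulate_cohort.py (regenerated
in memory here so the script is self-contained). Writes
``results/grid_results.csv`` and ``results/provenance.json`` and prints the
testing-cohort leaderboard.

Run from the repository root:  python analysis/02_run_strategy_grid.py
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import perifuse as pf
from perifuse.experiment import save_results

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pf.set_single_threaded()
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cases = pf.generate_cohort(pf.CohortSpec(n_cases=200), seed=1)
    train, test = cases[:150], cases[150:]
    result = pf.run_grid(train, test, config=pf.GridConfig(epochs=5, n_boot=200),
                         master_seed=1)
    csv_path = save_results(result, OUT)
    (OUT / "grid_results.csv").write_bytes(csv_path.read_bytes())
    testing = result.table[result.table.cohort == "testing"]
    print("\ntesting-cohort leaderboard (top 10 of 34):")
    cols = ["model", "auc", "accuracy", "sensitivity", "specificity"]
    print(testing.sort_values("auc", ascending=False)[cols].head(10).to_string(index=False))
    intra = testing[testing.model.str.endswith("Intra")]
    print(f"\nbest intratumoral model: "
          f"{intra.loc[intra.auc.idxmax(), 'model']} (AUC {intra.auc.max():.3f})")


if __name__ == "__main__":
    main()
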