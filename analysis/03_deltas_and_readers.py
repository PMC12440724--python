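"""Delta table versus the best intratumoral model, and a reader comparison.

From ``results/grid_results.csv`` (produced by 02_run_strategy_grid.py):

* writes ``results/delta_table.csv`` — per-model testing-cohort deltas in
  AUC/accuracy/sensitivity/specificity against the best intratumoral model
  (its own row is all zeros by construction);
* simulates six readers of graded skill on the same test cases (binormal
  scores thresholded to binary calls, seeded) and writes
  ``results/reader_comparison.csv`` with AUC (95% CI) per reader and the
  paired DeLong p-value against the best fusion model. The simulated-reader
  panel stands in for a human reader study, which needs clinicians; only the
  comparison statistics are the package's contribution.

Run from the repository root:  python analysis/03_deltas_and_readers.py
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

import perifuse as pf

OUT = Path(__file__).resolve().parents[1] / "results"


def simulate_reader(labels: np.ndarray, separation: float, rng) -> np.ndarray:
    """Binary reader calls from a binormal latent score of given separation."""
    latent = rng.standard_normal(len(labels)) + separation * labels
    return (latent > separation / 2.0).astype(float)


def main() -> None:
    table = pd.read_csv(OUT / "grid_results.csv")
    testing = table[table.cohort == "testing"]
    intra = testing[testing.model.str.endswith("Intra")]
    reference = intra.loc[intra.auc.idxmax(), "model"]
    deltas = pf.delta_table(table, reference)
    deltas.to_csv(OUT / "delta_table.csv", index=False)
    print(f"delta table vs {reference} -> {OUT / 'delta_table.csv'}")
    print(deltas.sort_values("delta_auc", ascending=False).head(8).to_string(index=False))

    # Rebuild the best model's test scores by rerunning the winning strategy.
    cases = pf.generate_cohort(pf.CohortSpec(n_cases=200), seed=1)
    train, test = cases[:150], cases[150:]
    best = testing.loc[testing.auc.idxmax(), "model"]
    result = pf.run_grid(
        train, test,
        margins_mm=[pf.StrategyConfig.from_name(best).margin_mm] if "Peri" in best else [],
        config=pf.GridConfig(epochs=5, n_boot=0), master_seed=1,
    )
    labels = result.test_labels
    rng = np.random.default_rng(99)
    readers = {
        "Junior Reader 1": simulate_reader(labels, 0.8, rng),
        "Junior Reader 2": simulate_reader(labels, 0.9, rng),
        "Intermediate Reader 1": simulate_reader(labels, 1.2, rng),
        "Intermediate Reader 2": simulate_reader(labels, 1.3, rng),
        "Senior Reader 1": simulate_reader(labels, 1.6, rng),
        "Senior Reader 2": simulate_reader(labels, 1.7, rng),
    }
    comparison = pf.reader_comparison(
        labels, result.test_scores[best], best, readers, n_boot=1000, seed=3
    )
    comparison.to_csv(OUT / "reader_comparison.csv", index=False)
    print(f"\nreader comparison -> {OUT / 'reader_comparison.csv'}")
    print(comparison[["reader", "auc_ci", "delta_auc_vs_model", "delong_p_vs_model"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
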