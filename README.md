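# perifuse

Intratumoral–peritumoral fusion pipeline for benign/malignant lesion
classification on contrast-enhanced-ultrasound-like (CEUS) images.

Radiomics studies increasingly show that tissue *around* a tumor carries
diagnostic signal, but how much of it to include — and how — is a design
choice with real consequences. `perifuse` implements the full evaluation
grid for that question: millimetre-calibrated peritumoral rings, the six
valid combinations of image color (pseudo-color vs grayscale), ROI shape
(precise mask vs bounding box) and fusion strategy (direct extension vs
feature-level fusion), deep-feature extraction from an early pooling layer
of a VGG16-family backbone, and the standard radiomics selection chain. A
synthetic cohort generator with *known, rim-confined* class signal makes
every stage testable without clinical data: if the pipeline works, models
whose peritumoral margin matches the true signal width should win, and
over-expanded margins should not.

It is aimed at medical-image-analysis researchers who want a tested,
reproducible reference implementation of the peritumoral-fusion methodology
— not a clinical classifier.

## The method

For a lesion mask $M$ and margin $m$ (mm), the peritumoral ring is

$$R_m = \{x : d(x, M) \le m\} \setminus M,$$

with $d$ the Euclidean distance in millimetres via the pixel spacing
(exact distance-transform thresholding, anisotropy-aware). Each model of the
grid crops the image by one strategy — `Intra` ($M$ only), `DE`
($M \cup R_m$ as one crop), `FLF` ($M$ and $R_m$ separately) — as either
`OP` (background outside the mask zeroed) or `BB` (bounding-box interior
retained), in `PC` (pseudo-color) or `GRAY`. `BB`+`FLF` is excluded because
the intratumoral bounding box overlaps the ring. Crops are resized to the
backbone input; deep features come from the first pooling layer, reduced by
8-fold consecutive-channel-group averaging (112×112×8 = 100,352 features for
the full `vgg16` configuration) and then passed through

PCA(32) → Mann–Whitney U (p < 0.05) → Pearson pruning (|r| ≥ 0.9) →
LASSO (10-fold CV) → logistic regression,

all fitted on training rows only. Models are compared by AUC (pairwise
concordance, ties ½) with stratified-bootstrap 95% CIs, at a Youden-optimal
threshold frozen on training; paired model comparisons use the DeLong test.
See `docs/methods.md` for the full account, including what the synthetic
generator does and does not emulate.

## Worked example

```python
import perifuse as pf

cases = pf.generate_cohort(pf.CohortSpec(n_cases=200), seed=1)
result = pf.run_grid(cases[:150], cases[150:], margins_mm=[2, 4, 10],
                     config=pf.GridConfig(epochs=5, n_boot=0), master_seed=1)
t = result.table[result.table.cohort == "testing"].set_index("model")
print(t["auc"].sort_values(ascending=False).head(6).round(3))
```

prints:

```
model
GRAY-OP-FLF-Peri (10mm)    0.974
PC-BB-DE-Peri (10mm)       0.966
PC-OP-FLF-Peri (4mm)       0.961
GRAY-BB-DE-Peri (4mm)      0.957
GRAY-OP-DE-Peri (4mm)      0.952
GRAY-BB-DE-Peri (10mm)     0.947
```

The generator plants class signal inside the lesion and a 4 mm rim only, so
every fusion model here outranks the best intratumoral-only model
(`PC-BB-Intra`, AUC 0.921). Individual 10 mm models can top a single 50-case
test split, as above; the stable effect is in the averages — across the ten
seeded replicates of the acceptance suite, margin-4 models beat margin-10
models on mean test AUC (0.914 vs 0.907), the expected penalty for diluting
a 4 mm rim with uninformative tissue. The same drivers are available as
narrative scripts:
`analysis/01_simulate_cohort.py` (cohort + TIC sanity check),
`analysis/02_run_strategy_grid.py` (full 34-model grid →
`results/grid_results.csv`), `analysis/03_deltas_and_readers.py`
(delta table vs the best intratumoral model and a simulated-reader
comparison), or via the CLI:

```bash
perifuse synth --spec cohort.yaml --out cohort/ --seed 1
perifuse run --cohort cohort/ --margins 2,4,6,8,10 --seed 1 --out results/
perifuse report --results results/results.csv --out results/
```

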