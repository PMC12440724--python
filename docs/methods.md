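# Methods

## Problem and pipeline

`perifuse` implements a deep-learning-radiomics pipeline for classifying
benign versus malignant lesions on contrast-enhanced-ultrasound-like (CEUS)
images, with the specific question of *how much peritumoral tissue to
include and how to include it*. Per case the inputs are a 2-D lesion image
(pseudo-color or grayscale), a binary lesion mask in pixel register, the
pixel spacing in mm/pixel, and a class label; dynamic loops are reduced to
their peak-enhancement frame via the time-intensity curve (TIC: mean in-mask
luminance per frame, argmax, earliest frame on ties).

Each model of the grid is one combination of

* **color**: `PC` (pseudo-color retained) or `GRAY` (Rec.601 luminance,
  weights 0.299/0.587/0.114);
* **ROI shape**: `OP` (crop to the defining mask's bounding box, pixels
  outside the mask set exactly to 0) or `BB` (same bounding box, interior
  retained);
* **fusion**: `Intra` (lesion only), `DE` (direct extension: one crop over
  lesion ∪ ring), or `FLF` (feature-level fusion: separate intra and peri
  crops, features concatenated);
* **margin**: the peritumoral ring width in millimetres, default schedule
  2, 4, 6, 8, 10 mm.

`BB`+`FLF` is invalid by construction (the intratumoral bounding box
overlaps the ring), leaving 4 intratumoral + 6 fusion models per margin = 34
models under the default schedule.

## Millimetre-calibrated geometry

Dilation by a physical margin is defined as thresholding the exact Euclidean
distance transform (`scipy.ndimage.distance_transform_edt` with the mm
spacing as sampling) at the margin, with a 1e-9 mm absolute slack so pixels
exactly on the margin circle are included independent of float rounding
order. This is exact and spacing-aware (anisotropic spacings included),
unlike iterated structuring-element dilation. The peritumoral ring is the
dilation minus the mask; dilations are clipped at image borders (no image
padding) and a truncated ring triggers a logged warning. Tests verify
equality with a brute-force all-pairs mm-distance oracle on random masks.

## Backbone and deep features

The feature extractor is a VGG16-family stack (five 3x3-convolution blocks
with 2x2 max pooling) implemented directly on NumPy (im2col + GEMM), so runs
are bit-reproducible on CPU with no weight downloads: convolution filters
are He-initialized from a seed (`weight_source="seeded-random"`).
Transfer learning uses the freeze-and-head recipe: convolutional features
stay frozen and a 2-unit softmax head on standardized, globally averaged
final-block activations is trained with cross-entropy by minibatch SGD
(batch 16, learning rate 1e-3, 5 epochs by default; all configurable). With
frozen features the extracted representations are weight-seed-determined;
the head supplies the classification signal for Grad-CAM.

Deep features are taken from the **first pooling layer** — the
fifth-to-last pooling layer of the stack, which preserves low-level spatial
detail. Its 64-channel map (112x112 at the full 224 input) is reduced to 8
channels by averaging 8 consecutive-channel groups and flattened in
(row, col, channel) order, giving 112 x 112 x 8 = 100,352 features per crop
for the `vgg16` configuration. The channel-group averaging is an explicit
design choice recorded in the checkpoint sidecar (`channel_groups: 8`): it
is the deterministic reduction consistent with an 8-channel target for a
64-channel layer.

Three registered configurations trade fidelity for speed: `vgg16`
(224 input, full widths; used to assert the 100,352-feature contract),
`vgg16-small` (112 input, widths/4; used for Grad-CAM localization checks at
7x7 CAM resolution) and `vgg16-tiny` (32 input, widths/8; used for the
strategy-grid experiments so a 34-model x 300-case grid runs in minutes on
one CPU core). Crops are resized bilinearly to the input size (grayscale
replicated to 3 channels) and normalized with the ImageNet convention
(mean 0.485/0.456/0.406, sd 0.229/0.224/0.225) for both weight sources.

Grad-CAM is computed at the last convolutional block for the predicted
class. With a linear head on standardized GAP features the gradient of the
class score with respect to channel *k*'s activation map is constant,
`head_weight[k, c] / (head_scale[k] * h * w)`, so the channel weights are
analytic; the ReLU-rectified weighted sum is upsampled bilinearly to the
crop and min-max normalized to [0, 1] (an all-zero map stays all-zero, a
constant positive map becomes all-ones).

## Selection chain

Per model: PCA to 32 components (fitted on training rows only; under FLF
each region block gets its own PCA to 32 and the blocks are concatenated to
64, keeping region contributions symmetric) → two-sided Mann-Whitney U
filter keeping p < 0.05 (constant features get p = 1 and drop) → greedy
Pearson pruning at |r| ≥ 0.9 visiting features in ascending p order (the
more class-associated member of a redundant pair survives; ties broken by
column order) → L1-penalized logistic path over a 30-point log-spaced
penalty grid with the penalty chosen by stratified 10-fold cross-validated
deviance (`LogisticRegressionCV`, liblinear) → a standard L2 logistic
classifier on the surviving features. Feature counts are asserted
non-increasing along the chain on every run.

Degenerate-input policy: if a filter stage would leave zero features, the
single feature with the smallest Mann-Whitney p (or the largest-magnitude
path coefficient, for LASSO) is carried forward so the classifier always
has an input; this can occur on small or signal-free cohorts and is
deliberately not an error.

The operating threshold maximizes Youden's index (sensitivity +
specificity − 1) on training scores — highest threshold among maximizers,
for determinism — and is frozen for the test cohort. 95% CIs are
class-stratified bootstrap percentile intervals (1000 replicates by default,
seeded). The training report also carries a stratified 5-fold
cross-validated AUC. AUC itself is the pairwise-concordance probability with
ties counted 1/2; model-versus-model and model-versus-reader comparisons use
the paired DeLong test (normal approximation on the covariance-adjusted
structural components), cross-checked against a bootstrap variance in tests.

PCA fitted on the pooled cohorts would leak test information into the
transform, so every fitted quantity — centering, p-values, correlations,
penalty, classifier, threshold — is a function of training rows only; tests
verify that permuting or editing test rows permutes or changes only the
corresponding test scores.

## Synthetic cohort generator

The generator emulates what the pipeline consumes, not ultrasound physics.
Each case is a pseudo-color rendering of an intensity field on a [0, 1]
scale over a 128x128 grid at 0.25 mm/px (default):

* lesion: an ellipse with axes drawn from 3–6 mm, random orientation, and
  low-frequency radial boundary perturbation (harmonics 2–4, amplitude 0.10)
  so that OP and BB crops differ meaningfully; placement keeps the worst-case
  lesion radius + true rim + 2 mm inside the image;
* tissue background 0.35, in-lesion enhancement +0.25 for both classes;
* class signal: +0.15 inside the lesion and +0.15 inside the true 4 mm rim
  for malignant cases only — exactly zero beyond the rim before noise, which
  is what makes margin recovery a well-posed question;
* malignant-only in-lesion texture (smoothed noise, sd 0.05) emulating
  heterogeneous enhancement;
* a slowly varying gain field (Gaussian-smoothed noise, 4 mm correlation
  length, sd 0.5 x noise_sd) emulating exam-to-exam and across-the-field
  gain/attenuation variation — this is the nuisance that keeps a plain
  in-lesion mean from being a perfect classifier, and because it decorrelates
  over a few millimetres, tissue far from the lesion is a poor gain
  reference: over-expanded crops buy no free normalization. An earlier
  constant-offset draft of this term let any background pixel cancel the
  offset exactly, which unrealistically *rewarded* over-expansion;
* smoothed speckle-like additive noise (sd 0.25, 1.2 px smoothing). A
  multiplicative Rayleigh speckle model would be more faithful to
  ultrasound; additive smoothed Gaussian noise is sufficient for pipeline
  testing and keeps the exact-confinement invariants provable.

All noise terms scale with `noise_sd`, so at `noise_sd=0` the two classes
are pixel-identical outside lesion ∪ rim (asserted exactly in tests) and the
in-lesion mean is a perfect oracle (AUC 1.0).

Pseudo-color rendering uses a fixed monotone map: gray level v plus a chroma
term projected orthogonal to the Rec.601 luma axis with amplitude
0.8·v·(1−v), so the rendered luminance equals v exactly, channels stay in
[0, 1], and grayscale conversion recovers intensity rank order (Spearman
rho = 1). Scanner color encodings are proprietary; any monotone map is an
assumption, and three ids (`sepia`, `ocean`, `verdant`) are provided.

Dynamic loops scale the in-mask enhancement by a gamma-variate-like curve
`tau^2 exp(2(1-tau))`, `tau = (t+1)/(peak+1)`, normalized to 1 at the peak,
which is strictly unimodal at integer samples; per-frame noise is added
outside the mask only, so the in-mask TIC is exactly unimodal with its
strict maximum at the requested peak frame.

What passing tests do **not** show about real data: the generator has no
speckle statistics, no attenuation/shadowing artifacts, no posterior
enhancement, no operator variability in segmentation, and its class signal
is a known additive offset rather than morphology. Results on it validate
the *pipeline* (geometry, crops, features, selection, evaluation), not
clinical discrimination performance.

## Experiment harness and study conditions

`run_grid` evaluates every enumerated strategy on a disjoint train/test
cohort pair: per strategy a backbone is fine-tuned on that strategy's
training crops (a `share_backbone` flag reuses one backbone instead; the
default re-tunes per strategy since the two choices are both defensible and
re-tuning is the more conservative reading), features are extracted, the
chain and classifier are fitted on training rows, and train/test metric rows
are recorded. Per-strategy seeds derive from the master seed and the model
name (CRC32), so results are independent of enumeration order; a case whose
crops cannot be built aborts the grid with its case id. Two runs with one
master seed produce byte-identical CSVs in single-threaded mode
(`set_single_threaded()`; the CLI and acceptance script enforce it).

Desk-scale study conditions (chosen once): cohorts of 400 (300/100
train/test) for the margin-recovery experiment and 200 (150/50) for the
full-grid run, 128x128 images, `vgg16-tiny` backbone, 5 fine-tuning epochs,
margins {4, 10} for recovery and {2, 4, 6, 8, 10} for the full grid. The
headline recovery property: with signal confined to lesion + 4 mm rim, the
best fusion model at margin ≤ 4 mm attains test AUC ≥ the best intratumoral
model in ≥ 8 of 10 seeds, and margin-10 models do not beat margin-4 models
on average. Bootstrap replicates are reduced (0–200) where only point
estimates are consumed.

## Known limitations

* Seeded-random convolution filters are untrained texture projections;
  absolute AUCs on the synthetic cohort are not comparable to a pretrained,
  fine-tuned VGG16 on clinical CEUS data.
* The Mann-Whitney filter uses scipy's exact p only where scipy chooses it
  (small samples without ties), the normal approximation otherwise.
* The DeLong p-value is asymptotic; for very small test cohorts the
  bootstrap CIs are the more trustworthy uncertainty statement.
* DICOM support is read-only (PixelSpacing consumed, not written); cohorts
  are written as 8-bit PNG, which quantizes intensities to 1/255.
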