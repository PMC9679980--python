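# Methods

`thermoseq` models the relationship between a protein's amino-acid sequence
and a scalar thermal trait — the optimal growth temperature (OGT) of its
source organism, the enzyme's catalytic optimum T_opt, or its melting
temperature T_m, all in °C — and provides the machinery to interrogate what
such a model has learned. This note records the model, the conventions and
numerical choices behind each component, what the synthetic benchmark does
and does not establish, and known limitations.

## The regressor

Sequences over the 20 standard amino acids are one-hot encoded into an
`L_max x 20` matrix under the fixed alphabetical column order
`ACDEFGHIKLMNPQRSTVWY`, post-padded with zero rows (an encoded residue
contributes exactly one unit of mass, padding none). The network is a 1-D
residual CNN:

```
input (L_max x 20)
  -> conv(f filters, kernel s, same padding) -> BN -> ReLU
  -> n_blocks x [conv -> BN -> ReLU -> conv -> BN, + identity skip, ReLU]
  -> max-pool(pool p, stride w, valid)
  -> flatten                                  # the sequence representation
  -> dropout -> dense(d_0) -> BN -> ReLU -> dropout
  -> dense(1, linear)                         # predicted temperature, °C
```

The flatten width is `f * (floor((L_max - p) / w) + 1)`. The default
configuration — input length 2000, one residual block of 512 filters,
pool 50 / stride 50 — yields a 20,480-dimensional representation; the
scaled-down configuration used throughout the test suite (input 128,
16 filters, pool 8 / stride 8) yields 256.

Design conventions, fixed where several readings were possible:

- **Entry convolution.** A same-padded convolution precedes the first
  residual block so the identity skip adds tensors of equal channel width;
  the alternative (projection shortcut) was rejected as heavier.
- **Batch normalization** follows every convolution and hidden dense layer,
  before the ReLU; the final linear output has no BN. Momentum 0.9,
  eps 1e-5, running statistics for inference.
- **Dropout** (default rate 0.3; 0.1 in the small test configuration) is
  standard inverted activation dropout after the flatten and after the
  hidden dense layer. A DropConnect-style weight dropout would be an
  alternative; activation dropout was chosen for simplicity and an
  equivalent test surface.
- **Initialization** is scaled-uniform with Glorot fan-based bounds, seeded
  from `ModelConfig.seed`.

The network, backpropagation, and the Adam optimizer (β₁ 0.9, β₂ 0.999,
eps 1e-8) are implemented directly on numpy in float32; convolutions run
as im2col matrix products. Training minimizes mean squared error.
Reproducibility contract: identical seeds give identical runs on one
platform within floating tolerance; bit-exactness across platforms is not
promised. There is no early stopping — epochs are explicit.

**Output-bias warm start.** At the start of training, if the output layer
is trainable, its bias is set to the mean training label. Thermal labels
sit tens of °C from zero; without the warm start the optimizer spends most
of a desk-scale budget climbing that constant offset, perturbing every
weight along the way. With it, capacity goes immediately to
sequence-dependent structure. A frozen head (see below) is never touched.

## Transfer modes

`set_transfer_mode` prepares a pretrained model for a target task:

| mode | weights | trainable |
|---|---|---|
| `from_scratch` | re-initialized from the config seed | all |
| `frozen_all`   | kept | none |
| `frozen_cnn`   | kept | dense head only |
| `tune_all`     | kept | all |

Freezing is strict: a frozen batch-norm layer runs in inference mode even
during fine-tuning, so neither its affine parameters nor its running
statistics move. Consequently, under `frozen_cnn` the whole pre-flatten
extractor — and therefore the flatten-layer representation of any
sequence — is bitwise identical before and after fine-tuning. This is an
invariant the test suite checks exactly.

In the repeated-seed benchmark (pretraining on 5,000 synthetic records,
fine-tuning on a correlated 200-record target), both arms receive the same
15-epoch fine-tuning budget. The short, equal budget is deliberate: it is
the small-data regime the transfer protocol targets, and longer budgets
mainly let the from-scratch arm overfit the easy synthetic target with
large seed-to-seed spread.

## Occlusion relevance

The relevance of residue positions is measured model-agnostically by
occlusion. For a window width `k` (default 5, matching short secondary
structure elements):

1. The sequence is flanked on each side by `k - 1` copies of its terminal
   residue, so every original position is covered by a full complement of
   `k` windows. (The flanking construction is a convention of this package;
   it simultaneously realizes a moving average over window scores as the
   mean over covering windows.)
2. Every window position (stride 1) is occluded by zeroing its one-hot
   rows — the same content as padding, hence in-distribution for the
   model — and scored as `(pred_occluded - pred_wt) / pred_wt`.
   A zero unperturbed prediction makes the relative score undefined and is
   reported as an error; synthetic labels are kept strictly positive so
   this cannot arise in the benchmark.
3. A residue's raw score is the mean over its covering windows; the profile
   is standardized per protein, `z = (s - mean) / sd` (a flat profile gets
   all-zero z), and positions with `|z| > 2` (strict) are significant.
   Per-cohort standardization is available by standardizing concatenated
   scores externally; per-protein is the default because the profile is a
   per-protein object.

`stability_check` reports the Jaccard overlap of significant sets across
widths (default 2, 5, 10, 20); two empty sets overlap 1.0 by convention.

**Enrichment.** Categories (amino acids, or DSSP 8-state codes from
precomputed annotations) are tested for over- and under-representation at
significant positions against the pooled background with one-sided
hypergeometric tails. Positions whose annotation character falls outside
the declared alphabet are treated as unannotated and excluded from both
background and foreground counts. Verdicts use raw p-values at α = 0.05 by
default; a Benjamini–Hochberg per-tail adjustment is available
(`correction="benjamini-hochberg"`) but off by default to match the
protocol the package reproduces.

**Domain coverage.** For a domain of length `d` in a protein of length
`L`, coverage is the fraction of its positions flagged significant. Only
domains with `d <= L/2` are scored (eligibility), so an outside control
exists. The control slides windows of length `d` (stride 1) within each
contiguous outside segment; with `n_windows = Σ max(0, seg_len - d + 1)`,

```
control = (#significant outside) / n_windows / d .
```

If no full outside window fits, the control is reported as missing. Note
this control is a per-window expected-count normalization, not an unbiased
estimate of outside coverage: under uniformly random significance it scales
like `coverage / d` for `d << L`. The package keeps this definition for
protocol fidelity and the property tests check it against its own analytic
expectation, not against the coverage rate. `select_domains` returns
eligible domains at coverage ≥ 0.30 (default), best first, ties broken by
name.

## Classical descriptors

Twenty families totalling exactly 5,494 features, with parameters
back-derived from the canonical widths: k-spaced pair families (CKSAAP
2400, CKSAAGP 150) use gaps 0–5; Moran, Geary and normalized Moreau–Broto
autocorrelations use 8 physicochemical scales × 30 lags (240 each); PAAC
uses λ = 30, weight 0.05 (50); APAAC λ = 30 (80); the sequence-order
families use 30 lags over two 20×20 distance matrices (SOCNumber 60,
QSOrder 100, weight 0.1); CTD uses 13 three-class property groupings
(39/39/195); conjoint triads use the 7-class partition (343), with the
k-spaced variant at gap 0. Lag-based families require sequences longer
than 30 residues; the standard length filter (≥ 100) guarantees this.

Constant tables are vendored in `descriptors/_tables.py` with their
customary identifiers (AAindex entries for the autocorrelation scales, the
classic CTD groupings, Chou's PAAC scales). The Grantham distance matrix is
computed at import from Grantham's published composition/polarity/volume
components and formula, normalized to mean 100 (spot checks: d(L,I) ≈ 5,
d(R,S) ≈ 110, d(W,C) ≈ 215, matching the published matrix). The second
sequence-order matrix is this package's own physicochemical distance, built
from the normalized hydrophobicity/hydrophilicity/side-chain-mass scales
(the same ingredients as the classic sequence-order distance) and scaled to
unit mean off-diagonal.

Degenerate cases: autocorrelations of a sequence whose property values are
all equal (homopolymers) are defined as 0; distribution descriptors of an
absent CTD class are 0.

**Scaling.** `fit_scaler`/`apply_scaler` standardize features; constant
columns map to 0. The reference protocol fits the scaler on all samples
pooled (train and test together); that mode is reproduced for fidelity, but
fitting on the training block only — as in the descriptor-baseline
example — is the leakage-free default recommendation.

## Data assembly

- `split` partitions uniformly at random with `|test| = floor(fraction·n)`.
  Floor is fixed deliberately; published corpus splits round inconsistently
  between floor and ceil, and one rule had to be chosen (a 1,902-record set
  at 10% gives 190 test records under floor).
- `uniform_subsample` rebalances a skewed label distribution for
  hyperparameter tuning: labels are binned into `bin_width`-degree bins
  (default 5 °C) anchored at `floor(min/width)·width`; the target size is
  divided as evenly as possible across non-empty bins; each bin contributes
  `min(quota, count)` records without replacement. Underfull bins are
  exhausted, never resampled — duplicates would be worse than a logged
  shortfall.
- `aggregate_mean_label` collapses repeated measurements per id to the
  arithmetic mean. `remove_overlap` drops records by id against an
  exclusion list (e.g. to de-overlap a pretraining corpus from a target
  set). Sequence-identity clustering is out of scope; the module only
  consumes a representative-id list if one is supplied.

## Synthetic benchmark

The generator emulates the statistical shape of thermal-trait corpora at
desk scale. Sequences are i.i.d. draws from configurable background
frequencies (uniform by default); a 5-residue motif (`FWYHC`, 0–4
occurrences, +2.5 °C each) is written over the background at recorded
non-overlapping positions; labels are base 30 °C plus motif and
composition effects plus N(0, 2 °C) noise, strictly positive by
construction. Default lengths are 100–120 so flank-extended occlusion
inputs still fit the 128-residue test architecture. Fake annotations carry
a planted truth: secondary-structure strings are run-length sampled over
the DSSP codes with motif positions forced to `G`, and each motif
occurrence lies inside a recorded eligible domain (plus one random decoy
per sequence).

Label-imbalance emulation (`emulate_imbalance`, and the
`label_distribution` option) draws labels from a target mixture or
histogram and absorbs the difference into a per-record intercept recorded
in the ground-truth sidecar; in those modes labels are reproducible but no
longer a global function of sequence alone.

What passing the benchmark shows: the training loop can recover a planted
local sequence determinant from realistic label noise (median holdout
R² ≈ 0.6 against a noise ceiling of ≈ 0.76 at these settings); occlusion
attributes predictions to the planted positions; transfer from a related
task helps when target data are scarce. What it does not show: performance
on real proteins — synthetic sequences have no homology structure, no
realistic secondary-structure statistics, no length/composition
covariation, and a single additive determinant, all of which real corpora
violate. Reproducing published real-data accuracies requires the
million-scale corpora and GPU-scale training those studies used, and is
explicitly out of scope.

## Problem sizes and runtime choices

The repeated-seed suites use 2,000-record training sets (5 seeds, 40
epochs, batch 64, learning rate 1e-2) for signal recovery, and a
5,000-record pretraining set with 200-record targets (15-epoch equal
budgets) for the transfer comparison — sizes at which the full suite runs
on a single CPU in minutes while leaving clear margins on every
statistical assertion.

## Known limitations

- The numpy network trains small configurations comfortably but is not a
  platform for million-sequence corpora; no GPU, no data parallelism.
- Welch's t is the only run-comparison test provided; the one-sided p is
  reported for the alternative mean(a) > mean(b).
- Hypergeometric enrichment pools positions across proteins, treating them
  as exchangeable draws; within-protein correlation of significance calls
  is ignored, as in the protocol it mirrors.
- The second sequence-order distance matrix is a reconstruction from
  standard scales, not a byte-identical copy of the classic matrix;
  descriptor values in the sequence-order families will differ slightly
  from tools vendoring the original table (dimensions and structure are
  identical).
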