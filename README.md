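# thermoseq

Thermal-trait regression from protein sequence: a residual convolutional
network that maps amino-acid sequences to temperature labels (optimal
growth temperature, catalytic optimum T_opt, melting temperature T_m, in
°C), transfer learning with selective layer freezing, occlusion-based
per-residue interpretation, and a 5,494-feature classical descriptor
baseline — plus a synthetic-data generator with planted, recoverable
signal so every component is testable at desk scale.

**Who it is for.** Computational biologists and ML practitioners studying
protein thermal adaptation: predicting thermal traits from sequence alone,
reusing a pretrained temperature representation on small labeled sets, and
asking *which residues* a trained model relies on.

## The model

Sequences are one-hot encoded (`L_max x 20`, alphabet `ACDEFGHIKLMNPQRSTVWY`,
zero post-padding) and passed through

```
conv(f, kernel s, same) – BN – ReLU
  → 1–3 residual blocks (conv–BN–ReLU–conv–BN + identity, ReLU)
  → max-pool(p, stride w, valid) → flatten
  → dropout → dense(d₀) – BN – ReLU – dropout → dense(1)
```

trained with Adam on mean squared error. The flatten layer, of width
`f · (⌊(L_max − p)/w⌋ + 1)` — 20,480 for the default 2000-residue input
with one 512-filter block and 50/50 pooling — is a reusable
temperature-related representation of the sequence. Transfer modes:
`from_scratch`, `frozen_all`, `frozen_cnn` (dense head only; the frozen
extractor, batch-norm statistics included, stays bit-identical), and
`tune_all`.

Interpretation is by occlusion: a sliding window of the input is zeroed,
the relative prediction change `(pred_occluded − pred_wt)/pred_wt` is
averaged over the windows covering each residue, standardized per protein,
and positions with |z| > 2 are called significant — then tested for
amino-acid / secondary-structure enrichment (one-sided hypergeometric,
α = 0.05) and domain coverage against an outside-window control.

The network and optimizer are implemented directly on numpy (float32,
im2col convolutions, manual backpropagation); see `docs/methods.md` for
every convention and numerical choice.

## Worked example

`examples/02_train_and_evaluate.py` generates 1,000 synthetic records
(labels = 30 °C + 2.5 °C per planted motif occurrence + N(0, 2) noise),
trains the scaled-down configuration, and scores the holdout:

```
train 900 / test 100
epoch 1 loss 11.0 -> epoch 30 loss 1.5 (degC^2)
holdout: R2=0.598 RMSE=2.35 degC pearson=0.789 (n=100)
```

With label noise of sd 2 °C the best achievable RMSE is 2, so 2.35 °C
means the planted determinant is essentially recovered. Probing that model
by occlusion (`examples/04_relevance_analysis.py`) pins the signal to the
planted positions:

```
40 profiles; 6.8% of positions significant (|z| > 2)
  ss code G: 244/304 significant vs 471/4464 background, p_over=4.6e-207 -> enriched
domains with >=30% significant coverage: 33 (33 of them motif-bearing)
```

`G` is the secondary-structure code the generator plants at motif
positions: the model's significant positions are overwhelmingly the
planted ones, and every domain selected at the 30% coverage cutoff
contains a motif. The remaining examples cover encoding and filtering
(`01`), transfer learning (`03`), the descriptor baseline (`05`), and
hyperparameter search (`06`); each prints its own numbers with a line on
what they mean.

A command-line interface wraps the same library for shell use
(`thermoseq simulate | features | train | transfer | predict | represent |
relevance | enrich | domains | evaluate | tune`); every command writes a
manifest with seeds and output checksums.

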