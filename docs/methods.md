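# Methods

## Problem and model

Back-splicing joins a downstream splice donor (SD) to an upstream splice
acceptor (SA), producing a circular RNA. `circsplice` frames back-splice
site recognition as binary classification of a *pair* of 100-nt RNA
windows: the SA window (50 nt of upstream intron, then 50 nt of exon) and
the SD window (50 nt of exon, then 50 nt of downstream intron). The
splice boundary always sits between window indices 49 and 50 (0-based);
`boundary_index = 50` names the first nucleotide 3' of the site.

Windows are one-hot encoded over (A, C, G, U); `N` becomes an all-zero
row, and samples with more than 10% `N` are rejected at load time.
DNA-alphabet input (T, lowercase) is canonicalized to uppercase RNA.

The classifier is a dual-branch convolutional network. Each branch
processes one window:

    conv1 (valid, stride 1) -> ReLU -> dropout
    conv2 ('same', stride 2) -> ReLU -> dropout
    max-pool (5, stride 5)   -> dropout -> flatten

The two branch vectors are concatenated, batch normalized, and mapped to
a probability by a dense sigmoid unit. The branches do **not** share
weights: SA and SD contexts carry different signals, and separate
filters avoid interference between them. Training minimizes binary
cross-entropy with RMSProp (rho 0.9), early stopping on validation loss,
and restoration of the best-validation weights.

With the default hyperparameters the per-branch shapes are

    input (100, 4) -> conv1 (89, 256) -> conv2 (45, 128)
    -> pool (9, 128) -> flatten (1152) -> concatenate (2304)

`shape_contract()` computes this table analytically for any
configuration; the same shapes are observable from a live forward pass
via `TrainedModel.forward(..., collect=True)`.

The network is implemented directly on numpy (forward, backprop and the
optimizer are hand-written in `circsplice._nn`). Convolutions are
evaluated as flattened im2col GEMMs; gradients were validated against
central finite differences in float64 (see the gradient tests).

### Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| `conv1_kernels` / `conv1_size` | 256 / 12 | motif-scanner layer; width 12 valid convolution |
| `conv2_kernels` / `conv2_size` | 128 / 30 | abstraction layer; 'same' padding, stride 2 |
| `pool_size` / `pool_stride` | 5 / 5 | non-overlapping max-pooling |
| `dropout1`, `dropout2` | 0.7 | after conv1 and conv2 (the post-pool dropout reuses `dropout2`) |
| `batchnorm` | true | after concatenation, before the dense unit |
| `learning_rate` | 1e-3 | RMSProp step size |
| `batch_size` | 1024 | |
| `max_epochs` | 100 | hard cap |
| `early_stopping_patience` | 20 | consecutive non-improving validation epochs |
| `validation_fraction` | 0.1 | stratified split carved from the training set when no validation set is given |

Choices the architecture description leaves open, resolved here: ReLU
after each convolution (required for the non-negative activation-score
reading used by motif extraction), sigmoid output with binary
cross-entropy, validation-loss early-stopping monitor, and unshared
branch weights. The 'same'-padded stride-2 convolution maps length
89 to ceil(89/2) = 45 and pooling maps 45 to floor(45/5) = 9 — the only
reading consistent with the published per-layer output shapes.

### Compact configuration

`compact_config()` is a smaller instance of the same topology
(32/16 kernels, conv2 width 12, dropout 0.2, batch 256, max 40 epochs,
patience 6) used by the test suite and the CLI `--compact` flag so that
7-fold cross-validation on the standard synthetic benchmark completes in
minutes on one CPU. The full-size defaults remain the reference
configuration for the shape contract.

## Dataset construction

`build_window` assembles windows from intron/exon flanks, trimming each
flank to the 50 nt proximal to the splice site and rejecting sites where
either flank is shorter than 50 nt. Duplicate instances are removed by
exact `(sa_seq, sd_seq)` identity (the loader may lack genomic
coordinates, so sequence identity is the dedup key). Negative instances
pair the canonical donor of exon *i* with the canonical acceptor of exon
*i+1* or *i+2* of the same transcript (a linear junction covering two or
three exons), drawn uniformly without replacement, excluding any pair
whose coordinates appear among the positives. Fold assignment for
cross-validation is stratified by label (fold sizes within each class
differ by at most 1) and deterministic per seed; both 7-fold
cross-validation and a holdout split are supported, with cross-validation
as the default mode.

## Synthetic benchmark

`synthetic.simulate_dataset` generates labeled window pairs with planted
motifs. Background sequence is i.i.d. per position from a configurable
composition (uniform by default). Each positive receives each
`PlantSpec` independently with its `plant_probability`; the realized
instance is drawn column-wise from the plant's PWM and written over the
background at a start position drawn from the plant's offset
distribution (uniform over the designated 50-nt side unless explicit
offsets are given). Negatives are pure background. A ground-truth log
records every realized plant (sample, plant, start), enabling recovery
tests.

The default fixture (`default_fixture_config`) is the standard
benchmark used throughout: 2000 positives + 2000 negatives, two sharp
10-mer PWMs (0.85 consensus probability per column) planted with
probability 0.9 — one in the SA upstream intron, one in the SD exon —
both at fixed start 20 so positional recovery has a well-defined target.
The fixture emulates the side-specific enrichment contrasts seen around
real back-splice junctions, *not* real genomes: real flanking sequence
has higher-order composition, repeats and correlated motif placement
that the i.i.d. background omits. Passing recovery tests therefore
demonstrates that the pipeline can find and localize genuine signals of
this strength, but says nothing about the harder discrimination problem
posed by genomic negatives.

## Motif interpretation pipeline

The first convolution layer's post-ReLU output assigns every window
position a score under every filter (a candidate-motif evaluation
matrix). The pipeline converts filters to motifs as follows:

1. **Subsequence selection** — for each filter, take the single
   best-scoring L-mer (L = `conv1_size`) from each positive sample,
   provided its score is strictly positive; ties break to the leftmost
   position; L-mers containing N are skipped. This argmax-per-sequence
   rule is the standard first-layer visualization convention for
   convolutional sequence models; it bounds a filter's support by the
   number of positive samples and is deterministic.
2. **PPM** — per-position nucleotide counts over the selected
   subsequences, divided by the number of subsequences. No pseudocounts
   are added; the MEME writer can optionally mix in 1e-6 smoothing for
   downstream tools that reject exact zeros (off by default). PPM width
   equals the kernel width; `trim_low_information` optionally strips
   flanking columns with information content below 0.1 bits.
3. **MEME export** — minimal motif format (`MEME version 4`,
   `ALPHABET= ACGU`, background frequency line, one letter-probability
   block per filter with `nsites=` support), suitable for external
   comparison tools such as TOMTOM. `parse_meme` reads the files back;
   the round trip is exact to 6 decimals.
4. **Occurrence scanning** — every position whose activation is at
   least `threshold_fraction` (default 0.5) of the filter's maximum over
   the scanned set becomes an occurrence. Positions are assigned to the
   intron or exon side of the window by the *center* of the filter's
   receptive field (SA: positions < 50 are intron; SD reversed).
   Per-position occurrence densities are normalized by the number of
   scanned sequences per class, so a profile sums to the mean occurrence
   count per sequence; a moving-average smoother (window 5) is available
   for plotting only.
5. **PPM set comparison** — best ungapped alignment between two PPMs
   over all offsets with at least `min_overlap` (default 5) columns,
   scored by the mean per-column Pearson correlation of probability
   vectors; pairs scoring at least 0.8 are reported. This is an
   internal, documented approximation of cross-set motif matching (it
   produces match/offset pairs, not E-values); exported MEME files are
   the route to statistically calibrated matching.

## Evaluation

`compute_metrics` reports accuracy, AUC, MCC, sensitivity and
specificity plus the confusion counts. Hard calls use threshold 0.5
(configurable). AUC uses the midrank tie convention (ties count 1/2),
equivalent to trapezoidal ROC integration; it is NaN for single-class
inputs, in which case the remaining metrics are still returned. MCC
uses the convention 0 when any factor of its denominator is 0.
Cross-validation trains one model per fold on the remaining folds (with
an internal stratified validation split for early stopping) and tests
each sample exactly once; reported summaries are the arithmetic mean
over folds and the best fold, with the best-AUC fold's model used for
motif extraction. The ablation harness runs the three head variants —
batch normalization, no normalization, and dropout in place of
normalization — under identical fold assignments for paired comparison.

## Numerical and reproducibility notes

- All randomness (initialization, shuffling, dropout, simulation,
  splits) flows through seeded numpy generators; identical seeds give
  byte-identical datasets and identical predictions.
- Parameters are float32; batch normalization uses eps 1e-3 and running
  statistics with momentum 0.9 (inference mode uses the running
  statistics, making predictions batch-size invariant).
- Probabilities are clipped to [1e-7, 1 - 1e-7] inside the loss only.
- Model checkpoints are single `.npz` archives holding the config
  (JSON), all parameter arrays and BN buffers; loading reproduces
  predictions bit-exactly, verified by a SHA-256 parameter hash.
- Early stopping with patience 0 stops after the first non-improving
  epoch; the epoch count never exceeds `max_epochs`.

## Problem sizes used by the test suite

Unit tests run miniature architectures (a few kernels) on 100-300
sample datasets. The end-to-end checks use the default synthetic
fixture (2000+2000) with the compact configuration: 7-fold
cross-validated recovery, a plant-probability-0 null control (capped at
8 epochs — chance-level AUC does not change with longer training), and
a 3-fold ablation comparison capped at 20 epochs. These sizes keep the
full suite in the tens of minutes on a single CPU.

## Known limitations

- The i.i.d. background understates the difficulty of real negative
  sets; reported synthetic AUCs are not comparable to performance on
  genome-derived data.
- The argmax subsequence rule yields at most one motif instance per
  sequence per filter; motifs occurring multiple times per window are
  under-counted in PPMs (occurrence scanning does count them).
- PPM-set comparison is correlation-based and ungapped; it has no null
  model, so match scores are comparable within this package but are not
  E-values.
- The dataset builder consumes a simplified exon/intron structure
  table; it does not parse annotation formats (GTF/GFF) or fetch
  genomes.
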