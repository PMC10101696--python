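# Methods

This note records the model, the numerical conventions, the synthetic data
generator and the open design choices of `ccaae`, in enough detail to
re-derive every number the package prints.

## Model

Five trainable components operate on a shared latent space of dimension
`d` (default 50; the synthetic studies and tests use 8):

| component | default architecture | role |
|---|---|---|
| `E_rna`, `E_atac` | MLP, two hidden layers of 64, leaky-ReLU (slope 0.2), linear output | encode each modality into the coordinated subspace |
| `D_rna`, `D_atac` | mirror-image MLPs | decode latent points back to feature space |
| discriminator | MLP, one hidden layer of 64, sigmoid output | probability a latent point came from the RNA encoder |
| classifier | single linear layer + softmax | cell-type prediction from the latent |

All weights are He-initialised from named, per-network substreams of one
seed, so any subset of the model can be rebuilt bit-identically.

### Losses and conventions

* Distance `d(·,·)` defaults to squared Euclidean **averaged over
  dimensions**; `l1` (dimension-averaged) and `l2` are configurable. The
  averaging makes loss magnitudes comparable across latent and feature
  spaces.
* Reconstruction and cycle losses are means over cells of the row-wise
  distance; the cycle runs *through the other modality's decoder and
  encoder* and is compared in latent space.
* Adversarial training uses the standard GAN form: the discriminator
  minimises label BCE (RNA = 1, ATAC = 0) on embeddings treated as fixed
  inputs; the encoders minimise the flipped-label, non-saturating BCE
  through the live path. BCE is computed from logits via softplus for
  stability. Reported discriminator probabilities are clamped to the open
  interval (0, 1) where float64 saturates.
* The triplet loss applies a hinge `max(0, d(a,p) − d(a,n) + α)` with
  margin `α = 1` by default. Mining is exhaustive within the current
  mini-batch pool (both modalities concatenated and treated equally):
  positive = farthest same-label point, negative = nearest other-label
  point, ties broken by lowest index, anchors never matched to
  themselves. Anchors whose label has no second member are skipped; a
  degenerate batch with a single label contributes zero contrastive loss
  for that step. Full-dataset mining would be quadratic per step and is
  deliberately not done.
* Classifier loss is mean negative log predicted probability of the true
  class over the pooled embeddings.
* The MMD ablation replaces the adversarial game with an **unbiased**
  multi-kernel Gaussian MMD² (bandwidths 0.5/1/2/4, diagonal terms
  omitted, clipped at zero).
* The anchor (pairwise-supervision) term is the mean latent distance over
  known cell pairs; its weight is 0 by default — the method is
  unsupervised with respect to pairing.
* All loss weights default to 1 (reconstruction and adversarial terms are
  trained with equal weight).

### Two-stage optimisation

Each outer iteration runs `k1` generator-group steps followed by `k2`
discriminator steps, with Adam (β = 0.9/0.999) and fixed iteration
budgets (no early stopping, so runs are deterministic). Mini-batches
(default m = 64) are drawn independently per modality with replacement.
Defaults: `k1 = 1`, `k2 = 2`, generator lr 1e-3, discriminator lr 1e-3,
2000 outer iterations. Giving the discriminator two steps per iteration
at the full learning rate is a deliberate choice: with a slow,
once-per-iteration critic the two latent clouds align only at cluster
granularity and pair-level alignment stalls; a critic that keeps pace
with the encoders (standard GAN practice) is what forces the
within-cluster fine structure of the two clouds together. The
literature's alternating-descent presentation leaves `k1`, `k2` and the
learning-rate ratio free; the 1/(2m) versus 1/m gradient scaling of the
two stages is absorbed into the learning rates.

Every random draw (initialisation, splitting, per-modality batch
sampling for both stages) comes from a named substream of the single run
seed. Consequences: identical seeds give bitwise-identical training logs
and evaluation reports, and a joint run with all weights except
reconstruction at zero reproduces two separately trained autoencoders
exactly (verified bit-for-bit in the tests).

Non-finite loss values abort training immediately, naming the component.

## Synthetic data generator

The generator emulates a paired co-assay with known ground truth:

1. `k` cell-type centroids are drawn from an isotropic Gaussian with
   scale `centroid_scale = 3` in a true latent space of dimension 10;
   cells get their type's centroid plus isotropic jitter (sd 1). With
   these defaults inter-centroid distances are several times the
   within-type spread.
2. Cells are allocated to types by largest remainder (deterministic;
   uniform proportions give counts differing by at most 1).
3. Each modality view is an independent random linear map of the latent
   (Gaussian weights, scaled by 1/sqrt(latent dim)) passed through tanh —
   the two views share only the latent, so cross-modal matching must go
   through the latent structure.
4. Isotropic Gaussian noise is added per modality with variance set so
   that `10·log10(var(signal)/var(noise))` equals the requested SNR in
   dB, measured on the whole matrix (global, not per-feature —
   documented choice; the per-feature reading would differ only through
   feature-variance heterogeneity of the tanh signal). `snr = inf`
   disables noise. An optional dropout mask can zero a fraction of ATAC
   entries (off by default).
5. The signal/noise decomposition, the true latent and the type index are
   stored in `PairedDataset.meta`, so the realised SNR is recomputable
   (`snr_empirical`); at the default sizes it lands within ±0.5 dB of the
   target.

Interpretations pinned here because they are not derivable elsewhere: SNR
values 0–25 are decibels (a *linear* ratio of 0 would mean no signal at
all, making any recovery impossible), and values are continuous reals,
not counts. The standard study grid is 4 sizes (1200/2100/3000/6000) × 6
SNRs (0/5/10/15/20/25 dB); `paper_grid()` builds the 24 configurations.

What the generator does **not** emulate: zero-inflated count
distributions, per-cell depth variation, batch effects, doublets. Passing
tests on this generator demonstrate that the optimisation recovers shared
low-dimensional structure under additive noise — they do not certify
performance on real chromatin data.

## Preprocessing

Fixed order: optional `log1p` (RNA default on, refused on negative values
and refused twice via provenance tracking), optional binarisation (ATAC,
default off), optional per-feature z-scoring (default on, population
convention ddof = 0, zero-variance features centred and left at zero).
Applied steps are recorded in the matrix's provenance and written next to
exported files. The synthetic views are used as generated (they are
already continuous and roughly centred); real count data should keep the
defaults. Matrices round-trip exactly through CSV and MTX (17
significant digits, round-trip float parsing).

Cells are paired across modalities by cell identifier when the two sides
share barcodes, else by row order with a loud warning. Splits are
stratified by label (80/20 by default), deterministic given the seed, and
never separate the two sides of a pair. Features enter the encoders as
preprocessed — there is no PCA or HVG pre-reduction stage.

## Evaluation

Exact brute-force nearest neighbours throughout (n is small; exactness
enables oracle tests). Integration accuracy: nearest RNA embedding by
Euclidean distance shares the ATAC cell's label. Recall@k: the true
paired RNA embedding is within the k nearest, ties resolved by (distance,
then lower index); this pair-level reading is what distinguishes
alignment from integration, and a `by_label` flag offers the
type-membership alternative. Metrics are reported on the held-out split.
Label transfer assigns each ATAC cell its nearest RNA embedding's label.

## Problem sizes used in the shipped studies

The default study (acceptance script, end-to-end tests) uses 1200 cells,
4 balanced types, 25 dB, RNA/ATAC dimensions 200/300, latent 8, 2000
outer iterations — about a minute on one CPU. The ablation study runs at
0 dB with 800 iterations per variant and 3 seeds, comparing the full
model against no-cycle-no-contrastive and no-adversarial variants;
directionally, removing cycle+contrastive collapses integration accuracy
(≈0.45 vs 1.0 at 0 dB) while the adversarial and no-adversarial variants
tie at this noise level. These sizes were chosen as the smallest at which
the phenomena of interest are stable across seeds.

## Known limitations

* Pair-level recall plateaus near 5–6× chance on the default study:
  nothing in the unsupervised objective pins within-cluster coordinates
  beyond what cycle consistency and the critic enforce, so exact-partner
  recovery is intrinsically partial. The anchor term exists for the
  supervised setting.
* Two modalities only; no variational latent; no convolutional or graph
  encoders.
* Dense matrices at the model boundary — intended scale is tens of
  thousands of cells at most.
* The convenience scatter plot is an untested extra (`plot` extra
  installs matplotlib); embeddings are exported as CSV for any external
  t-SNE/UMAP tool.
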