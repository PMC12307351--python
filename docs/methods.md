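# Methods

This note documents the models implemented in `modfus`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Overview

`modfus` classifies subjects as Parkinson's disease (PD) or healthy control
(HC) from two modalities: a 3-D T1-style brain volume and four clinical
rating-scale scores (MDS-UPDRS motor section, STAI, ESS, CDT). The pipeline
has four stages:

1. **Prompt generation** — each scale score is binned against severity
   breakpoints, the severity label is substituted into a per-scale sentence
   template, and the sentence is expanded into `N` lexically diverse
   paraphrases (default `N = 8`).
2. **Contrastive alignment** — a text encoder and an image encoder are
   pretrained so that a subject's prompt and volume embed close together in a
   shared d-dimensional space (default `d = 512`), using a symmetric
   temperature-scaled InfoNCE objective with `τ = 0.1`.
3. **Cross-modal attention (CMA) fusion** — pre-pooling token sequences from
   both encoders interact through bidirectional 8-head attention:
   text-enhanced image tokens `I*` (image queries, text keys/values) and
   image-enhanced text tokens `T*` (text queries, image keys/values), both
   computed from the same inputs in one pass.
4. **Classification** — `[I*; T*]` is collapsed to a single vector by a
   softmax self-attention reduction and classified by a two-layer network.
   Training minimises `L = λ·L_align + (1−λ)·L_cls` with `λ = 0.54`, where
   `L_align = 1 − cos(Ī*, T̄*)` on the pooled enhanced features and `L_cls`
   is binary cross-entropy on the PD-class softmax probability.

Evaluation is stratified K-fold cross-validation (default `K = 5`) with
ACC/precision/recall/F1 from the confusion counts, Mann–Whitney AUC (ties
half-credited), and per-metric mean `M` and *population* dispersion
`σ_M = sqrt((1/K) Σ (M_k − M)²)` (divisor `K`, not `K − 1`).

## Clinical scales and prompt generation

Severity bins are half-open `[lo, hi)` with the final bin closed at the range
maximum. Shipped defaults use conventional clinical bands and are fully
overridable through a YAML file (no threshold is hard-coded):

| scale | range | breakpoints | orientation |
|---|---|---|---|
| MDS-UPDRS (part III) | 0–132 | 15 / 33 / 59 | higher = worse |
| STAI | 20–80 | 38 / 45 / 55 | higher = worse |
| ESS | 0–24 | 6 / 11 / 16 | higher = worse |
| CDT (Shulman 0–5) | 0–5 | 2 / 3 / 4 | **lower = worse** (`invert`) |

Labels are ordered ("Mild", "Moderate", "Significant", "Serious"); no
"normal/none" band below "Mild" is defined, and the MDS-UPDRS input is
treated as a single numeric (motor-section) score. Paraphrase augmentation is
a deterministic substitution bank (phrase → synonym table); a variant is one
choice per applicable rule, sampled without replacement with a seeded
generator, so prompt sets are a pure function of (record, config, seed).
Severity labels never occur in any substitution rule, which guarantees the
round-trip property: every variant decodes back to its originating label by
substring match. External paraphrasers (e.g. an LLM service) can be plugged
in through the `Augmenter` protocol; nothing in the default path calls any
hosted model. The four per-scale sentences are joined in the fixed order
MDS-UPDRS, STAI, ESS, CDT; during training one variant per scale is sampled
uniformly per epoch, at inference the template sentences (variant 0) are
used.

## Encoders

The `tiny` preset is a pair of small pre-norm transformers trainable from
scratch, standing in for large pretrained backbones while preserving the
framework's structure (patch/word embedding → stages → shared projection):

* **image**: cubic patches (default 8³ voxels) → linear embedding
  (`d_model`, default 32) → `depth` self-attention stages → linear projection
  of every token to the shared space; the pooled embedding is the token mean.
  No positional embedding is used: the phantom task is content-addressable,
  and this keeps the encoder shape-agnostic.
* **text**: word-level tokenizer (UNK id 0, PAD id 1; vocabulary ordered by
  count desc, token asc) → token + positional embeddings → `depth`
  transformer layers with PAD keys masked → shared projection; the pooled
  embedding is the first token's contextual vector.

Freeze masks operate on parameter groups: group 0 bundles the embedding
layer(s) with the first block, group *i* is block *i*, and the last group
also owns the shared projection. This reproduces the usual recipe of
freezing early task-invariant stages while tuning the top (e.g. a 12-layer
text encoder with the lower 9 groups frozen), and makes an all-true mask
mean "fully frozen". Frozen parameters are excluded from the optimiser and
remain bit-identical across training.

## Contrastive objective

For a batch of B pairs, `S[b, k] = cos(f_tb, f_ik)` (embeddings are *not*
pre-normalised; the cosine kernel is computed explicitly), and

    L_t→i = Σ_b −log( exp(S[b,b]/τ) / Σ_k exp(S[b,k]/τ) ),
    L_i→t = the column-wise analogue,  L = (L_t→i + L_i→t) / 2.

The printed form is a sum over the batch and is what the public loss
functions compute (`reduction="mean"` divides by B). All soft-max and
log-sum-exp evaluations subtract the row maximum; τ is floored at 1e-4.

**Training-loop choices.** The estimators default to `reduction="mean"`
(batch-size-invariant gradient scale) and AdamW with lr 1e-3, weight decay
1e-4 — the standard regime for training small transformers from scratch; the
published AdamW setting (lr = wd = 1e-5) is a fine-tuning rate for large
pretrained backbones and remains the config-file default. One prompt variant
per subject is sampled per epoch, so the text side is naturally augmented.
The image side receives fresh Gaussian jitter at every presentation
(`image_noise_sd = 0.2`, both in pretraining and in the supervised phase).
This augmentation is essential at desk scale: without it the image encoder
memorises each training volume's noise fingerprint — training loss collapses
while held-out alignment and fold accuracy sit at or below chance. The same
jitter is applied to the early-concatenation baseline for fairness.

## Fusion and classification

Each CMA layer holds six bias-free projections (Q/K/V per modality). Per-head
scaling is `sqrt(d_model / heads)`; the printed scaling `√d` does not define
the granularity of `d`, and per-head width is the standard reading. Both
directions are computed from the same input features (no sequential
chaining). Heads are concatenated without an output projection — the
single-layer functional operator is exactly the printed attention.

Two residual-connection regimes exist:

* the functional fusion API default matches the printed operator at depth 1
  and inserts residual adds only between stacked layers (`depth > 1`);
* the **estimators default to a residual at depth 1** (`cma_residual=True`).
  Without it, `I*` is a reweighting of *text value vectors only* — no image
  content survives into the fused matrix except through attention weights —
  and the full model measurably underperformed the early-concatenation
  baseline and trained unstably. With the residual the fused tokens carry
  both the original and the cross-modally enhanced signal.

Pooling of `I*`/`T*` is the token mean (text restricted to non-PAD
positions). The reduction stage is single-head self-attention over the
concatenated token matrix, `α = softmax(QKᵀ/√d)`, with `F̂` the row-mean of
`αV`. The head is `Linear(d → 256) → ReLU → Linear(256 → 2) → softmax`; the
BCE probability is the PD-class softmax output, computed in log-space during
training and ε-clamped (ε = 1e-7) in the printed-form public function. The
alignment loss is applied per sample and batch-averaged.

## Synthetic cohort generator

The generator emulates the *structure* of a PD/HC multimodal cohort, not its
anatomy. A latent severity scalar `z ~ N(0,1)` couples the modalities
(`ρ = coupling`, default 0.5):

* scores: `x_j = μ_j + σ_j · s_j · (δ·d + √ρ·z + √(1−ρ)·ε_j)` clipped to the
  scale range, with diagnosis `d ∈ {0,1}`, standardised class shift
  `δ = score_effect`, and `s_j = −1` for inverted scales. HC baselines
  (μ, σ): UPDRS (5, 8), STAI (35, 10), ESS (6, 4), CDT (4.5, 1).
* volumes: an ellipsoidal phantom (intensity 1 inside, 0 outside, radii 0.42
  of each axis) with a spherical lesion region (default radius 5 voxels,
  centred at fractional position (0.35, 0.5, 0.5)) whose intensity is reduced
  by `image_effect · (d + √ρ·z + √(1−ρ)·f)`, plus voxel noise
  (`noise_sd = 0.1`). Default shape 32³.

By construction the *within-class* correlation between a scale score and the
lesion contrast equals ρ up to measurement noise; the pooled correlation also
contains the class main effects, so the coupling property is checked after
class-centering. Class balance defaults to 234:149 (PD fraction ≈ 0.61) so
stratification is exercised. The generator writes NIfTI volumes, a CSV table
and a checksummed JSON manifest; identical configs reproduce identical files.

What passing tests on this generator show: the losses, gradients, freezing,
fold hygiene and end-to-end recovery machinery work, and the pipeline can
extract a genuinely multimodal planted signal at realistic effect sizes.
What they do not show: performance on real MRI (no anatomy, no scanner
effects, no registration errors, one lesion site), or that the fusion
architecture's advantage over concatenation transfers to clinical data —
on this simple generator the two are statistically close, with fusion
matching or exceeding concatenation in most seeded replicates.

## Problem sizes and profiles

Heavy seeded experiments use a fixed desk-scale profile: shared space 64,
`d_model` 32, two encoder stages/layers, pretraining 15 epochs, supervised
training 25 epochs, batch 16, AdamW lr 1e-3 / wd 1e-4. Cohorts: n = 100 for
cross-validated recovery (planted: score_effect 2.0, image_effect 0.5; null:
both 0), n = 200 training pairs + 96 held-out for alignment recovery
(60 pretraining epochs), and n = 120 with a stratified 2:1 split for the
fusion-vs-concatenation comparison (5 replicates). The published-scale
defaults (512-d shared space, 8 heads, batch 32) remain the package
defaults for the estimator and config surface.

## Numerical and degenerate-input conventions

* Softmax/log-sum-exp always subtract the running maximum; attention is
  finite for key magnitudes scaled by 1e±3.
* Zero-norm embeddings raise a `NumericError` naming the offending row
  rather than returning NaN.
* precision/recall/F1 are defined as 0 when their denominators are 0; AUC
  with a single class raises instead of guessing.
* Confidence intervals beyond the per-fold dispersion `σ_M` are out of
  scope (no procedure is defined for them here).
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; a single global seed fans out to per-stage seeds
  by hashing the stage name (`derive_seed`), each below 2³¹. Repeated runs
  with the same seed are bit-identical.

## Attention-map export

Spatial saliency over image patches requires image tokens on the *key* axis
of an attention map, i.e. the image-guided text enhancement direction (text
queries attending image keys): its weights are averaged over heads and
queries, reshaped to the patch grid, upsampled, and the central axial slice
is written as an 8-bit grayscale PNG. The text-key direction has no spatial
key axis and raises `UnsupportedDirectionError`. The acceptance script
measures how often the overlay's peak falls inside the planted lesion and
reports the rate without asserting it; on the micro models trained at desk
scale the attention maps are *not* reliably lesion-localised — the
classification signal flows through distributed patch features rather than a
focal attention peak, so the qualitative heat-map story should not be assumed
to transfer from this phantom setting.

## Known limitations

* The tiny encoders are stand-ins: no shifted-window attention, no decoder,
  no pretrained weights; adapters for published backbones are out of the
  default dependency set.
* The paraphrase bank is finite; requesting more variants than its
  combinatorial capacity raises `CapacityError` (plug in an external
  augmenter for open-ended diversity).
* The reverse-mode tensor engine is deliberately minimal (float64, CPU,
  no broadcasting matmul beyond stacked batches) and sized for the tiny
  presets, not for production-scale models.
* `run_cv` pretrains inside each fold by default; the `global_pretrain`
  escape hatch reproduces the leakier pretrain-once variant and is clearly
  flagged.
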