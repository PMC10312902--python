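# Methods

## Problem and model

`seq2loc` predicts the subcellular localization of a protein as an image:
given an amino-acid sequence and a grayscale reference image of the cell
nucleus, it generates a per-pixel probability density map of where the
tagged protein would appear.  The approach follows the text-to-image
transformer recipe specialized to microscopy:

1. **Image tokenization (phases 1–2).**  Two vector-quantized autoencoders
   turn images into discrete token grids.  The *reference codec* encodes the
   nucleus morphology channel; the *protein-threshold codec* encodes the
   protein channel after mean-threshold binarization (pixel → 1 iff it is ≥
   the image mean, inclusive, so a constant image maps to all ones).  The
   binarized channel is a discrete spatial distribution of protein presence:
   a 16×16 binary patch alone has 2^256 ≈ 1.16 × 10^77 possible states, so a
   learned codebook of canonical patch patterns replaces an impossible
   exhaustive lookup.

2. **Joint token prior (phase 3).**  A decoder-only causal transformer
   models the concatenated stream
   `[START] ⊕ sequence ⊕ reference tokens ⊕ protein tokens`,
   with a learned start vector prepended and the final protein token removed
   from the input, so that shift-by-one targets make the last input position
   predict the g²-th protein token.  Amino-acid positions carry *frozen*
   per-residue embeddings (transfer-learning interface for protein language
   models); image tokens pass through learned embedding tables cast to the
   same width, plus learned per-segment positional embeddings.  Training
   minimizes cross-entropy over image-token targets while the codecs and
   sequence embeddings stay frozen (verified by checksums before/after).

3. **Generation.**  At inference the sequence and reference tokens are
   given; protein tokens are sampled row-major.  Each step restricts the
   logits to the top quartile of codebook entries by logit rank (count-based
   ⌈n/4⌉; ties at the cut break toward the lower index) and takes the
   Gumbel-noise argmax over the retained set, which samples exactly from the
   softmax of the retained logits.  Indices outside the quartile have
   probability exactly 0.

4. **Probability density map.**  Besides the sampled grid, the per-position
   softmax probabilities p(v_i), clipped to [0, 1], weight a convex
   combination Σᵢ wᵢ p(vᵢ) of codebook vectors.  The mixed latent grid is
   decoded once through the threshold codec's decoder, clipped to [0, 1]
   and peak-normalized (max pixel → 1).  A pixel-space mixture of decoded
   patches is available behind a flag (`mode="pixel"`); the latent mixture
   is the default because the combination is defined in the quantized
   embedding space.  Mass normalization (sum → 1) is available by flag;
   peak normalization is the default because the map is displayed as a
   relative-confidence heatmap.

## Synthetic benchmark

No public paired sequence/image corpus is needed to exercise the pipeline:
`synthetic_cells` generates OpenCell-style pairs whose ground truth is
planted in the sequence.

* **Nucleus**: a smooth elliptical blob (semi-axis 18–32% of the frame,
  axis ratio 1.0–1.6, jittered center, soft rim, 15% multiplicative noise);
  the binary mask is exactly the support used for drawing and covers 5–60%
  of the frame.
* **Sequence**: uniform over the 20-residue alphabet, length 30–60, with a
  class motif inserted once at a random interior position.  Motifs:
  `KKKRKV` (nuclear, an NLS-like basic stretch) and `LLVVLL` (peripheral,
  a hydrophobic stretch); cytoplasmic and diffuse sequences are guaranteed
  motif-free.  Motif occurrence and localization class determine each
  other exactly, giving attribution a sharp ground truth.
* **Protein channel**: nuclear → all base intensity inside the mask;
  cytoplasmic → inside a dilated cell boundary but outside the nucleus;
  peripheral → an annulus hugging the mask; diffuse → uniform over the
  frame.  20% multiplicative noise is applied on top; because the noise is
  multiplicative the support is exact, so with noise off the nuclear
  in-mask fraction is exactly 1.
* Everything is a pure function of (config, seed); images are stored as
  8-bit grayscale PNG and rescaled to [0, 1] in memory; the train/val
  split is stratified by class and no sequence appears in both splits.

What the generator does **not** emulate: point-spread functions, camera
noise statistics, multi-cell fields, out-of-focus light, or any real
sequence-to-localization biology beyond the planted motifs.  Passing the
recovery tests therefore shows the *mechanism* works end to end — that
the model can route information from sequence motifs to spatially
structured image tokens — not that it predicts real protein localization.

## Scale presets and numerical choices

Deep-learning scale is configurable; two presets are shipped.

| setting | mini (default) | full_scale |
|---|---|---|
| image / patch | 64×64 / 8×8 (g=8, 64 tokens) | 256×256 / 16×16 (g=16, 256 tokens) |
| codebooks | n=64, d=32 | n=512, d=64 |
| context L_max | 64 | 1000 |
| transformer | 3 layers, 4 heads, width 96 | 8 layers, 8 heads, width 512 |
| embeddings | offline context-window code, d_seq=96 | external (precomputed archive) |

The mini preset is sized so the full study — codec training, 2,400
transformer steps at batch 8, evaluation on 40 held-out samples and
attribution on 20 — runs on one CPU core in well under half an hour.  Its
context length (64) covers the generator's 30–60-residue sequences;
transformer width equals the embedding width so image-token embeddings are
cast into the language-embedding dimensionality.  `full_scale` is
config-complete but not exercised by the tests (it needs externally
computed protein-language-model embeddings and far more compute).

Other numerical decisions:

* **Quantization tie-break**: lowest index (`argmin` order), everywhere.
* **VQ training**: straight-through estimator for the encoder, commitment
  loss β=0.25, EMA codebook updates (decay 0.9) with dead-codes re-seeded
  from batch latents each epoch.  The codec is a per-patch MLP
  encoder/decoder — patchifying *is* the downsampling — which keeps tokens
  exactly patch-aligned and trains in seconds at mini scale.  Binary
  channel: sigmoid output + binary cross-entropy (no perceptual loss —
  targets are binary); reference channel: smooth-L1.  A patch-level
  discriminator provides an optional adversarial term, weight 0 by default
  at mini scale where GAN terms destabilize tiny-data training.
* **Codebook calibration**: after training, each code is pulled toward the
  fixed point of encode∘decode and codes whose canonical patch still
  re-encodes elsewhere are snapped onto their nearest self-consistent
  code.  This makes `encode(decode(T)) == T` exact for generated grids
  while leaving reconstruction quality essentially unchanged; duplicated
  codes are harmless because ties quantize to the lowest index and decode
  identically.
* **Sequence embeddings (offline)**: two deterministic providers are
  shipped.  `LookupTableProvider` assigns each residue a fixed seeded
  Gaussian vector (a pure per-residue lookup).  `ContextWindowProvider` —
  the mini pipeline's default — emits for each position a fixed random
  linear code of its ±2-residue window (per-residue vectors combined
  through seeded per-offset projections).  The latter mirrors the
  *contextual* character of pre-trained protein-language-model embeddings,
  whose position vectors encode their sequence neighborhood; with purely
  per-residue vectors the small transformer would additionally have to
  learn k-mer composition from scratch, which dominates the training
  budget at this scale.  Both are frozen, network-free and pure functions
  of (seed, sequence).
* **Regularization**: the 200-sample study is small enough for a
  transformer to memorize, so training uses 8-fold dihedral augmentation
  of the image pairs (sequences unchanged — the motif rule is preserved),
  residual dropout 0.1, and early stopping on a held-out-by-record slice
  of the training set (best holdout protein-token cross-entropy wins).
  Additionally, whole protein-prefix input positions are dropped with
  probability 0.5 during training: under teacher forcing the localization
  class is inferable from the generated prefix, which both starves the
  sequence pathway of gradient and mismatches generation, where the model
  must commit to a localization before any prefix exists.
* **Sequence loss**: weight 0 by default.  Sequence inputs are continuous
  frozen embeddings, so a token-level sequence likelihood is ill-defined
  without the language model's own head; the prior is learned over image
  tokens conditioned on the sequence.  A 21-way residue head with a
  configurable weight is provided for experiments.
* **Reference tokens** are teacher-forced targets during training but
  always given at inference.
* **Padding**: sequences shorter than L_max are padded with a zero vector;
  padded positions are masked out of attention (keys receive exactly zero
  weight).  Truncation, when enabled, keeps the N-terminal residues.
* **Optimizer**: AdamW (decoupled weight decay 0.01), cosine decay with
  50-step linear warmup, global-norm gradient clipping at 1.0.  Output
  heads are zero-initialized so an untrained model emits exactly uniform
  logits (cross-entropy ln n per token).
* **Attribution aggregation**: uniform mean over layers and heads; queries
  restricted to protein-token positions; present/absent patch cutoff
  defaults to the global image mean.  Per-residue scores are the signed
  difference (present − absent), but the segment report ranks maximal
  runs of the *magnitude* of the smoothed score (window 5, mean + 1 sd
  threshold).  The sign of the contrast is dataset-dependent: on real
  micrographs the protein-bearing patches carry the sequence-specific
  texture, whereas on the synthetic benchmark the background is equally
  class-informative (diffuse speckle spans the frame) and raster-order
  generation resolves the class at the earliest — background — positions,
  so absent-patch queries attend the NLS hardest and the signed
  difference dips negative at the motif.  A residue the model treats very
  differently between the two groups is a feature candidate either way,
  so the report is sign-agnostic; the signed scores remain available for
  display.
* **Nuclear call**: in-mask intensity fraction ρ ≥ 0.5, inclusive
  (majority-mass criterion).  Nucleus proportion accuracy is defined as
  1 − |ρ(pred) − ρ(truth)|.
* **Infrastructure**: the models are trained through a compact numpy-based
  reverse-mode autodiff module (`seq2loc.autodiff`) providing exactly the
  operator set these small models need; gradients are verified against
  finite differences in the test suite.

## Evaluation protocol

The standard study (reproduced by `scripts/acceptance.py`) generates 240
balanced samples (200 train / 40 validation), trains both codecs and the
transformer, and reports:

* **Overfit check** — teacher-forced protein-token cross-entropy after 300
  steps on a fixed 16-sample subset (memorization capacity of the prior).
* **NLS separation** — one-sided Mann-Whitney U comparing the in-nucleus
  probability-map mass ρ of NLS-bearing validation sequences against all
  NLS-free ones.  (Peripheral sequences carry a different, non-nuclear
  motif and therefore belong to the NLS-free side of this comparison.)
* **Nuclear classification accuracy** on validation, against the codec
  ceiling: the accuracy obtained by merely round-tripping the ground-truth
  threshold image through the tokenizer, which upper-bounds any model
  sampling that codebook.
* **Motif recovery** — the fraction of 20 freshly generated (held-out)
  nuclear sequences whose top-ranked attribution segment overlaps the
  planted NLS occurrence.

## Known limitations

* The offline embedding provider is a per-residue lookup table: it gives
  the transformer no evolutionary context, so all sequence signal must be
  learned from the synthetic data itself.  Real protein-language-model
  embeddings plug in through `sequence_embed.load_precomputed`.
* The mini transformer is far below the scale needed for real OpenCell
  data; `full_scale` provides the configuration but not trained weights.
* Attention-difference attribution is a correlational read-out of one
  model's attention; scores are comparable within a sequence, not across
  models.
* The synthetic benchmark's diffuse class binarizes to near-random speckle,
  which sets an irreducible floor on the token cross-entropy — training
  curves should not be expected to approach zero on the full dataset.
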