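# Methods

## The model

`seqstruct` implements multi-view contrastive alignment between two
per-protein encoders:

* a **sequence encoder** — a pre-LayerNorm transformer over amino-acid
  tokens (BEGIN + residues + END, PAD for batching).  Residue embeddings are
  mean-pooled over real residue positions only (BEGIN/END/PAD are excluded
  from the pool) and passed through a two-layer projector (ReLU between the
  layers) into a 256-dimensional contrastive space;
* a **structure encoder** — a small vision transformer over non-overlapping
  patches of a 3-channel contact-map image, with masked pooling over patches
  that cover real residues and its own two-layer projector into the same
  256-d space.

The structure input is the clipped-similarity transform of the Cα–Cα
distance matrix: with distance C and threshold d (default 22 Å on every
channel), each entry is `(d − min(C, d)) / d`, so contacts score near 1 and
anything beyond d scores exactly 0.  The matrix is replicated into three
channels to match the image-encoder convention; per-channel thresholds are
configurable because three identical channels are otherwise redundant.
Sequences and distance matrices are truncated to the same N-terminal
`max_len` residues (default 512) so the two modalities stay index-aligned.
Contact maps smaller than the encoder resolution are zero-padded ("no
contact") with an explicit patch-coverage mask; larger maps are bilinearly
downscaled.  Whether the original full-scale system downscaled or cropped is
not knowable from the outside; downscaling preserves the global contact
pattern and is the default here.

For a batch of N proteins with projected sequence embeddings s_i and
structure embeddings c_i, the per-protein loss is

    L_i = −log [ exp(sim(s_i, c_i)/τ) /
          Σ_{k≠i} ( exp(sim(s_i, c_k)/τ) + exp(sim(s_i, s_k)/τ)
                  + exp(sim(c_i, c_k)/τ) ) ]

with cosine similarity `sim` and temperature τ (default 0.05).  This is an
NT-Xent-style objective with cross-modal repulsion plus both intra-modality
repulsion terms.  Two deliberate reading choices:

* as typeset above the positive pair is **excluded** from the denominator,
  unlike standard NT-Xent/CLIP.  The default implements the exclusion
  literally; `include_positive_in_denominator=True` gives the standard
  variant.  Both are verified against an independent double-loop oracle.
* the loss is sequence-anchored (one term per protein); `symmetrize=True`
  averages with the structure-anchored mirror, default off.

Numerical stability comes from max-subtracted log-sum-exp; masked
(k = i) entries use a −1e30 additive bias so they vanish exactly under the
exponential.

## Lightweight tuning

Three strategies adapt a frozen encoder, all expressible through
`AdaptationSpec`:

* **fine-tune top-K** — the top K transformer layers (attention, FFN and
  their LayerNorms) unfreeze;
* **LoRA** — every base weight stays frozen; a rank-r update
  `h = W0 x + (α/r)·B A x` attaches to any subset of the
  query/key/value/output projections in the top K layers.  A is
  Gaussian-initialised, B is zero, so training starts exactly at the base
  model (initialisation is a free choice here; zero-B is the convention that
  makes the start point exact);
* **adapters** — bottleneck modules `a(h) = W_up·ReLU(W_down·h + b_down) +
  b_up` inserted twice per layer (after the attention projection and after
  the FFN), merged through a shared skip connection `h' = h + Σ_i a_i(h)`
  when several run in parallel.  W_up and b_up start at zero (identity
  start).  At most the newest parallel adapter trains; all earlier ones
  freeze.  During contrastive pretraining the sequence base is entirely
  frozen and only these "structure-aware" adapters (plus the projector)
  train, which yields the continual-learning guarantee tested in the suite:
  disabling the added modules reproduces the base encoder bit-for-bit.

Parameter accounting counts biases and LayerNorm weights; LoRA matrices
carry no biases.  Under this convention the closed-form counts for the
full-scale profile (33 layers, d=1280, FFN 5120) reproduce the published
trainable-parameter table: top-2 fine-tuning with GO heads → 42M/40M/40M,
LoRA (r=2, α=8, top 16, Q/K/V/O) → 3M/1M/0.7M.  The adapter bottleneck
width of the full-scale model is never printed; the published 55M/53M/53M
row back-derives to ≈640 = d/2, which is this package's default
(`bottleneck = embed_dim // 2`) and should be read as an estimate.

## Training recipe

`PretrainConfig` defaults mirror the published recipe: two separate SGD
optimizers (momentum 0.9) for the sequence and structure sides, weight decay
5e-4, batch size 20 with incomplete batches dropped (the loss needs N ≥ 2),
gradient-norm clipping at 1.0, τ = 0.05, 512-residue truncation, and a
cyclic learning rate falling linearly from `lr_max` = 1e-3 to 0 over 100
steps then restarting (a sawtooth; triangular ramp-up variants are not
used).  Dataset order reshuffles every epoch from the config seed; with
`mixed_precision` off (the default) training is bit-deterministic given the
seed.  `mixed_precision: true` switches the model to single precision —
useful for speed, still deterministic on one CPU, but no longer
bit-comparable with the double-precision path.

The engine underneath is a small tape-based reverse-mode automatic
differentiation layer over NumPy (`seqstruct.autodiff`), sized for
desk-scale encoders.  Its gradients are verified against central finite
differences both op-by-op and end-to-end through the contrastive loss
(`loss_gradient_check`, max relative error < 1e-4 at float64).  Backward
frees intermediate graph buffers as the sweep progresses, which caps peak
memory near the forward-pass footprint.

## Encoder profiles

* `tiny` — 2 layers, embedding 32, FFN 64, 4 heads; structure input 64×64,
  patch 8.  Sized so the full toy alignment experiment (below) pretrains in
  a few CPU-minutes.
* `full` — 33 layers, embedding 1280, FFN 5120, 20 heads; structure input
  256×256, patch 4.  Exists only for closed-form parameter accounting and is
  never instantiated.

The activation between the two projector layers is a free choice (ReLU by
default, configurable); nothing downstream depends on it.  BEGIN/END
embeddings are excluded from pooling along with PAD — the published
description names only padding explicitly, but excluding all three is the
conservative reading and is fixed here by the token mask contract.

## Synthetic corpus

`SynthConfig` defaults define the study conditions for every toy
experiment: 8 families × 25 proteins, family archetype lengths spread
evenly over 30–600 residues (so the 512-truncation path is always
exercised), per-residue substitution probability 0.45, and 0.5 Å isotropic
Gaussian jitter on coordinates.  Each family's archetype couples sequence
and structure: a random segment layout of idealized helical stretches
(2.3 Å radius, 1.5 Å rise, 100°/residue) and extended stretches (3.5 Å
rise with a perpendicular zigzag) gives consecutive Cα spacings of ≈3.8 Å,
and the residue pool of each segment depends on its type, so sequence
3-mers and contact-map patches both carry family signal (tested: both
predict the family above chance with a nearest-centroid classifier).

The 0.45 substitution rate corresponds to ≈55% within-family identity —
well inside the divergence range of real protein families, whose members
commonly share 30–70% identity.  It is also what keeps the toy
experiment's baseline meaningful: at low divergence the family structure is
so blatant that even an *untrained* encoder clusters families at or near
the ceiling (K-Means ARI 1.0 at a 0.10 substitution rate; still touching
1.0 at some seeds at 0.30 under the t-SNE pipeline), leaving no measurable
room for contrastive training to improve anything.  At 0.45 the untrained
encoder sits clearly below ceiling at every seed examined while the
structural signal (which the generator leaves untouched) remains clean, so
the trained-versus-untrained comparison is informative.

What the generator does **not** emulate: self-avoidance or any physical
realism of the backbone, indels (family members share the archetype
length), domain architecture, and long-range tertiary contacts beyond what
the segment layout induces.  Passing the toy experiment therefore shows the
machinery learns a real cross-modal signal at toy scale — not that the
method reaches any particular accuracy on real proteins.

## The toy alignment experiment

The acceptance experiment pretrains the tiny twin encoders for 10 epochs on
the default synthetic corpus and checks three behaviours: projected
positive-pair cosine exceeds negative-pair cosine by a clear margin;
clustering ARI of protein-level sequence embeddings against family labels
improves over the untrained encoder under the seeded t-SNE-to-2D + K-Means
pipeline (the protocol the clustering analyses in this literature use); and,
with the sequence base frozen (adapters only), sequence embeddings are
displaced less than structure embeddings (median Euclidean distance in the
original space).

One behaviour worth understanding rather than hiding: the multi-view loss
treats every other protein in the batch as a negative, including same-family
members, so at convergence the intra-modality repulsion caps how tightly
families can cluster in the *raw* embedding space — raw-space K-Means ARI
hovers around its untrained value while the local neighbourhood structure
that t-SNE reads improves clearly.  With a corpus of 8 families × 25
members the within-family negative fraction (~12% of pairs) is far higher
than in a diverse pretraining corpus, which makes this effect much stronger
at toy scale than it would be in production-scale training.

Toy runs use Adam (`optimizer: adam`) instead of the SGD default.  The SGD
recipe was designed for encoders that start from pretrained weights; a
freshly initialised tiny encoder instead starts with all pooled embeddings
nearly collinear (mean pooling over many random-transformer tokens
concentrates them), and momentum-SGD crawls along that collapse plateau —
the loss sits at log(3(N−1)) while positive and negative cosines stay
indistinguishable for tens of epochs.  Adam, the standard optimizer for
CLIP/SimCLR-style systems trained from scratch, escapes the plateau within
a couple of epochs at its conventional 1e-3 rate.  Batch size, temperature,
weight decay, clipping and the cyclic schedule keep their recipe values.

The conserved-K-NN statistic is validated by its invariances instead of any
published percentage (those require the released full-scale model): an
isometry of the embedding space conserves all neighbours (proportion 1.0)
and two independent random clouds conserve 1/(n−1) of first neighbours in
expectation.

## Evaluation statistics

* **ARI** — own contingency-table implementation of the permutation-model
  formula, cross-checked against scikit-learn to 1e-8.  The clustering
  pipeline (optionally t-SNE to 2D, then K-Means with 10 restarts and
  k = number of ground-truth categories) is seeded end-to-end; when the 2D
  reduction is used the perplexity is recorded in the report, because
  ARI-after-t-SNE depends on it and on the seed.
* **CHI** (Calinski–Harabasz) — `[tr(B)/(k−1)] / [tr(W)/(n−k)]` about label
  centroids, cross-checked against scikit-learn; errors on fewer than two
  labels or zero within-cluster dispersion.
* **Fmax** — protein-centric CAFA convention: precision at threshold t
  averages over proteins with ≥1 predicted label, recall over all proteins;
  a label is predicted when its score is strictly greater than t; grid
  0.00–1.00 in steps of 0.01.  The strict inequality makes the all-zero
  score matrix yield 0 rather than a spurious full-recall point at t = 0.
* **K-NN conservation** — Euclidean, self excluded, ties broken by index
  order.

## Degenerate inputs and numerical choices

Zero embedding vectors are rejected by cosine similarity rather than
silently regularised.  Focal loss clamps p_t at 1e-12 before the log.
Distance computations reject non-finite coordinates.  Empty pooling masks,
all-masked contact maps, single-protein contrastive batches, K ≥ n
neighbour queries, and single-label CHI calls all raise.  Alternate-location
Cα atoms resolve to the highest-occupancy conformer, ties to the earliest
altloc letter; residues without a Cα are dropped with a warning.

## Known limitations

* The structure encoder is a plain ViT satisfying the patch/masking
  contract, not a windowed hierarchical transformer; at 64×64 inputs the
  distinction is immaterial, at full scale it would matter.
* The sequence encoder is trained from scratch at toy size; nothing here
  loads released protein-language-model weights, so absolute embedding
  quality on real proteins is out of scope by design.
* Contact maps larger than the input resolution are downscaled, which blurs
  fine contact detail for proteins longer than the input side times the
  residue-per-pixel ratio.
* The NumPy autodiff engine favours clarity over throughput; full-scale
  pretraining is far outside its envelope.
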