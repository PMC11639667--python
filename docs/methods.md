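# Methods

## Problem setting

Given a single-chain protein structure, predict a score in [0, 1] for each
term of a Gene Ontology namespace (multi-label classification over a rooted
DAG whose child→parent `is_a` edges make annotations hierarchically
consistent: annotating a term implies all of its ancestors).  The predictor
combines two views of the same protein: the residue **contact graph**
derived from the structure, and the **residue feature sequence** derived
from the sequence.

## Inputs and feature channels

* **Contact graph.** Two residues are connected iff the Euclidean distance
  between their representative atoms is **< θ = 10 Å** (Cα by default,
  configurable to Cβ with a glycine fallback to Cα).  Edges are stored
  canonically once (u < v) and materialized in both directions for message
  passing; self-loops enter later through the graph-convolution
  normalization, not the edge list.  The distance-threshold inequality in
  the source description is internally inconsistent; we resolve it as
  "connected when *within* the threshold", which matches the stated intent
  and the usual contact-map convention.
* **Token channel.** Residues map to integers 0–20: the 20 standard
  one-letter codes in alphabetical order (ACDEFGHIKLMNPQRSTVWY → 0..19),
  anything else → 20 ("missing position").  A learnable 21×96 table embeds
  tokens to an L×96 matrix; the table is a model parameter, one per branch.
* **Language-model channel.** An L×1280 per-residue embedding matrix from a
  pluggable provider.  The built-in synthetic provider is deterministic
  given (sequence, seed): row = √ρ·r(residue) + √(1−ρ)·p(residue, position)
  with unit-normal r, p keyed on (seed, residue) and (seed, residue,
  position), mean 0, unit scale, and ρ = 0.9.  The residue-dominant mixture
  mirrors how strongly real protein-language-model embeddings encode residue
  identity; a purely (residue, position)-keyed construction would make
  residue identity unlearnable from this channel and the synthetic datasets
  untrainable, defeating their purpose.
* **Concatenated channel.** [lm | one-hot] row-wise, width 1376
  (language-model block first; the order is a fixed convention).

## Graph branch (AGCN)

Pipeline per protein: bidirectional LSTM over residue order (width
preserving by default: hidden d/2 per direction) → three graph-convolution
layers

    H_{l+1} = ReLU( D̃^{-1/2} (A + I) D̃^{-1/2} H_l W_l ),

no biases — the weight matrix is the layer's only parameter → two stages of
**attention pooling**: m learnable seed feature rows (drawn once from a
seeded standard normal, then trained) are linearly mapped to queries; keys
and values are one further graph-convolution transform of the nodes; per
head, Ψ_i = softmax(Q_iK_iᵀ/√D)V_i with D the per-head width, heads
concatenated.  Stage 1 pools L residues to m₀ = 32 rows (configurable);
stage 2 pools those to a single row (m = 1).  The pooled stage-2 transform
uses the self-loop-only adjacency (the pooled pseudo-nodes carry no edges),
which reduces to a linear map + ReLU under the same normalization.

Two sub-branches with identical architecture but separate parameters take
the 1280-wide and 1376-wide channels; their pooled rows are merged by
α·a_esm + (1−α)·a_concat with α = logistic of a single learnable scalar
(initialized 0, i.e. α = 0.5).  The classifier head is
sigmoid(dropout(ReLU(affine))) — note the consequence that branch scores lie
in [0.5, 1): a term the model rejects saturates at 0.5 rather than 0.
Threshold-sweep metrics (Fmax, Smin, AUPR) are unaffected since score
*ordering* still discriminates, but absolute scores should not be read as
calibrated probabilities.

## Convolutional branch (MCNN)

The 1376-wide channel, transposed channel-major, passes through three
cascaded same-padding 1-D convolutions (channels 512/256/128 by default,
kernels 7/5/3 descending, each conv → normalization → ReLU).  The three
scale maps are aligned to the widest width by 1×1 convolutions, summed, and
refined by a depthwise-separable convolution plus a 1×1 convolution (the
"feature pyramid" — interpreted as channel-width alignment; sequence length
is already shared under same-padding).  A bank of h = 4 channel-attention
heads with distinct kernel sizes {3, 5, 7, 9} gates channels by
σ(conv_k(avg-pool) + conv_k(max-pool)) (one shared bias-free kernel per
head, applied across the channel axis); the gated maps are mixed with
softmax weights, which keeps the mixing weights on the probability simplex
by construction.  Global max pooling over positions (mean available) feeds
the same sigmoid(dropout(ReLU(affine))) head.

Normalization: proteins are processed one at a time (variable lengths, no
padding), so the "batch" statistics are the current protein's own
per-channel position statistics — instance-normalization semantics applied
identically in training and inference.  This keeps inference deterministic
and independent of data ordering; cross-protein running statistics were
tried and made validation behaviour diverge from training.

## Objective, fusion and training protocol

The loss is multi-label binary cross-entropy (predictions clamped to
[1e-7, 1−1e-7]); the printed sum form is available, the optimizer uses the
mean. Training is three-phase:

1. graph branch: Adam, lr 1e-4, batch 48, early stopping on validation loss
   with patience 5, best-validation parameters restored;
2. convolutional branch: the same with lr 5e-4, batch 64;
3. fusion: both branches frozen; f̂ = α·ŷ_gcn + (1−α)·ŷ_cnn with α either a
   global logistic scalar or per-sample (affine map of the concatenated
   branch score vectors → one logit; the default).  α is fitted on the
   **validation split** (stacking-style held-out ensemble weighting, Adam lr
   0.1): the branches were themselves selected by validation loss, and
   fitting α on training data lets a branch that overfits the training
   split dominate.  Because the objective is convex in α and α → 0/1
   recover the single branches, the fused validation loss can never end
   above the better branch's.

Batch gradients are accumulated one protein at a time (losses averaged over
the batch); with fixed seeds the whole protocol is reproducible
run-to-run, and two independent prepare → train → predict runs produce
byte-identical prediction files.

**Desk scale.** The standard batch sizes exceed a 40-protein training split
(one optimizer step per epoch), so `TrainConfig.desk_scale()` shrinks them
to 1/2 and raises the epoch cap to 200; `ModelConfig.desk_scale()` narrows
hidden widths (32), m₀ (4), the convolution channels (64/32/16) and the
recurrent context width (64) while keeping the chosen structure — three
graph-convolution layers and four channel-attention heads.  Learning rates
and the patience window keep their standard values.

**Initialization.** ReLU-following layers use He gain; graph-convolution
weights use gain 2.0 (≈ √2 for the ReLU times √2 compensating the variance
contraction of neighbourhood averaging) — without this, activations decay
~40-fold through the stacked graph layers and nothing trains at lr 1e-4.
Classifier head biases start at +0.5: the literal sigmoid(ReLU(·)) head has
a zero-gradient region, and units whose pre-activation goes negative for
every input would otherwise die irreversibly.

## Evaluation metrics

Thresholds sweep t ∈ {0.01, …, 1.00}; a term is predicted at t when its
score ≥ t.

* **Fmax**: per t, precision is averaged over proteins with ≥ 1 predicted
  term and recall over proteins with ≥ 1 true term; F = 2·pr·rc/(pr+rc);
  Fmax is the maximum over thresholds where F is defined, 0 if no threshold
  yields any prediction.  The reported argmax is the smallest grid point
  attaining the maximum (plateaus are common).
* **Smin**: ru(t) and mi(t) average, over all proteins, the information
  content of missed true terms and of falsely predicted terms;
  S(t) = √(ru² + mi²), minimized over the grid.  IC(t) = −log₂ of the
  term's frequency in the **evaluation truth set** (base 2; an unannotated
  term is capped at −log₂(1/(N+1))) — the estimation corpus is not fixed by
  the source, so the evaluation set is used and stated here.
* **AUPR**: micro-averaged over all protein–term pairs, trapezoidal over the
  PR points at every distinct score cutoff, integration starting from
  (recall 0, precision of the top cutoff).

Ground truth is ancestor-closed before evaluation.  Predicted scores are
**not** hierarchically post-processed by default; an optional
max-over-descendants propagation (`propagate_scores_max`) is provided.

## Synthetic data generator

The generator emulates the minimal world the pipeline needs: per protein an
ideal α-helix Cα trace (rise 1.5 Å/residue, radius 2.3 Å, 100°/residue —
consecutive residues are always in contact at θ = 10 Å, residues seven apart
never are), a uniformly random sequence, and labels planted by sequence
motifs: each of 8 guaranteed-childless leaf terms of a random rooted DAG
(C = 16, ≤ 2 parents per term) maps to a 3-mer motif, implanted with
probability 0.5 per (protein, motif); the leaf label is *containment* of the
motif in the final sequence, flipped with probability `noise` (default 0),
then closed over ancestors.  Defaults: 50 proteins, lengths 30–60, split
8:1:1.

What a green test does and does not establish: labels are learnable from
sequence content through both branches (the contact graph relays sequence
neighbourhoods), but the helix topology is label-independent by
construction — these fixtures exercise correctness and trainability, not
structure-specific signal, fold diversity or realistic annotation sparsity.
Real-corpus performance claims are out of scope for this package.

## Numerical choices and degenerate inputs

* float64 throughout; loss clamp 1e-7; softmax max-shifted for stability.
* L = 1 proteins work end to end (softmax over one key is 1; normalization
  variance guard eps = 1e-5; same-padding handles k > L).
* Residues lacking the representative atom are skipped (sequence and
  coordinates stay aligned) with a logged warning; non-standard residues
  become 'X'; empty chains are an error.
* Contact-graph edge storage rejects self-edges and non-canonical ordering
  at construction.
* The early stopper counts consecutive non-improvements (strict <) and
  restores the best epoch's parameters; ties count as non-improvement.

## Known limitations

* Branch scores live in [0.5, 1) — a direct consequence of the
  sigmoid(ReLU(affine)) head; use threshold sweeps, not raw scores.
* The graph branch at the standard lr 1e-4 does not master the desk-scale
  training split within 200 epochs on its own (at full scale the same
  protocol takes ~30× more optimizer steps); the fused model compensates.
* Single namespace per evaluation run; multi-namespace reports are a loop
  over DAGs by the caller.
* The NumPy autodiff engine is single-threaded per protein and trains
  desk-scale models in minutes; it is not a general-purpose framework.
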