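# Methods

This note documents the model implemented by `modalcoder`, the choices
made where the architecture family leaves details open, and what the
synthetic study conditions do and do not establish.

## Problem setting

Automated case coding assigns a label vector to a medical record that
mixes three channels: an image (e.g. a chest radiograph), a token
sequence (clinical text), and a numeric structured-feature vector
(demographics, lab values).  The classifier must fuse the channels
without letting one corrupt another, remain usable when a channel is
missing, and be cheap to adapt to secondary tasks.  The architecture
here addresses those requirements with three mechanisms: causal masked
self-attention, whitelist-constrained cross-modal attention, and
low-rank adaptation inside a weighted multi-task objective.

## Model

**Encoding.**  Each modality is projected linearly into a shared
`d_model`-dimensional token space: the image as flattened `p x p`
patches in raster order, the text by embedding-table lookup, the
structured vector as a single token.  Tokens are concatenated in the
fixed canonical order (structured, text, image) — a causal mask needs a
total order over tokens, and nothing in the data dictates one, so the
order is a convention and is stated here rather than hidden.  Fixed
sinusoidal positional encodings are added; learned positions would add
a training dependency to unit tests without changing anything the
package claims.  An absent modality contributes zero tokens, and all
downstream masks adapt, which is what makes incomplete records
processable.

**Causal masked attention.**  Scaled dot-product attention
`softmax(Q K^T / sqrt(d_k) + M) V` with the additive mask `M[i,j] = 0`
for `j <= i` and `-inf` otherwise.  The implementation contract is
*exact-zero* weight on masked positions (softmax is computed only over
visible entries, with per-row max subtraction for stability), not
"numerically negligible" weight; that is what makes the causality
property testable at 1e-6 over every sequence length up to 16.  Blocks
are pre-norm residual transformer layers (LayerNorm → attention →
residual, LayerNorm → feed-forward → residual), two of them by default,
with `d_model = 64` and 4 heads — small enough to train in seconds on a
CPU while leaving the mechanisms non-trivial.  The mask is applied in
every causal block.  With token-grid images and short texts the
"causal" axis is token order, not time; the package makes no claim that
this ordering reflects clinical chronology.

**Constrained cross-modal fusion.**  Cross-attention in which a pair of
tokens may exchange attention only if their (query-modality,
key-modality) pair is on an explicit whitelist `P`; all other logits
are set to `-inf`, so off-whitelist attention mass is exactly zero.
The block follows the post-norm form
`LayerNorm(X_t + Concat(head_1..head_h) W_O)` followed by a
position-wise feed-forward `W2 ReLU(W1 x + b1) + b2`.  A query token
whose whitelist row is empty receives a zero attention term, so the
block degrades to `LayerNorm(X_t)` rather than NaN.  The network
applies one such block to the full assembled sequence against itself,
with the mask built from the per-token modality tags; this covers every
whitelisted direction in a single pass and keeps pooling trivial (mean
over all fused tokens).  The default whitelist is
`{(text,image), (image,text), (structured,text), (structured,image)}`:
text and image exchange symmetrically, the structured token reads both
but is not read from.  The whitelist is a config value, not a
constant — the mechanism, not any particular `P`, is the contribution.

**LoRA.**  Each attention block's query and value projections can be
placed under low-rank adaptation: the base weight `W0` is frozen and
the trainable update is `dW = B A` with `B` zero-initialized (rank 4 by
default).  There is no `alpha/r` scaling factor; any such rescaling is
expressible through the learning rate.  Three contracts are enforced by
tests: the adapted model equals the base model exactly at
initialization, `W0` is bit-identical after any number of optimizer
steps, and folding `B A` into `W0` reproduces the factored forward pass
to 1e-5 relative.

**Multi-task objective.**  The total loss is `sum_k lambda_k L_k` over
three tasks: (1) the primary coding loss — softmax cross-entropy over
classes for the single-label synthetic data, with an element-wise
sigmoid variant behind the `multi_label` flag; (2) a symmetric InfoNCE
contrastive loss over the mean-pooled per-modality token
representations taken *before* fusion (post-fusion representations are
already mixed, so they cannot serve as distinct views), with cosine
similarity at temperature 0.1; (3) a 3-class severity cross-entropy,
treating mild/moderate/severe as unordered classes.  Default weights
are `lambda = (1.0, 0.3, 0.3)` — auxiliary tasks as regularizers, not
co-equal objectives.  Turning multi-task learning off means setting the
auxiliary weights to zero; it is a configuration change, as are the
other two ablation switches (all-zero attention mask; fusion block
skipped in favor of plain concatenation + mean pooling).

**Training.**  Adam at learning rate 1e-3, batch size 32, at most 50
epochs, early stopping on validation subset accuracy with patience 5
and best-epoch restoration.  All randomness (parameter init, shuffling,
data generation) flows from explicit seeds; a fixed seed reproduces the
training history exactly under single-threaded execution.

The network and its gradients run on a small reverse-mode automatic
differentiation engine over NumPy arrays written for this package
(`modalcoder.autodiff`).  Every primitive's backward rule is validated
against central finite differences in the test suite, and a composite
attention-graph gradient check guards the interaction of primitives.

## Evaluation metrics

Five multi-label metrics are implemented from their definitions:
subset accuracy (exact-match fraction), Hamming loss (entry-wise error
fraction), macro F1 (per-class F1 averaged over classes), macro AUC-ROC
(per-label one-vs-rest AUC via the Mann–Whitney rank statistic with
midrank tie handling, averaged over labels with both classes present),
and a Jaccard index averaged **per sample** (intersection-over-union of
each sample's predicted and true label sets).  The sample-averaged form
is deliberate: it is the formula this metric family prints, even though
the name "macro" conventionally suggests per-label averaging; a
per-label variant is exposed separately as `labelwise_jaccard` so users
can have either.  Zero denominators: precision, recall, F1 and
per-sample Jaccard are 0 when undefined, except that a sample whose
truth and prediction are both empty scores Jaccard 1.  Single-label
C-class data is evaluated by one-hot reduction to an `N x C` label
matrix.  scikit-learn's implementations are used only as an independent
cross-check (1,000 random instances, 1e-9), never as the
implementation.

Reporting arithmetic: `relative_change(ref, new) = 100 |new - ref| /
ref` and `absolute_drop(std, pert) = std - pert`, both rounded half-up
to one decimal.  One convention covers improvement-over-baseline,
ablation-decrease and robustness-drop statements.  Hamming loss is
reported on both the percent scale ("3.4") and the fraction scale
("0.034"), since comparison tables use both.

## Synthetic study conditions

The generator emulates the *shape* of small medical-image coding
datasets — C mutually exclusive classes rendered in every modality —
not their appearance.  Defaults (chosen once as the study conditions):
n = 600 cases, C = 3 classes, 16x16 images, vocabulary 32, text length
12, structured dimension 8, class-mean separation delta = 4, pixel
noise sigma = 0.1, splits 70/15/15.  Structured features are
class-conditional unit-variance Gaussians with all pairwise mean
distances exactly delta; images are class-specific stripe/quadrant
templates plus clipped pixel noise; text is drawn from class-skewed
token distributions (70% of the mass on the class's vocabulary block);
severity is the tercile bin of the case's latent deviation from its
class mean, so the severity head has a learnable target tied to the
structured channel.

Perturbations: the noise setting corrupts exactly
`floor(fraction x total entries)` of the pooled continuous feature
entries (structured coordinates and image pixels) with additive
Gaussian noise at one pooled empirical standard deviation, re-clipping
images — an interpretation of "input noise" as feature corruption; a
label-noise mode exists behind a separate function for the alternative
reading.  The reduced-data setting drops training records only.  A
`drop_modality` operation removes one channel from a fraction of
records to exercise incomplete-record handling.

At delta = 4 the classes are nearly linearly separable from the
structured channel alone, so the headline end-to-end numbers (test
subset accuracy ≥ 0.90, noise drop within a few points, ablations
within ties of the full model) establish that the architecture trains,
fuses and degrades gracefully — **not** that any module is necessary
for this easy task, and not anything about real radiographs or clinical
text.  On these conditions the ablation claim is directional with ties
allowed (within 2 points), because all variants saturate near-perfect
accuracy.  Distinguishing module contributions would need harder
conditions (smaller delta, heavier noise), which would in turn make the
accuracy floor stochastic; the package chooses stable, fast conditions
and states the weaker claim honestly.

## Numerical choices and degenerate inputs

* Masked softmax subtracts the per-row maximum over visible entries;
  fully masked rows produce the zero vector rather than NaN.
* LayerNorm uses epsilon 1e-5 inside the square root.
* AUC excludes single-class label columns and errors only if every
  column is excluded.
* `relative_change` refuses a zero reference; `absolute_drop` has no
  such restriction.
* Empty text is an absent modality (zero tokens), not an error; a
  record with no modalities at all is rejected.
* Mini-batches are homogeneous in modality-presence signature so that
  batched tensors stay rectangular; records are regrouped to their
  original order after prediction.

## Known limitations

* Single-threaded CPU only; the autodiff engine favors clarity and
  testability over throughput, which is sufficient at desk scale.
* The contrastive task needs at least two present modalities and batch
  size ≥ 2; otherwise its term is skipped for that batch.
* Severity is treated as unordered 3-class classification; an ordinal
  treatment might use the mild < moderate < severe structure.
* The generator does not model class imbalance (beyond near-balanced
  assignment), realistic image statistics, or language structure in
  text.
* Multi-label evaluation is exercised mainly through one-hot reduction
  of single-label data; the `multi_label` training flag is provided and
  unit-tested but the study conditions are single-label.
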