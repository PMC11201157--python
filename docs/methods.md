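# Methods

`lapseg` implements an imbalance-aware pipeline for semantic segmentation of
laparoscopic surgical scenes: per-pixel classification of RGB frames into 13
classes (background, tissues such as liver / abdominal wall / fat, thin
structures such as the cystic duct and hepatic vein, instruments, blood).
The defining difficulty of this regime is severe class imbalance — four
classes together hold ~85% of all pixels while four structures hold less
than 1% each — and the pipeline's purpose is to make the minority
structures segmentable at all.

## Model

The segmentation network is a U-Net-style encoder–decoder with a
configurable number of stages. Each encoder stage applies two
(3×3 convolution → batch normalization → activation) blocks followed by 2×2
max pooling, doubling the channel width; the decoder mirrors the encoder
with 2×2 stride-2 transposed convolutions, concatenating the matching
encoder feature map (skip connection) before its own double-conv block; a
final 1×1 convolution emits per-class logits. The full-scale reference
configuration has five stages on 224×224 inputs with 64 base channels;
desk-scale experiments use three stages on 96×96 inputs with 8 base
channels. Input height and width must be divisible by 2^depth.

Hidden activations are pluggable and shape-orthogonal: ReLU max(x, 0), GELU
x·Φ(x) with the exact error-function form, and Swish in its sigmoid-weighted
(SiLU) configuration x·σ(x). Block internals (max pooling, transposed-conv
upsampling, batch norm placement, channel doubling) follow the canonical
U-Net choices.

The network, its losses, and both optimizers are implemented directly on
NumPy with hand-derived backpropagation (`lapseg.nn`). Every layer's
backward pass, and every loss's logit gradient, is checked against central
finite differences in the test suite (1e-4 relative tolerance on random
4×4×3 logits for losses).

## Losses

All losses act on the softmax probability map p (per-pixel simplex) against
the integer label mask. With p_t the probability assigned to a pixel's true
class:

* **CE** — mean of −log p_t; with class weights w_c the per-pixel terms are
  multiplied by w_{y} and normalized by the summed applied weights, so
  uniform weights reduce exactly to the plain mean. log arguments are
  clamped at 1e-12 (far below float32 softmax resolution), never infinite.
* **FL** — mean of α_t (1−p_t)^γ (−log p_t); γ=0, α_t=1 recovers CE. α_t
  may be a scalar (default 0.25) or a per-class vector; γ defaults to 2.
* **Tversky / Dice** — soft Tversky index per class c,
  TI_c = (ΣJ_cG_c + ε) / (ΣJ_cG_c + σ·FP + β·FN + ε), with J the predicted
  probability channel (soft, hence differentiable) and G the one-hot truth;
  TL = Σ_c (1−TI_c) ∈ [0, C]. σ=0.3 and β=0.7 by default, penalizing false
  negatives more; σ=β=0.5 is exactly the Dice loss. ε = 1e-6 enters both
  numerator and denominator, so a class absent from truth and prediction
  contributes ≈0. Sums run over the whole batch by default (more stable
  gradients at mini-batch 8); `per_image=True` averages per-image losses.
* **CEDL / CETL** — δ·CE + (1−δ)·X with X ∈ {Dice, Tversky}; δ = 0.7 gives
  the cross-entropy term priority. Class weights enter the CE term only;
  `weight_tversky=True` optionally weights the Tversky class terms too.

## Class weighting

Weights are computed from the pixel-frequency profile of the *training*
partition only (avoiding test leakage). The default scheme is
median-frequency balancing, w_c = median(f)/f_c — the standard choice in
encoder–decoder segmentation work, and the one whose behavior matches the
intended rebalancing: dominant classes fall below weight 1, minority
classes rise above it, and the weighted share profile w_c·f_c flattens.
Inverse-frequency (w_c = 1/(C·f_c), which equalizes w_c·f_c exactly) and
uniform weights are selectable. Weights depend (mildly) on image
resolution because nearest-neighbor resizing shifts class pixel counts;
they are therefore recomputed from the masks at the resolution actually
trained on, rather than rescaled from full-resolution tallies. A class with zero training pixels has no
frequency weight; the caller must exclude it or smooth counts explicitly —
the desk-scale harness floors counts at one pixel for exactly this reason.

## Metrics

All region metrics derive from a C×C pixel confusion matrix accumulated
over the evaluation set. Two per-class accuracies are reported because two
conventions coexist: the classical one-vs-rest accuracy
(TP+TN)/(TP+TN+FP+FN) and the recall-style class accuracy TP/(TP+FN) used
by segmentation toolboxes; the aggregate MAcc uses the recall-style value,
which is the convention the study regime's tabulated numbers are consistent
with. GAcc is pooled pixel accuracy; MIoU and Dice follow the Jaccard/F1
forms (Dice = 2·IoU/(1+IoU) identically). Classes absent from both truth
and prediction are *undefined* and excluded from all means, never counted
as 0 or 1.

The boundary F1 score extracts, per class, the pixels whose 4-neighborhood
(or the image border) leaves the class; boundary precision is the fraction
of predicted boundary pixels within Euclidean distance θ of any true
boundary pixel, recall the converse, bfs their harmonic mean. θ defaults to
0.75% of the image diagonal. Per class, bfs is averaged over the images
where the class appears in either mask, then across classes for Mbfs.

## Training

SGDM (momentum 0.9) and Adam (β₁=0.9, β₂=0.999, ε=1e-8) with coupled-L2
weight decay 5e-3 (decoupled decay behind a flag), mini-batch 8, 30 epochs
at full scale. The learning rate is piecewise constant,
ilr · 0.3^⌊(epoch−1)/10⌋: the drop factor 0.3 is the unique constant
linking the stated initial rates (1e-3 SGDM, 1e-4 Adam) to the stated final
rates (9e-5, 9e-6) over the two drops of a 30-epoch run. Shuffling is
seeded per epoch; training is deterministic single-threaded. Validation
runs once per epoch; final-epoch weights are used (best-validation
checkpointing optional). Non-finite parameter updates raise immediately
(divergence guard).

## Synthetic scenes

The generator reproduces the *statistics* of the target regime, not its
appearance. Each class is a stylized shape family: dominant tissues are
unions of ellipses grown until a measured pixel count is reached (the
dominant planes claim only still-unlabeled pixels, so they tile the scene);
medium structures (gallbladder, gastrointestinal tract, connective tissue)
overwrite tissue beneath them; ducts/vessels/ligaments are dilated Bézier
strokes; blood is scattered specks; instruments are rotated rectangles with
triangular tips entering from an image edge, painted last so they occlude
tissue. Images render per-class base colors plus a random tilted
illumination plane, Gaussian texture noise (sd 10 of 255), and Gaussian
blur (σ 1 px).

The bundled 13-class profile sets presence probabilities from the target
dataset's per-image frequencies (liver 100%, cystic duct 3.07%, …) and
pixel-share targets 0.27/0.22/0.21/0.15 for the four dominant classes with
the four minority structures below 1%. Presence and share are treated as
independently configurable, which is an approximation (their joint
distribution is not published). A structure's conditional area is
target_share / presence_prob, capped per shape family (e.g. 5% for thin
curves) so rare structures stay small *and* rare; capped classes therefore
realize mean shares below their nominal targets, by design, while remaining
<1%. Blob areas are inflated by the expected coverage of later-painted
layers so realized dominant shares land on target (verified by a
Monte-Carlo calibration of the generator itself: background realizes
0.31 ± 0.02 against its 0.27 target across 10 seeds at n=50). Every sample
is deterministic given (config seed, sample index) via a counter-style
sub-seed.

What passing tests on these fixtures show — and what they do not: the
pipeline demonstrably handles presence/share-imbalanced data where class
identity correlates with color and shape, which is the mechanism class
weighting targets; the fixtures do not model specular highlights, motion
blur, smoke, deformation, or inter-patient appearance variation, so
performance numbers here say nothing quantitative about real surgical
video.

## Desk-scale comparison harness

`experiment.imbalance_comparison` contrasts the imbalance-aware
configuration (median-frequency class-weighted CETL with δ=0.7, σ=0.3,
β=0.7, Swish, Adam) against a plain baseline (unweighted CE, ReLU, Adam)
on identical data per seed: 48 training and 24 test scenes at 96×96, a
depth-3/8-channel network, 15 epochs, 3 seeds, scored by the mean IoU over
the minority classes (target share <1%) where defined. Both arms use Adam
so the contrast isolates the loss, weighting, and activation; both use
learning rate 1e-3 — a desk-scale run sees ~90 optimizer steps rather than
the ~18k of a full-scale training, and the full-scale rate of 1e-4 cannot
move the network in that budget, so the standard Adam default is used for
both arms. The expected outcome is directional (weighted arm's median
minority IoU strictly higher), not a magnitude claim.

## Numerical choices and edge cases

* Softmax is max-stabilized; argmax ties in prediction resolve to the
  lowest class id (NumPy argmax semantics, asserted in tests).
* Masks are resized nearest-neighbor (labels can never be interpolated);
  images bicubically. Identity resizes are short-circuited bit-exactly.
* Color↔index mask matching is exact byte equality — masks are annotation
  artifacts, not photographs — and unknown colors raise with the offending
  color and coordinate.
* Manifest splitting sorts records by path before the seeded shuffle, so
  partitions are independent of filesystem enumeration order; |val| and
  |test| are ⌊f·N⌋ with the remainder assigned to train.
* Presence percentages round half-up to two decimals (decimal arithmetic,
  not float rounding).
* The disagreement overlay renders prediction-derived grayscale into the
  red channel and truth-derived grayscale into green+blue, so agreement is
  gray and disagreement magenta (prediction) or green (truth); grayscale is
  class_id · 255/(C−1).

## Known limitations

* The NumPy network trains at CPU speed; paper-scale trainings (8k images,
  224×224, depth 5, 30 epochs) are out of reach and out of contract —
  pretrained-backbone architectures (SegNet-VGG19, DeepLabv3+) are exposed
  only as the `SegmentationModel` interface.
* Minority-class IoU at desk scale is small in absolute terms: with ~3%
  presence, a 48-image training set contains roughly one example of each
  rare structure. The comparison is meaningful directionally.
* Determinism is promised only for single-threaded execution; BLAS
  threading may perturb float32 reductions.
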