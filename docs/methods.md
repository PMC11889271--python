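# Methods

## Model

The segmenter is a four-level U-Net encoder–decoder over two-class
(lesion/skin) score maps. Input images are RGB, square, with side divisible
by 2⁴; the default full-size preset works at 576×576 with encoder widths
32/64/128/256 and a 512-channel bottleneck, and a "tiny" preset
(96×96, widths 8/16/32/64, bottleneck 128) scales the same architecture to
single-CPU experiments. Three optional components extend the baseline; each
is an independent boolean in `ModelConfig`, which makes the ten-configuration
ablation lattice (baseline, each single addition, each pair, full model)
constructible from one code path.

**Multiscale input fusion (MIF).** The input image is reduced to a pyramid by
exact area averaging (block means), one halving per encoder level:
576/288/144/72 at full size, 96/48/24/12 at the tiny preset. At encoder
levels 1–3 the scaled image is lifted to the incoming feature width by a 1×1
convolution and added residually to the pooled features. The fused map both
feeds that level's encoder block and serves as the level's skip-connection
source; with MIF off, the skip source is the block output, which makes the
all-off configuration exactly a conventional U-Net. Area averaging was chosen
over interpolation because it is deterministic, alias-free for power-of-two
ratios, and preserves constants exactly; addition was chosen over
concatenation because the fusion is a residual structure.

**Res2-SE encoder blocks.** The block body projects to the output width with
a 1×1 convolution, splits the channels into n = 4 equal groups and applies
the hierarchical recurrence Y₁ = X₁, Y₂ = K₂(X₂), Yᵢ = Kᵢ(Xᵢ + Yᵢ₋₁) with
3×3 convolutions Kᵢ, then concatenates the groups and fuses with a second
1×1 convolution. Group 1 deliberately passes through unconvolved, exactly as
the recurrence states. Squeeze-and-excitation attention follows: global
average pooling per channel, a bottleneck gate S → max(S/R, 4) → S with ReLU
then sigmoid (reduction R = 16 by default; the clamp keeps the gate
expressive at narrow widths), and channelwise rescaling. The composite closes
with dropout (rate 0.2), batch normalisation and ReLU, in that order. The
two attention pieces are separately switchable (`use_res2net`, `use_se`);
with both off the stage is a plain double 3×3 convolution with BN/ReLU, and
the dropout/BN/ReLU tail is only attached when at least one attention piece
is active so the baseline remains the classic U-Net stage.

**Pyramid dilated convolution (PDC) bottleneck.** After one channel-lifting
3×3 convolution, a shared cascade of 3×3 convolutions at dilation rates
(1, 2, 4, 8) runs in sequence; the output after k stages is pyramid branch k,
so branch k has receptive field 1 + 2·Σⱼ≤ₖ rateⱼ (3, 7, 15, 31). The four
branches are concatenated, fused by a 1×1 convolution back to the bottleneck
width, and the block input is added residually (switchable; the residual
makes the zero-weight block an exact identity and stabilises small-scale
training). All convolutions everywhere are stride-1 and zero-padded to
preserve the spatial size; dilated kernels are padded by their rate.

**Decoder and head.** Each decoder stage upsamples by a learned 2×2
stride-2 transposed convolution, concatenates the matching skip tensor, and
applies a double 3×3 convolution with BN/ReLU. A 1×1 convolution produces
two class scores; predictions are the pixelwise argmax, with ties breaking
toward background.

## Training recipe

Adam (β₁ = 0.9, β₂ = 0.999) minimises unweighted two-class cross-entropy;
batch size 16; up to 100 epochs; batch-norm running statistics retain 99.8%
per update (decay 0.998). The learning rate decays geometrically,
lr(e) = 0.01 · (10⁻⁴)^{e/(E−1)}, the unique monotone exponential through the
endpoints 0.01 (epoch 0) and 10⁻⁶ (final epoch). Model selection keeps the
epoch with the best validation Dice. Optional per-class loss weights exist
but are off by default; no data augmentation is applied.

**Batch-norm calibration.** With a 0.998 decay, the running statistics move
by only 0.2% per step, so after the few hundred steps of a small study they
still reflect their initialisation rather than the trained network, and
evaluation-mode outputs are meaningless. Before each validation pass (and
hence in every saved checkpoint) the running statistics are therefore
recomputed as the cumulative average of per-batch statistics over the
training set with dropout inactive (precise-BN recalibration). The 0.998
decay is kept for the within-training updates.

## Compute backend

No GPU framework is used: `mrpunet.nn` is a small reverse-mode autodiff
engine on numpy arrays. Convolutions are im2col + BLAS matrix products; the
input gradient is computed as the full correlation of the output gradient
with the spatially flipped kernel (exact for stride-1 same padding), and the
weight gradient reuses the cached im2col matrix. Transposed 2×2/stride-2
convolution, 2×2 max pooling (first-maximum tie-break), batch normalisation
(train and eval modes), dropout (inverted scaling), linear layers, channel
scaling and softmax cross-entropy all carry hand-written backward passes;
every one is verified against central finite differences in float64 in the
test suite. Model weights are float32 with He initialisation from a seeded
generator; batch-norm running statistics are float64 buffers. Checkpoints
are a single `.npz` holding a JSON header (format tag, config, seed) plus
all named parameters and buffers; an eval-mode forward after reload is
bit-identical.

## Synthetic data

The generator emulates the challenge taxonomy of public dermoscopy sets
rather than their appearance. Each sample is a warm-toned skin field with
smooth shading; the lesion is a star-convex region around a rotated ellipse,
radius(θ) = r_ell(θ)·(1 + irregularity·noise(θ)) with low-frequency periodic
noise, filled with a pigment colour pulled toward dark melanin by a contrast
parameter in (0, 1] and smooth within-lesion colour jitter. Hairs (dark
Bézier strokes), air bubbles (bright rings), vessels (thin reddish curves)
and an optional black device frame are painted *after* the ground-truth mask
is captured, so artifacts occlude the image but never change the label.
Default parameters: 96-pixel images, semi-axes 12–38% of the side,
irregularity 0.25, contrast 0.45, up to 6 hairs and 2 bubbles, 20% of
dataset samples framed — chosen to make the task non-trivial (occlusion,
low-contrast tail, size spread) while remaining learnable in minutes on one
CPU. Dataset splits are stratified by lesion-size tercile.

What this does and does not show: with irregularity 0 the mask area has a
closed form (πab), so geometry, determinism and artifact policy are exactly
testable; but the images lack real textures, specular highlights, colour
calibration differences and ambiguous boundaries, so performance here says
the implementation learns and generalises on in-distribution shapes — it is
no estimate of clinical accuracy on ISIC-like data.

## Evaluation

Masks are compared by confusion counts; the five metrics follow the standard
formulas, and Dice = 2·JI/(1+JI) holds identically. Degenerate denominators
are defined rather than raised: a metric whose denominator is empty scores
1.0 (nothing to find, nothing found), except sensitivity with false
positives on a lesion-free truth, which scores 0.0 with a logged warning.
Both per-image-mean (default; each image counts equally) and globally pooled
aggregations are computed.

## Study sizes

The packaged learning study uses the tiny preset: 80 synthetic images
(60 train / 20 test, stratified), 25 epochs, three seeds for the full model
and one for the U-Net baseline under the identical harness. These sizes keep
a full run in the ten-minute range on one CPU while leaving the task hard
enough that an untrained or miscalibrated model scores far below the
passing Dice.

## Known limitations

* The backend is CPU-only and unoptimised beyond BLAS matmuls; full-size
  (576×576) training is out of reach — the full preset is provided for
  architecture fidelity, not training.
* Binary segmentation only; one head, softmax over two classes.
* The PDC cascade shares intermediate convolutions between branches
  (branch k is the output after k cascade stages); a variant with
  independent per-branch cascades would have more parameters but the same
  receptive-field pyramid.
* At tiny scale the ranking between ablation configurations is
  seed-sensitive; the harness reports the gap but no claim is made that the
  full model beats the baseline on every seed.
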