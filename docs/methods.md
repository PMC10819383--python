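# Methods

## Model

The classifier is a five-stage hybrid of MobileNetV2-style inverted
residual blocks and location-preserving ViT (LP-ViT) blocks. The stage
table (channel bases 32/64/96/160/320, expansion ratios
1,1 | 1,1,3 | 3,3,3 | 6,2.5,2.5 | 6, LP-ViT counts 1/2/3/2/1) is transcribed
in `network.TABLE_LAYOUT`. Channel widths scale as `round(base · α)` with
the width multiplier α restricted to [0.5, 2.0]; every listed α gives exact
integers, and fractional expansion ratios (2.5) likewise produce integer
hidden widths by round-to-nearest. Spatial resolution halves at the stem
and at the first inverted residual of stages 2–5 (256→128→64→32→16→8).
The stage table prints a stride-2 entry for stage 1's first block while its
resolution column stays at 128; we honor the resolution column (stride 1 in
stage 1). Parameter counts are unaffected by this choice; MAC totals are
not, which is one reason no exact MAC figure is asserted anywhere.

### LP-ViT block

`unfold → (inter-patch ∥ intra-patch separable attention) → add → shared
output projection → residual → FFN → residual → fold`, with parameter-free
layer normalization over the channel axis before the attention stage and
before the FFN. Unfold/fold are exact permutations (tested bit-exact), so
the block preserves pixel-level location through its global stage.

Separable attention follows the linear-complexity "separate self-attention"
design: a context projection `w_I ∈ R^{C×1}` scores each token, softmax
over the token axis (patches `N` for the inter-patch branch, within-patch
positions `P` for the intra-patch branch) yields weights, the weighted sum
of key-projected tokens forms one context vector, and that vector gates the
ReLU-rectified value projection. Degenerate token axes of length 1 fall out
of the same code path (softmax over a singleton is 1), never special-cased.

**Weight-axis convention.** All projection weights live on the channel axis
(`C×1` and `C×C`). The alternative reading with token-axis weights
(`N×N`) is dimensionally valid but produces hundreds of millions of
parameters at the first stage alone and would also make the block's size
depend on input resolution; the channel-axis reading is the only one
compatible with the published model-family sizes and keeps a block's
parameter count resolution-independent (asserted in tests). A literal
`patch_weight_axis="patch"` mode with `P×P` weights for the intra-patch
branch is kept for comparison.

**Shared output projection.** The two branches' output maps are each
other's transpose in the source algebra, i.e. a single weight applied after
the branch sum; we implement exactly that (one `C×C` map). Per block the
trainable arrays are: two context projections (2C), four key/value maps
(4C²), the shared output map (C²), and the FFN (C·2C + 2C bias + 2C·C),
totalling `9C² + 4C`.

**FFN.** Expansion factor exactly 2. As printed, the FFN composes two
affine maps with no nonlinearity between them, which would collapse to a
single affine map; the default inserts SiLU between them
(`ffn_activation=None` restores the literal affine composition). The
expansion carries a bias; the projection is bias-free (counting
convention, below).

**Normalization and residuals.** The source block diagram draws a plain
pipeline; pre-normalization and residual connections around the attention
stage and the FFN are standard transformer practice and necessary for
trainable depth, so both default on and both are toggleable
(`use_norm`, `use_residual`). With all weights zero and residuals on, the
block is the identity (tested).

### Counting convention

Calibrated against the published totals and used consistently everywhere:
convolutions and attention projections are bias-free; every normalization
layer (batch-norm in the convolutional path, layer-norm inside LP-ViT) is
**parameter-free** — affine rescaling is absorbed by the adjacent linear
maps; the classifier head keeps its bias. Under this convention the family
reproduces 2.82 / 2.84 / 2.87 M parameters at α = 1.0 for 101 / 172 / 256
classes and 11.1 M at α = 2.0, and the class-count delta law
`Δparams = Δclasses · (320α + 1)` holds exactly.

The published sizes for the fractional multipliers (0.8 M at α = 0.5,
1.8 M at 0.75, 4.5 M at 1.25) are **not** reproducible by any fixed block
design under pure width scaling: scaling the pinned 2.82 M total by α²
bounds the α = 1.25 model at 4.41 M, below the printed 4.5 M, while α = 0.5
lands near 0.72 M. Divisor-16 channel snapping (the convention of the
lineage codebase) overshoots to 4.63 M instead. The printed family is
internally inconsistent with a single scaling rule, so this package
implements the documented `round(base · α)` rule and reports its honestly
computed totals (0.72 / 1.60 / 4.39 M).

### MAC profiling

"FLOPs" columns in this model family's literature are multiply–accumulate
counts; the profiler reports MACs and says so in every header. Counted:
convolution and affine-map multiplies, the attention projections, and the
score/context weighted-sum contractions. Excluded: normalization, softmax,
activations, pooling, and plain element-wise products. No published MAC
value is asserted (the source tables disagree by ~2% for identical
configurations, and the stage-1 stride ambiguity shifts totals further);
the suite asserts orderings instead — e.g. the quadratic multi-head
attention ablation strictly exceeds the canonical model's MACs.

### Ablation variants

Built from the same config: `cnn_only` drops the attention stacks;
`vit_only` replaces each stage's convolution stack with one strided 3×3
downsampling convolution (the table's downsampling chain is preserved);
`mha` swaps each LP-ViT block for textbook multi-head attention over the
unfolded patch tokens in the same unfold/fold wrapper. The MHA head count
is not stated in the source (default 4 here), so the MHA variant's
parameter total is not treated as a reference value.

## Training recipe

AdamW; batch 32 at 256×256 by default; learning rate warms up linearly
from 1e-6 to 0.002 over the first 20k iterations, then cosine-anneals to
2e-4. The warmup endpoint is not named in the source recipe; warming to the
cosine maximum is the standard reading of "cosine schedule ranging from
0.0002 to 0.002" and makes the schedule continuous at the junction
(tested). Total iteration budget and weight decay are unstated; defaults
are 100k iterations and 0.01. Loss is cross-entropy with label smoothing
0.1 (configurable). Top-1 ties resolve to the lowest class index.
Augmentation is a generic random-resized-crop + horizontal-flip hook; the
source defers to an external pipeline that is out of scope here.

Desk-scale sanity runs use reduced conditions chosen once: α = 0.5 at
64×64 input, 200 iterations with a 30-iteration warmup, 4 classes ×
40 training / 12 held-out images. At these sizes one full run takes a few
minutes on one CPU.

## Numerical stack

Layers, autodiff and the optimizer are implemented on NumPy
(`ehfrnet.nn`): a tape-based reverse-mode engine with broadcasting-aware
gradients, a grouped 2-D convolution expressed as nine BLAS contractions
per 3×3 kernel, and softmax computed with a gradient-free max shift.
Gradient accumulation never mutates a possibly-shared array in place.
Primitives are verified against central-difference numeric gradients in
float64; the network trains in float32. Batch norms keep running statistics
for evaluation mode. Determinism: with fixed seeds, generation, batching
and training are reproducible on a single device (byte-identical datasets,
identical loss traces).

## Synthetic corpus

The generator emulates the statistical premise of fine-grained dish
recognition — same ingredients, different arrangement. Every class draws
the identical multiset of procedurally drawn motifs (a radial blob, a
striped disc, a granular disc; three of each by default) and differs only
in which cell of a 3×3 grid each motif occupies; per-image jitter (default
4 px at 256) and additive Gaussian noise (σ = 0.03 in [0,1] units) provide
intra-class variability. Layouts are distinct per class and derived
deterministically from the seed; `sample_offset` yields held-out images
with the same layouts but fresh noise. Consequently an image-wide intensity
histogram is class-uninformative (a nearest-centroid histogram baseline
scores near chance, tested), while any model that can use spatial
arrangement separates the classes.

What passing on this corpus does and does not show: it demonstrates that
the architecture can exploit purely global layout signal that defeats a
local-statistics baseline, under controlled, high-SNR conditions. It does
not demonstrate photographic-domain performance — real food imagery adds
texture diversity, lighting, occlusion, non-rigid deformation and label
noise that the generator deliberately omits.

## Known limitations

- Inference speed: the NumPy stack is built for correctness and desk-scale
  experiments, not throughput; a 256×256 forward pass of the α=1.0 model
  takes on the order of a second per image on one CPU.
- Non-divisible spatial sizes are an error by design (no silent padding);
  the full network therefore requires inputs that are multiples of 64.
- The MAC convention is one of several defensible choices; comparisons
  across profilers should use orderings, not absolute values.
- Published sizes at fractional width multipliers are approximated to
  within ~4–10% for the reasons given above; the α = 1.0 and α = 2.0
  figures are reproduced exactly at their printed precision.
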