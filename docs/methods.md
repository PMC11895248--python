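# Methods

## Problem and model

Microaneurysm segmentation is a binary pixel-labelling problem with two
defining pathologies: the positive class is minuscule (lesions of 1–4 px
radius at 512×512, typically < 0.1 % of pixels) and the positives are
locally confusable with vessels.  The package addresses both the way the
field does: aggressive contrast normalisation of the green channel,
patch-based training so every 64×64 tile contributes a gradient at lesion
scale, and attention mechanisms that let the network reweight channels,
locations and skip connections.

The network is a standard U-Net skeleton — double 3×3 convolution + ReLU
per stage, 2×2 max-pool downsampling, 2×2 transposed-convolution
upsampling, skip connections, 1×1 sigmoid head — with three multiplicative
attention mechanisms:

- **Channel attention**: global average- and max-pooled channel
  descriptors pass through a shared MLP (hidden width C/r, ReLU after the
  first layer), are summed and squashed: M_c = σ(MLP(avg) + MLP(max)).
- **Spatial attention**: channel-wise mean and max maps, concatenated and
  convolved with one 7×7 kernel: M_s = σ(f^{7×7}([avg; max])).
- **CBAM** applies them sequentially, channel first (the arrangement that
  works best empirically for this family of modules).
- **Attention gates**: skip features s and the coarser decoder signal g
  are projected to a common width by 1×1 convolutions, g is bilinearly
  resampled to s's grid, and α = σ(ψ(ReLU(θ(s) + φ(g)))) scales s before
  concatenation.

All attention outputs are sigmoid-valued, hence strictly inside (0,1):
every mechanism is an elementwise contraction (|out| ≤ |in|), a property
the tests assert.  With `use_cbam=False` and `use_ag=False` the network
reduces exactly to a plain U-Net of the same widths (verified by an
independent parameter-count computation).

## Numerical engine

No deep-learning framework is used; `masegnet.nn` is a compact
reverse-mode autodiff engine over numpy (float32): dynamic graph,
topological backward sweep, im2col + GEMM convolutions whose input
gradient is reassembled by k² strided adds.  Every op's analytic gradient
is tested against central finite differences on float64 inputs; max-pool
and channel-max ties split the gradient equally (a deterministic
subgradient).  Weights are He-uniform initialised from a single seeded
numpy Generator, so networks, shuffles and therefore whole training
histories are bit-reproducible on a fixed platform with a fixed BLAS
thread count.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `target_size` | 512 px | working resolution after border crop |
| `clahe_tiles` | (8, 8) | non-overlapping CLAHE grid |
| `clahe_clip` | 2.0 | histogram-count convention; mapped to the normalized clip of the underlying implementation as clip/256 |
| `gamma` | 0.9 | power-law brightening; < 1 is pointwise non-decreasing |
| NLM `h`, windows | 10, 7/21 | filter strength on the [0,255] scale; template/search full widths (the filter is named by the recipe, strengths are the common defaults) |
| `patch_size` | 64 px | 64 patches per 512×512 frame |
| `base_filters`/`depth` | 32 / 4 | widths double per stage → 512-filter bottleneck; the 256-bottleneck ablation uses base 16 |
| `reduction_ratio` | 16 | channel-attention bottleneck (reference default for CBAM-style modules) |
| AG `inter_channels` | skip/2 | projection width inside the gate |
| `batch_size`/`epochs` | 16 / 40 | reference training recipe |
| lr schedule | 1e-3, ×0.5, patience 5, floor 1e-5 | plateau halving on validation loss |
| BCE clamp ε | 1e-7 | log stability |
| binarisation threshold | 0.5 | probability → mask |

Open choices resolved as package decisions: the decoder applies the
attention gate to the raw skip (gated by the coarser decoder signal)
*before* upsample-concat-convolve, following the attention-U-Net lineage;
the gating signal is resampled bilinearly; the bottleneck block carries
CBAM too (toggleable via `bottleneck_cbam`); no batch normalisation by
default (blocks are conv + ReLU), with a `use_batchnorm` flag; plateau
"improvement" means a decrease > 1e-4; focal-loss ablation uses γ=2,
α=0.25; the validation set that drives the scheduler is a seeded 10 %
holdout of the training patches — never the test set.  Residual margins
when the patch size does not divide a dimension are dropped (512 is
divisible by 64, so this only affects foreign sizes); masks are
re-thresholded at 0.5 after any interpolation so they stay binary.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical structure* the method targets:
a circular field of view on black; a reddish-orange background with
low-frequency texture and radial brightness falloff (so CLAHE has real
work to do); 4–10 dark quadratic-Bézier vessel strokes as confusable
distractors; 3–20 lesions of radius 1–4 px with a 10–40 % intensity drop,
strongest in the green channel (so green-channel selection is
consequential); Gaussian sensor noise (σ = 3).  Lesion centres stay
inside the field of view, are mutually separated (so connected-component
counts are well defined), and the mask marks exactly the lesion disks —
vessels are never positive.  Default lesion load is ≈ 0.05–0.2 % of
pixels, mirroring the clinical class imbalance.

It does **not** emulate optic disc, fovea, exudates/hemorrhages, vessel
branching topology, JPEG artefacts or inter-patient colour variation.
Passing tests therefore demonstrate that the pipeline's mechanics,
arithmetic and learning capacity are correct — not that the trained
weights transfer to clinical images; training on a real annotated dataset
is expected for that.

## Verification strategy and problem sizes

- Every attention operation is checked against an independent loop-based
  implementation (explicit pooling, matrix products, direct convolution,
  hand-coded bilinear resampling) to relative 1e-5 on small tensors.
- Metric identities are asserted exactly: Dice = 2·IoU/(1+IoU); the
  precision–sensitivity Dice form equals the overlap form; trapezoidal
  AUC equals Mann–Whitney pair counting to 1e-12 (ties count half).
  Empty-vs-empty Dice/IoU are defined as 1.0 (needed for lesion-free
  patches).  The ROC threshold grid is 256 even points plus the empirical
  score set when ≤ 10⁴ unique values, with (0,0) and (1,1) endpoints.
- Patch bookkeeping runs at the reference scale (64+17 images, 512×512):
  64 patches per image, 4096/1088 train/test, 16 384 after augmentation.
- The capacity check trains the full-size default network (7.9 M
  parameters) to memorize 8 lesion-bearing patches — full-batch Adam at a
  fixed 1e-3, Dice > 0.9 within 200 epochs.  Other training tests use a
  reduced network (depth 2, 16-filter bottleneck) and a handful of
  epochs; these sizes keep the whole suite to minutes on one CPU while
  still exercising every code path at full fidelity.

## Known limitations

Stride-1 convolutions only (pooling handles all downsampling), so exotic
strides are unsupported; the engine is CPU-only and unbatched across
devices; BatchNorm running statistics are not serialised in checkpoints
(the flag is off by default); training at the full reference recipe
(16 384 patches × 40 epochs) is a multi-hour CPU job — the package keeps
the recipe as defaults but is routinely exercised at desk scale.
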