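# Methods

## Model

FPSiam learns a visual representation from unlabelled colonoscopy frames
by joint local/global instance discrimination on a siamese network. The
encoder `f_pyramid` is backbone → feature pyramid → shared projection
head; a shared prediction head cross-predicts the two views'
representations, and the negative cosine similarity with stop-gradient is
applied at both the highest-resolution (`m_local`) and lowest-resolution
(`m_global`) pyramid outputs:

```
D(p, z)   = −mean_i ⟨ p_i/‖p_i‖₂ , z_i/‖z_i‖₂ ⟩
L_level   = ½ D(p1, stopgrad(z2)) + ½ D(p2, stopgrad(z1))
L         = λ·L_local + (1−λ)·L_global ,  λ ∈ [0,1]
```

Assumptions inherited from the siamese/stop-gradient lineage: two
augmented views of one frame are semantically interchangeable; no
negative pairs are needed (important for video corpora whose adjacent
frames are near-duplicates and would be false negatives); stop-gradient
plus the prediction head suffice to avoid representational collapse.

### Architecture choices

* **Backbone taps.** Stage outputs `c1..cn` with strictly doubling
  cumulative strides. The 50-layer residual reference configuration taps
  the last block of each of its four stages: channels
  (256, 512, 1024, 2048) at strides (4, 8, 16, 32); the stem is not
  tapped (memory). Arbitrary backbones declare their taps in
  `BackboneSpec`.
* **Pyramid.** Lateral 1×1 convs to `d` channels (default 256), top-down
  nearest-neighbour 2× upsampling, element-wise addition; a 3×3 conv
  smooths the first and the last merged map (anti-aliasing); no
  nonlinearity or normalisation inside the pyramid. Intermediate merged
  maps only carry the recursion. When ceil-halved odd sizes make the 2×
  upsample one row/column too large it is cropped to the lateral's size.
* **Heads.** Projection: GAP, then fc–BN–ReLU ×2 and fc–BN; the output
  BN carries no learnable affine, following the published recipe this
  method builds on. Prediction: fc–BN–ReLU to a bottleneck (default
  512 for a 2048-D projection — a 1:4 ratio) and a plain fc back out.
  One head instance serves both pyramid levels and both branches, so
  parameters *and* BN running statistics are shared; the two levels pass
  through as separate forward calls.
* **BN.** eps 1e-5, momentum 0.1. Single-process BN is the supported
  contract; fc layers feeding a BN carry no bias.

## Training

SGD with momentum 0.9 and weight decay 1e-4 (applied to conv/fc weights
only, never to biases or BN parameters — the lineage convention). Base
learning rate 0.05, per-step (fractional-epoch) cosine annealing
`lr(t) = base · ½(1 + cos(π t/T))` over `T = 200` epochs; the prediction
head's parameter group keeps the base rate throughout ("fixed prediction
head LR"), which in this lineage is itself part of the anti-collapse
story. No warmup. Default batch 256 at crop 224; the desk-scale
experiments below use batch 32 at crop 64.

Augmentation defaults (the recipe the method inherits): random resized
crop with area scale 0.2–1.0 and aspect 3/4–4/3; horizontal flip p=0.5;
colour jitter p=0.8 with strengths (0.4, 0.4, 0.4, 0.1); grayscale
p=0.2; Gaussian blur p=0.5 with σ ∈ [0.1, 2]; ImageNet per-channel
normalisation last. Blur kernel support is configurable
(`blur_kernel_size`; default σ-dependent truncation) since the reference
recipe does not pin it. Each view of each sample consumes independent
draws from one seeded stream, so a single integer seed reproduces every
view bit-for-bit.

A single `seed` in `TrainConfig` drives parameter initialisation, data
order (per-epoch permutation streams) and per-step augmentation streams;
streams are derived as `SeedSequence([seed, salt, index])`, which is what
makes checkpoint resume reproduce the uninterrupted trajectory exactly.

## Collapse diagnostics

Collapse — every input mapped to one representation — is monitored as the
per-channel standard deviation of ℓ2-normalised representations across a
batch, compared to the `1/sqrt(dim)` value that uniformly spread unit
vectors would give. Two design points matter:

* **Tap point.** The metric reads the projection MLP's final fc output
  *before* the output BN. The output BN standardises every training
  batch per channel, so measured after it a collapsing encoder still
  shows healthy spread (we observed post-BN ratios pinned to ~0.35–0.5
  throughout runs whose pre-BN representation had collapsed by an order
  of magnitude). The pre-whitening activations are where the degeneracy
  is visible.
* **Batch.** The diagnostic forwards one augmented batch in training
  mode (batch statistics), with running statistics snapshot-restored so
  the probe has no side effects. At random initialisation the ratio sits
  near 1 by construction.

At desk scale the collapse dynamics without stop-gradient are
*intermittent*: the loss quickly approaches −1 and the metric is driven
far below the healthy band, but small-batch BN noise lets the run
repeatedly escape and re-enter the degenerate regime (ratios oscillating
between ~0.05 and ~0.6 over hundreds of steps). The stop-gradient run
never leaves the healthy band. The experiment therefore records the
diagnostic every 10 steps and judges the no-stop-gradient arm by the
minimum of its trajectory (the run is *driven below* the threshold),
while the healthy arm is judged by its final value.

## Synthetic corpus

The generator emulates the corpus properties that matter to this method,
not photorealism:

* per-sequence mucosa base colour and low-frequency texture; radial
  darkening toward a lumen centre that random-walks
  (`lumen_center_drift` px/frame);
* an AR(1) low-frequency detail field whose coefficient is the target
  inter-frame correlation `interframe_rho`, so consecutive frames
  correlate at or above the requested level (the static components only
  raise it) — this reproduces the "temporally adjacent frames are highly
  similar" structure of real colonoscopy video;
* specular highlights whose positions random-walk; compositional
  degradations (Gaussian blur, foam speckle) on sub-seeded streams;
* optionally one polyp per sequence, rendered as a shaded ellipsoid bump
  whose exact above-threshold support defines its bounding box
  (0-based, top-left, `[x, y, w, h]` — the COCO dialect the downstream
  detection ecosystem consumes).

What it does **not** emulate: real mucosal texture statistics, camera
motion blur patterns, instrument occlusions, patient variability.
Passing tests therefore demonstrate the *mechanics* of the method
(objective, geometry, schedule, collapse behaviour) — not that the
learned representation transfers to real polyp detection, which requires
the full-scale corpus and a downstream detector and is out of scope.

## Desk-scale experiment sizes

The pre-training experiments use a 3-stage fixture backbone (8/16/32
channels, strides 2/4/8), pyramid `d=16`, projection 64→32 with an
8-wide prediction bottleneck (keeping the 1:4 bottleneck ratio of the
full architecture), 512 synthetic 64×64 frames, batch 32, 1200 SGD
steps per arm with the collapse diagnostic sampled every 10 steps.
These sizes keep a full two-arm collapse experiment to roughly ten
minutes on one CPU while preserving every structural property of the
full configuration (multi-scale taps, shared heads, BN semantics,
schedule shape).

## Numerical notes

* Exact zero-norm vectors in `D` raise by default; a configurable
  `eps` clamps norms as `sqrt(‖v‖² + eps²)` for production robustness.
* Batch reduction of `D` is the mean over samples.
* Odd-size pyramid levels: ceil-halving in the backbone, crop-to-lateral
  after upsampling in the pyramid (exact for even geometry).
* New conv/fc layers initialise with fan-based schemes (He-normal for
  convs, uniform ±1/sqrt(fan_in) for fc) under the run's seed.
* All tensors are float32; the autodiff engine accumulates gradients in
  float32.

## Known limitations

* Single-process training only; the BN "synchronised across devices"
  notion degenerates to plain BN here (a documented extension point).
* The numpy-based network core is CPU-bound and desk-scale; it is not a
  route to pre-training on an 861k-frame corpus.
* `init="imagenet"` expects a locally supplied weights file in the
  package's own checkpoint layout; no weights are downloaded.
* Downstream detector fine-tuning and mAP evaluation are out of scope;
  the hand-off artefact is the backbone-only checkpoint.
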