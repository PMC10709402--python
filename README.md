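# fpsiam

Self-supervised pre-training for colonoscopy imagery with a
**feature-pyramid siamese network** (FPSiam).

## The problem

Polyp detectors are trained on annotated colonoscopy frames, but expert
bounding-box annotation is expensive while *unlabelled* colonoscopy video
is abundant. Self-supervised pre-training learns a visual representation
from the unlabelled frames; the backbone is then handed off to a
downstream detector and fine-tuned on the small labelled set. Generic
instance-discrimination methods compare only the backbone's final,
low-resolution feature map, which carries global semantics but little of
the geometric detail that dense prediction (detection) needs — and
negative-pair contrastive methods are actively harmed by colonoscopy
video, whose temporally adjacent frames are near-duplicates that get
wrongly pushed apart as "negatives".

FPSiam addresses both points. It is a SimSiam-style siamese method (no
negative pairs) whose encoder fuses the backbone's multi-scale stage
features through a feature pyramid, and whose objective is applied
jointly at a local (high-resolution) and a global (low-resolution)
pyramid level.

## The method

Two augmented views `x1, x2` of each frame pass through a shared encoder:
backbone stages emit feature maps `c1..cn` (spatial size halving, channels
rising); lateral 1×1 convolutions and nearest-neighbour 2× top-down
upsampling with element-wise addition fuse them; 3×3 convolutions smooth
the first and last merged maps into `m_local` (at `c1` resolution) and
`m_global` (at `cn` resolution), both with `d = 256` channels. Global
average pooling and a shared 3-layer projection MLP give representations
`z_local, z_global`; a shared 2-layer bottleneck prediction MLP gives
`p_local, p_global`.

With the negative cosine similarity
`D(p, z) = −⟨p/‖p‖₂, z/‖z‖₂⟩` the per-level symmetric loss is

```
L_level = ½ D(p1, stopgrad(z2)) + ½ D(p2, stopgrad(z1))
```

and the joint objective is the convex combination

```
L = λ · L_local + (1 − λ) · L_global,    λ = 0.5 by default.
```

The stop-gradient on `z` is the sole anti-collapse mechanism. Training is
SGD (lr 0.05, momentum 0.9, weight decay 1e-4) with a per-step cosine
annealing schedule over 200 epochs; the prediction head's learning rate
stays fixed at the base rate. After pre-training only the backbone
weights are exported — pyramid and heads exist solely for pre-training.

A synthetic colonoscopy-frame generator (`fpsiam.synthdata`) emulates the
relevant corpus structure — mucosa texture, lumen darkening, specular
highlights, optional polyp blobs with COCO-format boxes, and the high
inter-frame similarity of video — so the whole pipeline runs at desk
scale without any download.

## Worked example

```python
import fpsiam as fp

frames = fp.make_corpus(512, frame_size=64, seq_len=32, seed=5)
model = fp.FPSiamModel(
    frames,
    backbone_spec=fp.tiny_backbone_spec(),
    augment_config=fp.AugmentationConfig(crop_size=64),
    pyramid_config=fp.PyramidConfig(d=16, n_levels=3),
    head_config=fp.HeadConfig(proj_in=16, proj_hidden=64, proj_out=32,
                              pred_hidden=8),
    train_config=fp.TrainConfig(batch_size=32, epochs=200, seed=0),
)
results = model.fit(max_steps=200)
print(results.summary())
results.export_backbone("backbone.npz")
```

prints (abridged):

```
FPSiam pre-training results
============================================================
frames: 512   batch: 32   steps run: 200
schedule: SGD lr=0.05 momentum=0.9 wd=0.0001, cosine over 200 epochs (prediction head fixed)
lambda (local/global weight): 0.5
------------------------------------------------------------
                         first        last
L_total                -0.0143     -0.4209
L_local                -0.0039     -0.3230
L_global               -0.0247     -0.5187
lr (encoder)            0.0500      0.0495
------------------------------------------------------------
collapse metric (local): 0.1270 (reference 1/sqrt(d) = 0.1768, ratio 0.72)
collapse metric (global): 0.1142 (reference 1/sqrt(d) = 0.1768, ratio 0.65)
```

`L_total` is the λ-weighted negative cosine similarity (−1 would mean the
two views' representations agree perfectly); it decreases as the encoder
learns augmentation-invariant features. The collapse metric is the
per-channel standard deviation of the ℓ2-normalised representations
across a batch; a healthy run sits near the `1/sqrt(dim)` reference,
while a collapsed encoder (all inputs mapped to one point) drives it to
zero. Training the same model with `stop_gradient=False` demonstrates
exactly that failure.

The command line mirrors the library:

```
fpsiam synth    --config synth.yaml --out corpus/
fpsiam pretrain --config cfg.yaml --out model.npz
fpsiam export   --ckpt model.npz --out backbone.npz
fpsiam diagnose --ckpt model.npz --data corpus/
```

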