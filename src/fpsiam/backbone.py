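"""Stage-structured convolutional backbones and multi-scale feature taps.

The feature pyramid consumes per-stage feature maps ``c1..cn`` whose
spatial sizes halve stage to stage (a scaling step of 2) while channel
counts grow.  This module provides:

* :class:`BackboneSpec` — declarative description of the taps (channels,
  cumulative strides, initialisation);
* a generic plain stage CNN (:class:`ConvStageBackbone`) used for small
  fixtures and custom configurations;
* a residual bottleneck backbone (:class:`ResidualBackbone`) whose
  ``resnet50`` configuration reproduces the reference 50-layer network's
  stage geometry: taps after stages conv2-conv5 with channels
  (256, 512, 1024, 2048) at cumulative strides (4, 8, 16, 32).  The stem
  is not tapped.
* :func:`extract_multiscale` — runs the bottom-up pathway and validates
  the halving-chain shape contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class BackboneSpec:
    """Declarative description of a backbone's tapped stages.

    ``stage_strides`` are cumulative downsampling factors relative to the
    input and must double between consecutive taps.  ``init`` is one of
    ``random`` (seeded), ``imagenet`` / ``checkpoint`` (load parameters
    from ``weights_path``).
    """

    name: str = "resnet50"
    stage_channels: Tuple[int, ...] = (256, 512, 1024, 2048)
    stage_strides: Tuple[int, ...] = (4, 8, 16, 32)
    init: str = "random"
    weights_path: Optional[str] = None
    seed: int = 0
    # for generic conv-stage backbones: conv layers per stage
    blocks_per_stage: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        n = len(self.stage_channels)
        if n < 1 or len(self.stage_strides) != n:
            raise ValueError("stage_channels and stage_strides must be "
                             "non-empty and equal-length")
        for a, b in zip(self.stage_strides, self.stage_strides[1:]):
            if b != 2 * a:
                raise ValueError(
                    f"stage strides must double between taps, got {a} -> {b}")
        if self.init not in {"random", "imagenet", "checkpoint"}:
            raise ValueError(f"unknown init mode {self.init!r}")
        if self.init in {"imagenet", "checkpoint"} and not self.weights_path:
            raise ValueError(f"init={self.init!r} requires weights_path")

    @property
    def n_stages(self) -> int:
        return len(self.stage_channels)


@dataclass
class MultiScaleFeatures:
    """Ordered per-stage feature maps c1..cn (finest to coarsest)."""

    maps: List[Tensor]

    def __post_init__(self) -> None:
        for i, (a, b) in enumerate(zip(self.maps, self.maps[1:])):
            ha, wa = a.shape[2], a.shape[3]
            hb, wb = b.shape[2], b.shape[3]
            if hb != -(-ha // 2) or wb != -(-wa // 2):
                raise ValueError(
                    f"level {i + 2} is {hb}x{wb}, expected ceil-half of "
                    f"{ha}x{wa}")
        for i, m in enumerate(self.maps):
            if not np.isfinite(m.data).all():
                raise ValueError(f"non-finite values in feature map c{i + 1}")

    @property
    def channels(self) -> Tuple[int, ...]:
        return tuple(m.shape[1] for m in self.maps)

    @property
    def spatial_sizes(self) -> Tuple[Tuple[int, int], ...]:
        return tuple((m.shape[2], m.shape[3]) for m in self.maps)


class _Bottleneck(nn.Module):
    """1x1 - 3x3 - 1x1 residual block with expansion 4."""

    expansion = 4

    def __init__(self, in_ch: int, width: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = nn.Conv2d(in_ch, width, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                       bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + shortcut).relu()


class ResidualBackbone(nn.Module):
    """Bottleneck residual network tapped at the end of every stage.

    ``blocks=(3, 4, 6, 3)`` with ``widths=(64, 128, 256, 512)`` is the
    50-layer reference configuration.  The stem (7x7/2 conv + 3x3/2 max
    pool) brings the input to stride 4 before the first tapped stage.
    """

    def __init__(self, blocks: Sequence[int] = (3, 4, 6, 3),
                 widths: Sequence[int] = (64, 128, 256, 512),
                 stem_channels: int = 64, in_channels: int = 3,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.stem = nn.Sequential(
            nn.Conv2d(in_channels, stem_channels, 7, stride=2, padding=3,
                      bias=False, rng=rng),
            nn.BatchNorm2d(stem_channels),
            nn.ReLU(),
            nn.MaxPool2d(3, stride=2, padding=1),
        )
        stages = []
        in_ch = stem_channels
        for si, (nb, width) in enumerate(zip(blocks, widths)):
            layers = []
            for bi in range(nb):
                stride = 2 if (bi == 0 and si > 0) else 1
                layers.append(_Bottleneck(in_ch, width, stride, rng))
                in_ch = width * _Bottleneck.expansion
            stages.append(nn.Sequential(*layers))
        self.stages = stages
        for i, s in enumerate(stages):
            self._modules[f"stage{i + 1}"] = s
        self.stage_channels = tuple(w * _Bottleneck.expansion for w in widths)
        self.stage_strides = tuple(4 * 2 ** i for i in range(len(blocks)))

    def forward_stages(self, x: Tensor) -> List[Tensor]:
        out = self.stem(x)
        feats = []
        for stage in self.stages:
            out = stage(out)
            feats.append(out)
        return feats

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_stages(x)[-1]


class ConvStageBackbone(nn.Module):
    """Plain conv-BN-ReLU stage CNN for fixtures and custom taps.

    Stage ``i`` downsamples by ``stage_strides[i] / stage_strides[i-1]``
    (a scaling step of 2) using stride-2 3x3 convolutions; the
    first stage may carry a larger entry stride, realised as a chain of
    stride-2 convs.
    """

    def __init__(self, stage_channels: Sequence[int],
                 stage_strides: Sequence[int],
                 blocks_per_stage: Optional[Sequence[int]] = None,
                 in_channels: int = 3,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        if blocks_per_stage is None:
            blocks_per_stage = [1] * len(stage_channels)
        stages = []
        in_ch = in_channels
        prev_stride = 1
        for ch, cum_stride, nb in zip(stage_channels, stage_strides,
                                      blocks_per_stage):
            step = cum_stride // prev_stride
            if step * prev_stride != cum_stride or step < 1 or \
                    (step & (step - 1)) != 0:
                raise ValueError(f"stride step {cum_stride}/{prev_stride} "
                                 "is not a power of 2")
            layers: List[nn.Module] = []
            s = step
            while s > 1:
                layers += [nn.Conv2d(in_ch, ch, 3, stride=2, padding=1,
                                     bias=False, rng=rng),
                           nn.BatchNorm2d(ch), nn.ReLU()]
                in_ch = ch
                s //= 2
            for _ in range(max(0, nb - max(0, step.bit_length() - 1))):
                layers += [nn.Conv2d(in_ch, ch, 3, stride=1, padding=1,
                                     bias=False, rng=rng),
                           nn.BatchNorm2d(ch), nn.ReLU()]
                in_ch = ch
            stages.append(nn.Sequential(*layers))
            prev_stride = cum_stride
        self.stages = stages
        for i, s_ in enumerate(stages):
            self._modules[f"stage{i + 1}"] = s_
        self.stage_channels = tuple(stage_channels)
        self.stage_strides = tuple(stage_strides)

    def forward_stages(self, x: Tensor) -> List[Tensor]:
        feats = []
        out = x
        for stage in self.stages:
            out = stage(out)
            feats.append(out)
        return feats

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_stages(x)[-1]


def resnet50_spec(init: str = "random", weights_path: Optional[str] = None,
                  seed: int = 0) -> BackboneSpec:
    """Spec for the reference 50-layer residual backbone."""
    return BackboneSpec(name="resnet50", stage_channels=(256, 512, 1024, 2048),
                        stage_strides=(4, 8, 16, 32), init=init,
                        weights_path=weights_path, seed=seed)


def tiny_backbone_spec(seed: int = 0) -> BackboneSpec:
    """A small fixture backbone: 3 stages, <=32 channels, runs at 64x64."""
    return BackboneSpec(name="convstage", stage_channels=(8, 16, 32),
                        stage_strides=(2, 4, 8), init="random", seed=seed)


def load_backbone(spec: BackboneSpec) -> nn.Module:
    """Construct (and optionally initialise from disk) a backbone.

    ``init="random"`` is fully seeded from ``spec.seed``; ``imagenet`` and
    ``checkpoint`` load a parameter dict from a local ``.npz`` file whose
    keys match the backbone's ``state_dict`` layout.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.name == "resnet50":
        net: nn.Module = ResidualBackbone(rng=rng)
    elif spec.name in {"convstage", "tiny"}:
        net = ConvStageBackbone(spec.stage_channels, spec.stage_strides,
                                blocks_per_stage=spec.blocks_per_stage, rng=rng)
    else:
        raise ValueError(f"unknown backbone name {spec.name!r}")
    if net.stage_channels != tuple(spec.stage_channels) or \
            net.stage_strides != tuple(spec.stage_strides):
        raise ValueError(
            "constructed backbone does not match spec: channels "
            f"{net.stage_channels} vs {tuple(spec.stage_channels)}, strides "
            f"{net.stage_strides} vs {tuple(spec.stage_strides)}")
    if spec.init in {"imagenet", "checkpoint"}:
        path = Path(spec.weights_path)
        if not path.exists():
            raise FileNotFoundError(f"backbone weights not found: {path}")
        with np.load(path) as data:
            net.load_state_dict({k: data[k] for k in data.files})
    return net


def extract_multiscale(backbone: nn.Module, images) -> MultiScaleFeatures:
    """Run the bottom-up pathway and return validated stage features."""
    x = images if isinstance(images, Tensor) else Tensor(np.asarray(images))
    h, w = x.shape[2], x.shape[3]
    for i, stride in enumerate(backbone.stage_strides):
        if h // stride < 1 or w // stride < 1:
            raise ValueError(
                f"input {h}x{w} too small to survive downsampling to stage "
                f"{i + 1} (cumulative stride {stride})")
    feats = backbone.forward_stages(x)
    ms = MultiScaleFeatures(maps=feats)
    expected = tuple(backbone.stage_channels)
    if ms.channels != expected:
        raise ValueError(f"stage channels {ms.channels} != spec {expected}")
    return ms
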