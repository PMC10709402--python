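"""Feature-pyramid fusion: lateral 1x1 projections, top-down merging,
and 3x3 smoothing of the two emitted maps.

The fusion stage takes the backbone's stage maps ``c1..cn`` and builds a
top-down pathway: a 1x1 convolution of ``cn`` starts the recursion; each
lower merged map is the 1x1-projected lateral plus the nearest-neighbour
2x upsample of the next-higher merged map.  Two maps are emitted after a
3x3 anti-aliasing convolution: ``m_local`` at ``c1`` resolution (local
geometry) and ``m_global`` at ``cn`` resolution (global semantics), both
with ``d`` channels.  There is no nonlinearity or normalisation inside
the pyramid — only convolutions, upsampling and addition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import nn
from .backbone import MultiScaleFeatures
from .nn import Tensor, upsample_nearest2x


@dataclass
class PyramidConfig:
    """Fusion-stage geometry: output channels ``d`` and level count."""

    d: int = 256
    n_levels: int = 4

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"d={self.d} must be >= 1")
        if self.n_levels < 1:
            raise ValueError(f"n_levels={self.n_levels} must be >= 1")


@dataclass
class PyramidOutputs:
    """The two fused maps forwarded to the shared projection head."""

    m_local: Tensor
    m_global: Tensor

    def __post_init__(self) -> None:
        if self.m_local.shape[1] != self.m_global.shape[1]:
            raise ValueError("m_local and m_global must share channel count")
        for name in ("m_local", "m_global"):
            if not np.isfinite(getattr(self, name).data).all():
                raise ValueError(f"non-finite values in {name}")


class FeaturePyramid(nn.Module):
    """Lateral + top-down fusion module.

    Parameters are one 1x1 lateral conv per level plus two 3x3 smoothing
    convs (for the first and last merged maps).  Intermediate merged maps
    are carriers of the recursion only and are not emitted.
    """

    def __init__(self, in_channels: Sequence[int], config: PyramidConfig,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if len(in_channels) != config.n_levels:
            raise ValueError(f"got {len(in_channels)} input levels, config "
                             f"says n_levels={config.n_levels}")
        rng = rng if rng is not None else np.random.default_rng()
        self.config = config
        self.laterals = [nn.Conv2d(c, config.d, 1, rng=rng) for c in in_channels]
        for i, lat in enumerate(self.laterals):
            self._modules[f"lateral{i + 1}"] = lat
        self.smooth_local = nn.Conv2d(config.d, config.d, 3, padding=1, rng=rng)
        self.smooth_global = nn.Conv2d(config.d, config.d, 3, padding=1, rng=rng)

    def forward(self, features: MultiScaleFeatures) -> PyramidOutputs:
        maps = features.maps
        if len(maps) != self.config.n_levels:
            raise ValueError(f"expected {self.config.n_levels} feature maps, "
                             f"got {len(maps)}")
        # start map: 1x1 projection of the coarsest level cn
        merged = self.laterals[-1](maps[-1])
        start = merged
        for i in range(len(maps) - 2, -1, -1):
            lateral = self.laterals[i](maps[i])
            up = upsample_nearest2x(merged)
            th, tw = lateral.shape[2], lateral.shape[3]
            if up.shape[2] < th or up.shape[3] < tw:
                raise ValueError(
                    f"upsampled map {up.shape[2]}x{up.shape[3]} smaller than "
                    f"lateral {th}x{tw} at level {i + 1}")
            if up.shape[2] != th or up.shape[3] != tw:
                # odd-size policy: ceil-halved levels upsample one row/col
                # large; crop back to the lateral's size before addition
                up = up[:, :, :th, :tw]
            merged = lateral + up
        m_local = self.smooth_local(merged)
        m_global = self.smooth_global(start)
        return PyramidOutputs(m_local=m_local, m_global=m_global)


def build_pyramid(features: MultiScaleFeatures, config: PyramidConfig,
                  module: Optional[FeaturePyramid] = None,
                  rng: Optional[np.random.Generator] = None) -> PyramidOutputs:
    """Fuse multi-scale features into (m_local, m_global).

    A :class:`FeaturePyramid` module may be supplied to reuse trained
    parameters; otherwise a fresh seeded module is built from the feature
    channel counts.
    """
    if module is None:
        module = FeaturePyramid([m.shape[1] for m in features.maps],
                                config, rng=rng)
    return module(features)
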