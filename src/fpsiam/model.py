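"""Assembly of the full siamese network: backbone -> pyramid -> heads.

The feature-pyramid encoder ``f_pyramid`` is the composition of the
bottom-up backbone, the pyramid fusion stage and the shared projection
head; the prediction head sits on top during pre-training only.  Both
siamese branches are the same module objects (weight sharing is object
identity), so one forward per view suffices.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from . import nn
from .backbone import BackboneSpec, extract_multiscale, load_backbone
from .heads import (HeadConfig, PredictionHead, Predictions, ProjectionHead,
                    Projections)
from .nn import Tensor
from .pyramid import FeaturePyramid, PyramidConfig


class FPSiamNetwork(nn.Module):
    """Backbone + feature pyramid + shared projection/prediction heads."""

    def __init__(self, backbone_spec: BackboneSpec,
                 pyramid_config: Optional[PyramidConfig] = None,
                 head_config: Optional[HeadConfig] = None,
                 seed: int = 0):
        super().__init__()
        self.backbone_spec = backbone_spec
        n = backbone_spec.n_stages
        if pyramid_config is None:
            pyramid_config = PyramidConfig(n_levels=n)
        if pyramid_config.n_levels != n:
            raise ValueError("pyramid n_levels must match backbone stages")
        if head_config is None:
            head_config = HeadConfig(proj_in=pyramid_config.d)
        if head_config.proj_in != pyramid_config.d:
            raise ValueError("head proj_in must equal pyramid d")
        self.pyramid_config = pyramid_config
        self.head_config = head_config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF95]))
        self.backbone = load_backbone(backbone_spec)
        self.pyramid = FeaturePyramid(backbone_spec.stage_channels,
                                      pyramid_config, rng=rng)
        self.projection = ProjectionHead(head_config, rng=rng)
        self.prediction = PredictionHead(head_config, rng=rng)

    # -- encoder -----------------------------------------------------------
    def encode(self, x) -> Projections:
        """f_pyramid: images -> (z_local, z_global)."""
        feats = extract_multiscale(self.backbone, x)
        pyr = self.pyramid(feats)
        return Projections(z_local=self.projection(pyr.m_local),
                           z_global=self.projection(pyr.m_global))

    def forward(self, x) -> Projections:
        return self.encode(x)

    def predict_heads(self, z: Projections) -> Predictions:
        return Predictions(p_local=self.prediction(z.z_local),
                           p_global=self.prediction(z.z_global))

    def forward_views(self, view1, view2
                      ) -> Tuple[Tuple[Tensor, ...], Tuple[Tensor, ...]]:
        """Run both views; returns (p1, z1, p2, z2) per feature level.

        The tuples are ordered for the symmetric loss:
        ``local = (p1_local, z1_local, p2_local, z2_local)`` and the same
        for the global level.
        """
        z1 = self.encode(view1)
        z2 = self.encode(view2)
        p1 = self.predict_heads(z1)
        p2 = self.predict_heads(z2)
        local = (p1.p_local, z1.z_local, p2.p_local, z2.z_local)
        global_ = (p1.p_global, z1.z_global, p2.p_global, z2.z_global)
        return local, global_
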