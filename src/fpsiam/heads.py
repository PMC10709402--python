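"""Shared projection and prediction heads.

One projection head (global average pooling followed by a 3-layer MLP)
serves both pyramid levels and both siamese branches; one prediction head
(2-layer bottleneck MLP) likewise.  Sharing is by object identity — the
same module instance is called at every site, so its parameters and
batch-norm running statistics are common to all call sites.

Projection MLP: fc-BN-ReLU, fc-BN-ReLU, fc-BN (output layer has BN but no
ReLU).  Prediction MLP: fc-BN-ReLU down to the bottleneck width, then a
plain fc back out (no BN, no ReLU on the output).  Fully connected layers
feeding a BN carry no bias (the BN shift subsumes it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class HeadConfig:
    """Widths of the projection and prediction MLPs."""

    proj_in: int = 256
    proj_hidden: int = 2048
    proj_out: int = 2048
    pred_hidden: int = 512

    def __post_init__(self) -> None:
        for name in ("proj_in", "proj_hidden", "proj_out", "pred_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class Projections:
    z_local: Tensor
    z_global: Tensor


@dataclass
class Predictions:
    p_local: Tensor
    p_global: Tensor


def global_avg_pool(m: Tensor) -> Tensor:
    """Spatial mean: (batch, d, H, W) -> (batch, d)."""
    return m.mean(axis=(2, 3))


class ProjectionHead(nn.Module):
    def __init__(self, config: HeadConfig,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.config = config
        self.mlp = nn.Sequential(
            nn.Linear(config.proj_in, config.proj_hidden, bias=False, rng=rng),
            nn.BatchNorm1d(config.proj_hidden), nn.ReLU(),
            nn.Linear(config.proj_hidden, config.proj_hidden, bias=False, rng=rng),
            nn.BatchNorm1d(config.proj_hidden), nn.ReLU(),
            nn.Linear(config.proj_hidden, config.proj_out, bias=False, rng=rng),
            # output BN carries no learnable affine, as in the SimSiam recipe
            nn.BatchNorm1d(config.proj_out, affine=False),
        )

    def _check(self, m: Tensor) -> None:
        if m.ndim != 4:
            raise ValueError(f"expected (batch, d, H, W), got shape {m.shape}")
        if m.shape[1] != self.config.proj_in:
            raise ValueError(f"channel count {m.shape[1]} != proj_in "
                             f"{self.config.proj_in}")
        if self.training and m.shape[0] < 2:
            raise ValueError("projection head in training mode needs batch >= 2 "
                             "(batch norm is degenerate on a single sample)")

    def forward(self, m: Tensor) -> Tensor:
        self._check(m)
        return self.mlp(global_avg_pool(m))

    def embed(self, m: Tensor) -> Tensor:
        """Representation before the output BN (the diagnostic tap).

        The output BN whitens each training batch, which masks a
        collapsing encoder at the head's output; collapse diagnostics
        therefore read the final fc activations prior to that whitening.
        """
        self._check(m)
        h = global_avg_pool(m)
        for layer in self.mlp.layers[:-1]:
            h = layer(h)
        return h


class PredictionHead(nn.Module):
    def __init__(self, config: HeadConfig,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.config = config
        self.mlp = nn.Sequential(
            nn.Linear(config.proj_out, config.pred_hidden, bias=False, rng=rng),
            nn.BatchNorm1d(config.pred_hidden), nn.ReLU(),
            nn.Linear(config.pred_hidden, config.proj_out, bias=True, rng=rng),
        )

    def forward(self, z: Tensor) -> Tensor:
        if z.ndim != 2 or z.shape[1] != self.config.proj_out:
            raise ValueError(f"expected (batch, {self.config.proj_out}), "
                             f"got shape {z.shape}")
        return self.mlp(z)


def project(m: Tensor, head: ProjectionHead) -> Tensor:
    """GAP + 3-layer MLP, returning a (batch, proj_out) representation."""
    return head(m)


def predict(z: Tensor, head: PredictionHead) -> Tensor:
    """Bottleneck MLP mapping one branch's z to match the other's."""
    return head(z)
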