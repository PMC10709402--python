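"""The siamese objective: negative cosine similarity with stop-gradient,
its symmetric two-view form, and the lambda-weighted local/global total.

For prediction p and projection z (row vectors per sample),

    D(p, z) = - mean_i < p_i / ||p_i||_2 , z_i / ||z_i||_2 >

The symmetric loss cross-predicts the two views and stops the gradient
through the projection argument,

    L = 1/2 D(p1, stopgrad(z2)) + 1/2 D(p2, stopgrad(z1)),

which is the sole anti-collapse mechanism — z is a constant in each term,
so no gradient reaches the parameters through the stopped branch.  The
joint objective weighs the local and global feature levels:

    L_total = lambda * L_local + (1 - lambda) * L_global,  lambda in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .nn import Tensor


@dataclass
class LossBreakdown:
    """Per-batch loss terms; all values are plain floats."""

    L_local: float
    L_global: float
    lambda_weight: float
    L_total: float

    def __post_init__(self) -> None:
        recomposed = (self.lambda_weight * self.L_local
                      + (1 - self.lambda_weight) * self.L_global)
        if abs(recomposed - self.L_total) > 1e-5:
            raise ValueError("L_total does not recompose from its terms")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _l2_normalize(v: Tensor, eps: float) -> Tensor:
    sq = (v * v).sum(axis=1, keepdims=True)
    norms = sq.data.ravel()
    if eps == 0.0 and np.any(norms <= 0.0):
        raise ValueError("zero-norm vector in cosine similarity; pass eps > 0 "
                         "to clamp if this is expected")
    return v * ((sq + eps * eps) ** -0.5)


def neg_cosine(p, z, eps: float = 0.0) -> Tensor:
    """Batch-mean negative cosine similarity D(p, z) in [-1, 1].

    ``eps`` (default 0: exact, raising on zero norms) stabilises the
    norm as sqrt(||v||^2 + eps^2) for production training.
    """
    p, z = _as_tensor(p), _as_tensor(z)
    if p.shape != z.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {z.shape}")
    if p.ndim == 1:
        p, z = p.reshape(1, -1), z.reshape(1, -1)
    pn = _l2_normalize(p, eps)
    zn = _l2_normalize(z, eps)
    return -(pn * zn).sum(axis=1).mean()


def symmetric_loss(p1, z1, p2, z2, eps: float = 0.0,
                   stop_gradient: bool = True) -> Tensor:
    """Symmetrised cross-prediction loss with stop-gradient on z.

    ``stop_gradient=False`` removes the detach and exists only for
    collapse diagnostics; training without it collapses.
    """
    p1, z1 = _as_tensor(p1), _as_tensor(z1)
    p2, z2 = _as_tensor(p2), _as_tensor(z2)
    if stop_gradient:
        z1, z2 = z1.detach(), z2.detach()
    return 0.5 * neg_cosine(p1, z2, eps) + 0.5 * neg_cosine(p2, z1, eps)


def fpsiam_loss(local: Tuple, global_: Tuple, lambda_weight: float = 0.5,
                eps: float = 0.0, stop_gradient: bool = True
                ) -> Tuple[Tensor, LossBreakdown]:
    """Joint local/global objective.

    ``local`` and ``global_`` are each ``(p1, z1, p2, z2)`` tuples of the
    prediction/projection batches at that feature level.  Returns the
    differentiable total and a float :class:`LossBreakdown`.
    """
    if not 0.0 <= lambda_weight <= 1.0:
        raise ValueError(f"lambda_weight={lambda_weight} outside [0, 1]")
    l_local = symmetric_loss(*local, eps=eps, stop_gradient=stop_gradient)
    l_global = symmetric_loss(*global_, eps=eps, stop_gradient=stop_gradient)
    total = lambda_weight * l_local + (1.0 - lambda_weight) * l_global
    breakdown = LossBreakdown(
        L_local=float(l_local.data), L_global=float(l_global.data),
        lambda_weight=float(lambda_weight), L_total=float(total.data))
    return total, breakdown
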