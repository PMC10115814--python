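"""Pixel-wise cross-entropy and the three-head weighted training loss.

The network is deeply supervised: the fused decoder output M_ff and each
branch's aggregation-decoder output (M_st, M_u) are all compared with the
ground-truth mask G by a two-class softmax cross-entropy, and combined as a
convex sum

    L = α·L_ff + β·L_st + γ·L_u,      α + β + γ = 1.

The defaults (α, β, γ) = (0.5, 0.2, 0.3) weight the fused output highest and
the convolutional branch above the attention branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor


@dataclass(frozen=True)
class LossWeights:
    """Convex weights for the fused, attention-branch and conv-branch losses."""

    alpha: float = 0.5
    beta: float = 0.2
    gamma: float = 0.3

    def __post_init__(self):
        for name, v in (("alpha", self.alpha), ("beta", self.beta),
                        ("gamma", self.gamma)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-9:
            raise ValueError(
                f"loss weights must sum to 1, got "
                f"{self.alpha + self.beta + self.gamma}")


def _validate_mask(logits: Tensor, target: np.ndarray) -> np.ndarray:
    target = np.asarray(target)
    if target.shape != logits.shape[:1] + logits.shape[2:]:
        raise ValueError(
            f"mask shape {target.shape} does not match logits "
            f"{logits.shape}")
    uniq = np.unique(target)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"ground-truth mask must be binary, found {uniq}")
    return target.astype(np.int64)


def pixel_ce(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel two-class softmax cross-entropy.

    ``logits`` is (N, 2, H, W); channel 1 is the lesion class.  Equals
    ``-mean[G·log p̂ + (1-G)·log(1-p̂)]`` with p̂ the softmax foreground
    probability; ln 2 at maximal uncertainty, → 0 for a perfect prediction.
    """
    if logits.shape[1] != 2:
        raise ValueError("pixel_ce expects 2-channel logits")
    target = _validate_mask(logits, target)
    logp = logits - logits.max(axis=1, keepdims=True).detach()
    logp = logp - logp.exp().sum(axis=1, keepdims=True).log()
    onehot = np.stack([1 - target, target], axis=1).astype(logits.dtype)
    return -(logp * Tensor(onehot)).sum(axis=1).mean()


def foreground_probability(logits: Tensor) -> np.ndarray:
    """Softmax probability of the lesion channel, as a plain array."""
    return logits.softmax(axis=1).data[:, 1]


def total_loss(l_ff: Tensor | float, l_st: Tensor | float,
               l_u: Tensor | float, weights: LossWeights = LossWeights()):
    """Weighted sum of the three head losses (validates the weights)."""
    return weights.alpha * l_ff + weights.beta * l_st + weights.gamma * l_u
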