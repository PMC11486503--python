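"""Prediction head: pooling, per-vector standardization, MLP and BCE loss.

The cross-attention outputs O1, O2 (M x d) are average-pooled over the M
pattern rows and the resulting length-d vector is standardized to zero mean
and unit (population) standard deviation across its own d entries — a
per-vector normalization, not a batch statistic.  The two interaction vectors
are concatenated with the flattened similarity vector s and fed to an MLP
ending in a single logit; binary cross-entropy is computed from logits in the
numerically stable softplus form.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import MLP

__all__ = ["pool_and_standardize", "PredictionHead", "bce_loss", "sigmoid"]

STANDARDIZE_EPS = 1e-6


def pool_and_standardize(o: Tensor, normalize: bool = True) -> Tensor:
    """Column-mean over the M pattern rows, then standardize over the d entries.

    A constant pooled vector (zero deviation) maps to all zeros via the eps
    guard.  With ``normalize=False`` only the pooling is applied (ablation).
    """
    pooled = o.mean(axis=-2)  # (..., d)
    if not normalize:
        return pooled
    mu = pooled.mean(axis=-1, keepdims=True)
    centred = pooled - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred / (var.sqrt() + STANDARDIZE_EPS)


class PredictionHead:
    """MLP from (inter1 || inter2 || s) to a single interaction logit."""

    def __init__(self, input_width: int, hidden: tuple[int, ...],
                 rng: np.random.Generator):
        self.input_width = input_width
        self.mlp = MLP([input_width, *hidden, 1], rng)

    def __call__(self, parts: list[Tensor]) -> Tensor:
        x = concat(parts, axis=-1) if len(parts) > 1 else parts[0]
        if x.shape[-1] != self.input_width:
            raise ValueError(
                f"head expects width {self.input_width}, got {x.shape[-1]}"
            )
        return self.mlp(x)

    def parameters(self):
        return self.mlp.parameters()


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits.

    Uses softplus(z) - y*z, which equals -[y log s(z) + (1-y) log(1-s(z))]
    and stays finite for saturated logits.
    """
    y = np.asarray(labels, dtype=np.float64).reshape(-1, 1)
    if y.size == 0:
        raise ValueError("empty batch")
    if logits.shape[-1] != 1 or logits.data.reshape(-1, 1).shape[0] != y.shape[0]:
        raise ValueError("logits and labels lengths differ")
    z = logits.reshape(y.shape[0], 1)
    return (z.softplus() - Tensor(y) * z).mean()
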