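"""Pattern self-attention pooling and the substructure similarity matrix.

A set of M learnable pattern queries attends over a molecule's GIN node
embeddings, compressing it into M "representative vectors", each read as a
substructure-pattern summary:

    Q = Q0 WQ,  K = H WK,  V = H WV
    A = softmax(Q K^T / scale)          (row-stochastic, M x N)
    O = ReLU((Q + A V) W0)              (M x d representative vectors)

Both drugs of a pair share Q0 and the projections (siamese), which makes the
M x M cosine-similarity matrix S between their representative vectors
comparable across the pair; S's entries are interpreted as interaction
strengths between substructure patterns, and its row-major flattening feeds
the prediction head.
"""

from __future__ import annotations

import logging

import numpy as np

from .autodiff import Tensor, masked_softmax
from .nn import xavier_uniform

__all__ = ["PatternSelfAttention", "cosine_matrix", "flatten_similarity", "attention_scale"]

log = logging.getLogger(__name__)


def attention_scale(d: int, attn_scale: str) -> float:
    if attn_scale == "sqrt_d":
        return float(np.sqrt(d))
    if attn_scale == "d":
        return float(d)
    raise ValueError(f"attn_scale must be 'sqrt_d' or 'd', got {attn_scale!r}")


class PatternSelfAttention:
    """M learnable queries attending over node embeddings (single head, no biases)."""

    def __init__(self, d: int, n_patterns: int, rng: np.random.Generator,
                 attn_scale: str = "sqrt_d"):
        if n_patterns < 1:
            raise ValueError("need at least one pattern")
        self.d = d
        self.n_patterns = n_patterns
        self.scale = attention_scale(d, attn_scale)
        self.patterns = xavier_uniform((n_patterns, d), rng)  # Q0
        self.w_q = xavier_uniform((d, d), rng)
        self.w_k = xavier_uniform((d, d), rng)
        self.w_v = xavier_uniform((d, d), rng)
        self.w_o = xavier_uniform((d, d), rng)

    def __call__(self, nodes: Tensor, valid: np.ndarray | None = None
                 ) -> tuple[Tensor, Tensor]:
        """Return (attention M x N row-stochastic, representative vectors M x d).

        ``nodes`` may be N x d or batched B x N x d with ``valid`` a
        B x 1 x N mask of real (non-padded) atoms.
        """
        if nodes.shape[-2] == 0:
            raise ValueError("graph with zero nodes")
        if nodes.shape[-1] != self.d:
            raise ValueError(f"node width {nodes.shape[-1]} != model width {self.d}")
        q = self.patterns @ self.w_q
        k = nodes @ self.w_k
        v = nodes @ self.w_v
        logits = (q @ k.T) * (1.0 / self.scale)
        attn = masked_softmax(logits, valid)
        rep = ((q + attn @ v) @ self.w_o).relu()
        if not np.all(np.isfinite(rep.data)):
            raise FloatingPointError("non-finite representative vectors")
        return attn, rep

    def parameters(self):
        return [self.patterns, self.w_q, self.w_k, self.w_v, self.w_o]


def cosine_matrix(rep_a: Tensor, rep_b: Tensor, eps: float = 1e-12) -> Tensor:
    """Pairwise cosine similarities between two sets of representative vectors.

    Entry (i, j) is <z_i^a, z_j^b> / (||z_i^a|| ||z_j^b||).  A zero-norm row
    (possible after ReLU) yields cosine 0 rather than NaN; the tiny ``eps`` in
    the denominator implements that limit smoothly.
    """
    if rep_a.shape[-1] != rep_b.shape[-1]:
        raise ValueError("representative vector widths differ")
    norm_a = (rep_a * rep_a).sum(axis=-1, keepdims=True).sqrt()
    norm_b = (rep_b * rep_b).sum(axis=-1, keepdims=True).sqrt()
    if np.any(norm_a.data < eps) or np.any(norm_b.data < eps):
        log.debug("zero-norm representative row; cosine defined as 0")
    return (rep_a @ rep_b.T) / (norm_a @ norm_b.T + eps)


def flatten_similarity(s: Tensor) -> Tensor:
    """Row-major unrolling of the M x M similarity matrix to a length-M^2 vector."""
    m1, m2 = s.shape[-2], s.shape[-1]
    if s.ndim == 2:
        return s.reshape(1, m1 * m2)
    return s.reshape(s.shape[0], m1 * m2)
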