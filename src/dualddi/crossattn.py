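"""Cross-drug interaction attention with hard threshold masking.

Each drug has its own key/value projections (slot 1 / slot 2); queries come
from one shared set of learnable patterns, tiled across the batch and
projected through a shared WQ.  The queries of one drug attend over the keys
of the other:

    A1 = softmax(Q K2^T / scale)        (row-stochastic over drug 2's atoms)
    Mask1 = [A1 >= lambda]              (hard gate, constant w.r.t. gradients)
    O1 = ReLU((Q + (A1 * Mask1) V2) WO)

and symmetrically for O2 over drug 1's keys/values.  The threshold lambda is
an absolute cutoff on softmax weights; surviving rows are NOT renormalized,
and gradients flow only through the surviving attention entries.  WO is
shared between the two directions.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, masked_softmax
from .nn import xavier_uniform
from .selfattn import attention_scale

__all__ = ["CrossAttention", "cross_attend"]


def cross_attend(
    queries: Tensor,
    keys: Tensor,
    values: Tensor,
    lam: float,
    w_o: Tensor,
    scale: float,
    valid: np.ndarray | None = None,
) -> tuple[Tensor, np.ndarray, Tensor]:
    """One attention direction: returns (raw attention, binary mask, output).

    ``valid`` masks padded key/value positions out of the softmax; the binary
    threshold mask is computed from the raw weights and treated as a constant
    during differentiation.
    """
    if lam < 0:
        raise ValueError(f"threshold lambda must be >= 0, got {lam}")
    if valid is not None and not np.all(np.asarray(valid).max(axis=-1) > 0):
        raise ValueError("a graph in the batch has zero valid nodes")
    logits = (queries @ keys.T) * (1.0 / scale)
    raw = masked_softmax(logits, valid)
    mask = (raw.data >= lam).astype(np.float64)
    filtered = raw * Tensor(mask)
    out = ((queries + filtered @ values) @ w_o).relu()
    return raw, mask, out


class CrossAttention:
    """Slot-specific keys/values, shared tiled queries, lambda-gated attention."""

    def __init__(self, d: int, n_patterns: int, lam: float, rng: np.random.Generator,
                 attn_scale: str = "sqrt_d"):
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        self.d = d
        self.n_patterns = n_patterns
        self.lam = lam
        self.scale = attention_scale(d, attn_scale)
        self.patterns = xavier_uniform((n_patterns, d), rng)
        self.w_q = xavier_uniform((d, d), rng)
        self.w_k1 = xavier_uniform((d, d), rng)
        self.w_v1 = xavier_uniform((d, d), rng)
        self.w_k2 = xavier_uniform((d, d), rng)
        self.w_v2 = xavier_uniform((d, d), rng)
        self.w_o = xavier_uniform((d, d), rng)

    def project_keys_values(self, nodes: Tensor, slot: int) -> tuple[Tensor, Tensor]:
        if slot == 1:
            return nodes @ self.w_k1, nodes @ self.w_v1
        if slot == 2:
            return nodes @ self.w_k2, nodes @ self.w_v2
        raise ValueError(f"slot must be 1 or 2, got {slot}")

    def tiled_queries(self, batch_size: int) -> Tensor:
        """The projected pattern block, replicated per batch element."""
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        q = self.patterns @ self.w_q  # (M, d)
        if batch_size == 1:
            return q
        tile = np.ones((batch_size, 1, 1))
        return Tensor(tile) * q  # broadcast to (B, M, d); identical copies

    def __call__(
        self,
        nodes_1: Tensor,
        nodes_2: Tensor,
        valid_1: np.ndarray | None = None,
        valid_2: np.ndarray | None = None,
    ) -> tuple[Tensor, Tensor, dict]:
        """Both attention directions for a pair (or padded batch of pairs).

        Returns (O1, O2, diagnostics); O1 uses drug 1's queries against drug
        2's keys/values and vice versa.  Diagnostics include the raw
        attention matrices, the binary masks and the surviving-entry fraction
        ("mask density") over valid positions.
        """
        k1, v1 = self.project_keys_values(nodes_1, 1)
        k2, v2 = self.project_keys_values(nodes_2, 2)
        batch = nodes_1.shape[0] if nodes_1.ndim == 3 else 1
        q = self.tiled_queries(batch) if nodes_1.ndim == 3 else self.patterns @ self.w_q
        a1, mask1, o1 = cross_attend(q, k2, v2, self.lam, self.w_o, self.scale, valid_2)
        a2, mask2, o2 = cross_attend(q, k1, v1, self.lam, self.w_o, self.scale, valid_1)
        diagnostics = {
            "attention_1": a1.data, "mask_1": mask1,
            "attention_2": a2.data, "mask_2": mask2,
            "mask_density": _mask_density(mask1, valid_2, mask2, valid_1),
        }
        return o1, o2, diagnostics

    def parameters(self):
        return [self.patterns, self.w_q, self.w_k1, self.w_v1,
                self.w_k2, self.w_v2, self.w_o]


def _mask_density(mask1, valid2, mask2, valid1) -> float:
    total, kept = 0.0, 0.0
    for mask, valid in ((mask1, valid2), (mask2, valid1)):
        if valid is None:
            valid = np.ones_like(mask[..., :1, :])
        weight = np.broadcast_to(np.asarray(valid), mask.shape)
        total += weight.sum()
        kept += (mask * weight).sum()
    return float(kept / total) if total else 0.0
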