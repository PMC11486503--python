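"""Full dual-attention DDI model: GIN encoder, two attention branches, head.

The pair score is computed as

    H1 = GIN(G1), H2 = GIN(G2)                     (shared encoder)
    s  = flatten(cosine(SelfAttn(H1), SelfAttn(H2)))
    inter_k = standardize(avgpool(CrossAttn(H1, H2)_k)),  k = 1, 2
    logit = MLP(inter1 || inter2 || s)

Because the cross-attention slots give the two drugs distinct key/value
projections, the raw model is not symmetric in pair order; pairs are scored
in a single canonical order (lexicographic drug id, which the data layer
already enforces), with an option to average both orders instead.

Ablation flags drop a branch entirely and shrink the head input accordingly:
no similarity branch -> 2d, no cross-attention branch -> M^2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .chem import MolecularGraph
from .crossattn import CrossAttention
from .featurize import DEFAULT_SCHEME, get_scheme
from .gin import GINEncoder, dense_batch
from .head import PredictionHead, bce_loss, pool_and_standardize, sigmoid
from .selfattn import PatternSelfAttention, cosine_matrix, flatten_similarity

__all__ = ["ModelConfig", "DDIModel"]


@dataclass
class ModelConfig:
    d: int = 128                 # node/pattern embedding width
    n_patterns: int = 60         # M representative vectors
    n_gin_layers: int = 5
    lam: float = 0.75            # cross-attention threshold
    attn_scale: str = "sqrt_d"
    scheme: str = DEFAULT_SCHEME
    head_hidden: tuple[int, ...] = (512, 128)
    share_gin: bool = True       # one GIN feeding both attention branches
    share_patterns: bool = False  # separate pattern sets for the two branches
    use_gsat: bool = True        # similarity branch
    use_giat: bool = True        # cross-attention branch
    use_normalization: bool = True
    symmetric_scoring: bool = False  # average f(a,b) and f(b,a)

    def __post_init__(self):
        if not (self.use_gsat or self.use_giat):
            raise ValueError("at least one attention branch must be enabled")
        self.head_hidden = tuple(self.head_hidden)

    @property
    def head_input_width(self) -> int:
        width = 0
        if self.use_giat:
            width += 2 * self.d
        if self.use_gsat:
            width += self.n_patterns ** 2
        return width


class DDIModel:
    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d0 = get_scheme(config.scheme).n_features
        self.gin = GINEncoder(d0, config.d, config.n_gin_layers, rng)
        self.gin_cross = (
            self.gin if config.share_gin
            else GINEncoder(d0, config.d, config.n_gin_layers, rng)
        )
        self.self_attn = (
            PatternSelfAttention(config.d, config.n_patterns, rng, config.attn_scale)
            if config.use_gsat else None
        )
        self.cross_attn = (
            CrossAttention(config.d, config.n_patterns, config.lam, rng,
                           config.attn_scale)
            if config.use_giat else None
        )
        if config.use_gsat and config.use_giat and config.share_patterns:
            self.cross_attn.patterns = self.self_attn.patterns
        self.head = PredictionHead(config.head_input_width, config.head_hidden, rng)

    # -- forward -----------------------------------------------------------
    def forward_batch(
        self,
        graphs_a: list[MolecularGraph],
        graphs_b: list[MolecularGraph],
        collect_diagnostics: bool = False,
    ) -> tuple[Tensor, dict]:
        """Score a batch of pairs; returns (logits B x 1, diagnostics)."""
        if len(graphs_a) != len(graphs_b):
            raise ValueError("side A and side B batches differ in length")
        xa, adja, valida = dense_batch(graphs_a)
        xb, adjb, validb = dense_batch(graphs_b)
        ha = self.gin(Tensor(xa), Tensor(adja))
        hb = self.gin(Tensor(xb), Tensor(adjb))
        parts: list[Tensor] = []
        diagnostics: dict = {}
        if self.cross_attn is not None:
            if self.gin_cross is self.gin:
                hac, hbc = ha, hb
            else:
                hac = self.gin_cross(Tensor(xa), Tensor(adja))
                hbc = self.gin_cross(Tensor(xb), Tensor(adjb))
            o1, o2, cross_diag = self.cross_attn(hac, hbc, valida, validb)
            inter1 = pool_and_standardize(o1, self.config.use_normalization)
            inter2 = pool_and_standardize(o2, self.config.use_normalization)
            parts += [inter1, inter2]
            diagnostics["mask_density"] = cross_diag["mask_density"]
            if collect_diagnostics:
                diagnostics["cross"] = cross_diag
        if self.self_attn is not None:
            _, rep_a = self.self_attn(ha, valida)
            _, rep_b = self.self_attn(hb, validb)
            similarity = cosine_matrix(rep_a, rep_b)
            parts.append(flatten_similarity(similarity))
            if collect_diagnostics:
                diagnostics["similarity"] = similarity.data
        logits = self.head(parts)
        return logits, diagnostics

    def loss(self, graphs_a, graphs_b, labels) -> tuple[Tensor, dict]:
        logits, diagnostics = self.forward_batch(graphs_a, graphs_b)
        return bce_loss(logits, labels), diagnostics

    def predict_proba(
        self,
        graphs_a: list[MolecularGraph],
        graphs_b: list[MolecularGraph],
        batch_size: int = 256,
    ) -> np.ndarray:
        """Interaction probabilities for pairs of graphs (canonical order)."""
        probs = []
        for start in range(0, len(graphs_a), batch_size):
            ga = graphs_a[start:start + batch_size]
            gb = graphs_b[start:start + batch_size]
            logits, _ = self.forward_batch(ga, gb)
            p = sigmoid(logits.data.reshape(-1))
            if self.config.symmetric_scoring:
                logits_rev, _ = self.forward_batch(gb, ga)
                p = 0.5 * (p + sigmoid(logits_rev.data.reshape(-1)))
            probs.append(p)
        return np.concatenate(probs)

    # -- parameters / persistence ------------------------------------------
    def parameters(self):
        params = list(self.gin.parameters())
        if self.gin_cross is not self.gin:
            params += self.gin_cross.parameters()
        if self.self_attn is not None:
            params += self.self_attn.parameters()
        if self.cross_attn is not None:
            cross = self.cross_attn.parameters()
            if self.config.share_patterns and self.self_attn is not None:
                cross = [p for p in cross if p is not self.cross_attn.patterns]
            params += cross
        params += self.head.parameters()
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = a.copy()

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        cfg = asdict(self.config)
        cfg["head_hidden"] = list(cfg["head_hidden"])
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, path) -> "DDIModel":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        cfg["head_hidden"] = tuple(cfg["head_hidden"])
        model = cls(ModelConfig(**cfg))
        with np.load(path.with_suffix(".npz")) as data:
            arrays = [data[f"param_{i}"] for i in range(len(data.files))]
        model.load_state_arrays(arrays)
        return model
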