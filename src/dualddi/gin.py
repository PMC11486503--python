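"""Graph Isomorphism Network encoder.

Each layer updates node i as  h_i <- h_i + MLP(sum_{j in N(i)} h_j): sum
aggregation over neighbours followed by a two-layer perceptron, with the
previous state added back outside the MLP.  The first layer maps raw atom
features (width d0) to the embedding width d; because the residual term is
then shape-inconsistent, layer 1 projects the input through a learned linear
map before adding.  Only the final layer's node embeddings are exposed.

Batched graphs are held in dense padded form (features B x N_max x d0,
adjacency B x N_max x N_max); padded nodes have no edges, so they never
contribute to a real node's neighbour sum, and downstream attention masks
them out entirely.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .chem import MolecularGraph
from .nn import MLP, Linear

__all__ = ["GINLayer", "GINEncoder", "dense_batch"]


class GINLayer:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.d_in, self.d_out = d_in, d_out
        self.mlp = MLP([d_in, d_out, d_out], rng)
        self.residual = Linear(d_in, d_out, rng, bias=False) if d_in != d_out else None

    def __call__(self, h: Tensor, adjacency: Tensor) -> Tensor:
        if h.shape[-1] != self.d_in:
            raise ValueError(f"expected node width {self.d_in}, got {h.shape[-1]}")
        if adjacency.shape[-1] != h.shape[-2]:
            raise ValueError("adjacency does not match node count")
        neighbour_sum = adjacency @ h
        res = h if self.residual is None else self.residual(h)
        return res + self.mlp(neighbour_sum)

    def parameters(self):
        params = self.mlp.parameters()
        if self.residual is not None:
            params += self.residual.parameters()
        return params


class GINEncoder:
    """L stacked GIN layers; layer 1 maps d0 -> d, the rest d -> d."""

    def __init__(self, d0: int, d: int, n_layers: int, rng: np.random.Generator):
        if n_layers < 1:
            raise ValueError("need at least one GIN layer")
        self.d0, self.d = d0, d
        self.layers = [GINLayer(d0 if i == 0 else d, d, rng) for i in range(n_layers)]

    def __call__(self, x: Tensor, adjacency: Tensor) -> Tensor:
        if x.shape[-1] != self.d0:
            raise ValueError(
                f"graph featurized with width {x.shape[-1]} but encoder expects {self.d0}"
            )
        h = x
        for layer in self.layers:
            h = layer(h, adjacency)
        return h

    def encode(self, graph: MolecularGraph) -> Tensor:
        """Encode a single (unbatched) molecular graph to N x d node embeddings."""
        return self(Tensor(graph.node_features), Tensor(graph.adjacency))

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


def dense_batch(graphs: list[MolecularGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad graphs to a dense batch: features, adjacency, and a validity mask.

    Returns (X: B x N x d0, A: B x N x N, valid: B x 1 x N) with N the largest
    node count in the batch; the mask is 1 on real atoms, 0 on padding.
    """
    if not graphs:
        raise ValueError("empty batch")
    n_max = max(g.num_nodes for g in graphs)
    d0 = graphs[0].node_features.shape[1]
    x = np.zeros((len(graphs), n_max, d0))
    adj = np.zeros((len(graphs), n_max, n_max))
    valid = np.zeros((len(graphs), 1, n_max))
    for k, g in enumerate(graphs):
        n = g.num_nodes
        x[k, :n] = g.node_features
        adj[k, :n, :n] = g.adjacency
        valid[k, 0, :n] = 1.0
    return x, adj, valid
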