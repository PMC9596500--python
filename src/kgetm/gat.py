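"""Multi-head graph-attention refinement of code embeddings.

Each layer recomputes every node's vector as an attention-weighted sum of
linearly mapped vectors of the node itself and its graph neighbours; the
attention logit for the pair (c, j) is LeakyReLU(a^T [W h_c || W h_j]),
softmax-normalised over {c} union N(c).  The outputs of all layers are
max-pooled elementwise to form the final code embedding, from which the
vocabulary rows are extracted.

Head outputs are averaged by default, keeping the embedding dimension fixed
at L across layers; a concat-project rule is available behind the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, gather_rows, scatter_add_rows
from .graph import KnowledgeGraph

__all__ = ["GATConfig", "GATLayerParams", "GATNetwork", "CodeEmbedding",
           "attention_weights", "gat_layer_forward", "gat_forward"]


@dataclass
class GATConfig:
    num_layers: int = 3
    num_heads: int = 4
    leaky_slope: float = 0.2
    head_combine: str = "average"          # or "concat-project"
    pool_includes_input: bool = False

    def __post_init__(self):
        if self.num_layers < 1 or self.num_heads < 1:
            raise ValueError("num_layers and num_heads must be >= 1")
        if self.head_combine not in ("average", "concat-project"):
            raise ValueError(f"unknown head_combine {self.head_combine!r}")


@dataclass
class GATLayerParams:
    """Per-head linear maps W_i (L_out x L_in) and attention vectors a_i."""

    W: list[Tensor]        # H tensors, each (L_out, L_in)
    a: list[Tensor]        # H tensors, each (2 * L_out,)
    proj: Tensor | None = None   # (L_out, H*L_out) for concat-project

    @property
    def num_heads(self) -> int:
        return len(self.W)

    def parameters(self) -> list[Tensor]:
        out = [*self.W, *self.a]
        if self.proj is not None:
            out.append(self.proj)
        return out

    @classmethod
    def random(cls, dim: int, num_heads: int, rng: np.random.Generator,
               head_combine: str = "average") -> "GATLayerParams":
        scale = 1.0 / np.sqrt(dim)
        W = [Tensor(rng.standard_normal((dim, dim)) * scale, requires_grad=True)
             for _ in range(num_heads)]
        a = [Tensor(rng.standard_normal(2 * dim) * scale, requires_grad=True)
             for _ in range(num_heads)]
        proj = None
        if head_combine == "concat-project":
            proj = Tensor(rng.standard_normal((dim, num_heads * dim)) *
                          (1.0 / np.sqrt(num_heads * dim)), requires_grad=True)
        return cls(W=W, a=a, proj=proj)


@dataclass
class CodeEmbedding:
    """Final code embedding restricted to the corpus vocabulary.

    Stored row-major (one row per code); ``rho_icd`` / ``rho_atc`` are the
    (V_t, L) modality blocks in vocabulary order.
    """

    rho_icd: np.ndarray
    rho_atc: np.ndarray

    @property
    def dimension(self) -> int:
        return self.rho_icd.shape[1]


def _segment_softmax(logits: Tensor, tgt: np.ndarray, num_nodes: int) -> Tensor:
    """Softmax of edge logits grouped by target node (differentiable)."""
    # subtract per-group max for stability (constant shift, detached)
    shift = np.full(num_nodes, -np.inf)
    np.maximum.at(shift, tgt, logits.data)
    shifted = logits - Tensor(shift[tgt])
    e = shifted.exp()
    denom = scatter_add_rows(e.reshape(-1, 1), tgt, num_nodes).reshape(-1)
    return e / gather_rows(denom.reshape(-1, 1), tgt).reshape(-1)


def _layer_head_forward(W: Tensor, a: Tensor, h: Tensor,
                        tgt: np.ndarray, src: np.ndarray,
                        num_nodes: int, slope: float) -> Tensor:
    """One attention head: returns the (num_nodes, L_out) aggregation."""
    Wh = h @ W.T                                   # (N, L_out)
    L_out = W.shape[0]
    a_self = Wh @ a[:L_out].reshape(-1, 1)         # (N, 1) contribution of target
    a_nbr = Wh @ a[L_out:].reshape(-1, 1)          # (N, 1) contribution of source
    logits = (gather_rows(a_self, tgt) + gather_rows(a_nbr, src)).reshape(-1)
    logits = logits.leaky_relu(slope)
    w = _segment_softmax(logits, tgt, num_nodes)   # per-edge attention
    msgs = gather_rows(Wh, src) * w.reshape(-1, 1)
    return scatter_add_rows(msgs, tgt, num_nodes)


def gat_layer_forward(layer: GATLayerParams, h: Tensor,
                      tgt: np.ndarray, src: np.ndarray, num_nodes: int,
                      config: GATConfig) -> Tensor:
    """Forward one GAT layer over the whole graph."""
    if layer.W[0].shape[1] != h.shape[1]:
        raise ValueError(
            f"dimension mismatch: W expects {layer.W[0].shape[1]}, "
            f"input has {h.shape[1]}")
    heads = [_layer_head_forward(W, a, h, tgt, src, num_nodes,
                                 config.leaky_slope)
             for W, a in zip(layer.W, layer.a)]
    if config.head_combine == "average":
        out = heads[0]
        for extra in heads[1:]:
            out = out + extra
        return out * (1.0 / len(heads))
    from .autodiff import concat
    return concat(heads, axis=1) @ layer.proj.T


class GATNetwork:
    """A stack of GAT layers with elementwise max-pooling over layer outputs."""

    def __init__(self, dim: int, config: GATConfig | None = None,
                 seed: int = 0):
        self.config = config or GATConfig()
        rng = np.random.default_rng(seed)
        self.layers = [
            GATLayerParams.random(dim, self.config.num_heads, rng,
                                  self.config.head_combine)
            for _ in range(self.config.num_layers)
        ]

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, h0: Tensor, g: KnowledgeGraph) -> Tensor:
        tgt, src = g.edge_arrays()
        n = len(g)
        outputs = [h0] if self.config.pool_includes_input else []
        h = h0
        for layer in self.layers:
            h = gat_layer_forward(layer, h, tgt, src, n, self.config)
            outputs.append(h)
        pooled = outputs[0]
        for o in outputs[1:]:
            pooled = pooled.maximum(o)
        return pooled


def gat_forward(network: GATNetwork, init_matrix: np.ndarray,
                g: KnowledgeGraph, vocab_icd: list[str],
                vocab_atc: list[str]) -> CodeEmbedding:
    """Run the network and extract vocabulary rows (inference-only)."""
    for code in [*vocab_icd, *vocab_atc]:
        if code not in g.node_index:
            raise KeyError(f"vocabulary code {code!r} missing from graph")
    pooled = network.forward(Tensor(init_matrix), g).data
    icd_rows = pooled[[g.node_index[c] for c in vocab_icd]]
    atc_rows = pooled[[g.node_index[c] for c in vocab_atc]]
    return CodeEmbedding(rho_icd=icd_rows, rho_atc=atc_rows)


def attention_weights(layer: GATLayerParams, head: int, code: str,
                      embeddings: dict[str, np.ndarray],
                      adjacency: dict[str, list[str]],
                      leaky_slope: float = 0.2) -> dict[str, float]:
    """Attention weights of one node over itself and its neighbours.

    Reference (non-batched) evaluation of the attention rule; weights are a
    softmax over {code} union neighbours(code) and sum to 1.
    """
    if code not in adjacency:
        raise KeyError(f"node {code!r} absent from adjacency")
    W = layer.W[head].data
    a = layer.a[head].data
    L_out = W.shape[0]
    group = [code] + sorted(adjacency[code])
    hc = W @ np.asarray(embeddings[code])
    logits = []
    for j in group:
        hj = W @ np.asarray(embeddings[j])
        z = a[:L_out] @ hc + a[L_out:] @ hj
        logits.append(z if z > 0 else leaky_slope * z)
    logits = np.asarray(logits)
    e = np.exp(logits - logits.max())
    w = e / e.sum()
    return dict(zip(group, w))
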