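"""node2vec pre-training of the initial code embedding.

Second-order biased random walks over the merged knowledge graph followed by
skip-gram with negative sampling (SGNS).  The resulting matrix initialises
the graph-attention encoder; downstream it is refined end-to-end, so this
stage only needs to place taxonomy-adjacent codes near each other.

Defaults follow the original node2vec settings: 10 walks per node of length
80, window 5, 5 negatives, 5 epochs, return/in-out biases p = q = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import KnowledgeGraph

__all__ = ["WalkSet", "InitialEmbedding", "generate_walks", "train_skipgram",
           "write_embedding", "read_embedding", "node2vec_embedding"]

log = logging.getLogger(__name__)


@dataclass
class WalkSet:
    walks: list[list[str]]
    params: dict = field(default_factory=dict)


@dataclass
class InitialEmbedding:
    """Dense node embedding; one row per graph node, in graph node order."""

    matrix: np.ndarray  # (num_nodes, L)
    nodes: list[str]

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def rows(self, codes: list[str]) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.nodes)}
        return self.matrix[[index[c] for c in codes]]


def generate_walks(g: KnowledgeGraph, walks_per_node: int = 10,
                   walk_length: int = 80, p: float = 1.0, q: float = 1.0,
                   seed: int = 0) -> WalkSet:
    """Second-order biased random walks from every node.

    Transition weight from current node v (previous node t) to candidate x:
    1/p if x == t (return), 1 if x is adjacent to t, 1/q otherwise.
    """
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    if len(g) == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)
    neighbors = {c: sorted(g.graph.neighbors(c)) for c in g.nodes}
    neighbor_sets = {c: set(ns) for c, ns in neighbors.items()}
    walks: list[list[str]] = []
    for _ in range(walks_per_node):
        for start in g.nodes:
            walk = [start]
            while len(walk) < walk_length:
                cur = walk[-1]
                nbrs = neighbors[cur]
                if not nbrs:
                    break
                if len(walk) == 1:
                    nxt = nbrs[rng.integers(len(nbrs))]
                else:
                    prev = walk[-2]
                    prev_nbrs = neighbor_sets[prev]
                    w = np.array([
                        1.0 / p if x == prev else (1.0 if x in prev_nbrs else 1.0 / q)
                        for x in nbrs
                    ])
                    w /= w.sum()
                    nxt = nbrs[rng.choice(len(nbrs), p=w)]
                walk.append(nxt)
            walks.append(walk)
    return WalkSet(walks, params=dict(walks_per_node=walks_per_node,
                                      walk_length=walk_length, p=p, q=q,
                                      seed=seed))


def _walk_pairs(walks: list[list[int]], window: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for walk in walks:
        n = len(walk)
        for i, c in enumerate(walk):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(walk[j])
    return np.asarray(centers, dtype=np.intp), np.asarray(contexts, dtype=np.intp)


def train_skipgram(w: WalkSet, nodes: list[str], dim: int = 256,
                   window: int = 5, negatives: int = 5, epochs: int = 5,
                   lr: float = 0.0125, seed: int = 0,
                   batch_size: int = 1024) -> InitialEmbedding:
    """Skip-gram with negative sampling over the walk corpus.

    Minibatch SGD with a linearly decaying learning rate and per-batch
    update clipping (updates within a batch are accumulated per row, so on
    small vocabularies unclipped steps can diverge); negatives are drawn
    from the unigram distribution raised to 3/4.  Nodes never visited by a
    walk keep their random initialisation (logged).
    """
    if not w.walks:
        raise ValueError("empty walk set")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    index = {c: i for i, c in enumerate(nodes)}
    n = len(nodes)
    walks_idx = [[index[c] for c in walk] for walk in w.walks]
    centers, contexts = _walk_pairs(walks_idx, window, rng)
    if centers.size == 0:
        # all walks singleton: nothing to train on
        log.warning("no skip-gram pairs; returning random initialisation")
        return InitialEmbedding((rng.standard_normal((n, dim)) / dim), list(nodes))

    counts = np.bincount(np.concatenate([np.asarray(wk) for wk in walks_idx]),
                         minlength=n).astype(float)
    unseen = int((counts == 0).sum())
    if unseen:
        log.warning("%d nodes never visited by walks keep random vectors", unseen)
    noise = counts ** 0.75
    noise /= noise.sum()

    W_in = (rng.random((n, dim)) - 0.5) / dim
    W_out = np.zeros((n, dim))

    n_pairs = centers.size
    total_steps = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch_size):
            batch = order[s:s + batch_size]
            c_idx, o_idx = centers[batch], contexts[batch]
            neg_idx = rng.choice(n, size=(batch.size, negatives), p=noise)
            alpha = lr * max(1e-4, 1 - step / total_steps)
            _sgns_step(W_in, W_out, c_idx, o_idx, neg_idx, alpha)
            step += 1
    return InitialEmbedding(W_in, list(nodes))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35.0, 35.0)))


def _sgns_step(W_in, W_out, c_idx, o_idx, neg_idx, alpha):
    vc = W_in[c_idx]                       # (B, L)
    vo = W_out[o_idx]                      # (B, L)
    vn = W_out[neg_idx]                    # (B, neg, L)
    s_pos = _sigmoid((vc * vo).sum(axis=1))          # sigma(vc.vo)
    s_neg = _sigmoid(np.einsum("bl,bnl->bn", vc, vn))
    g_pos = (s_pos - 1.0)[:, None]         # d(-log sigma)/d(score)
    g_neg = s_neg[:, :, None]
    grad_c = g_pos * vo + np.einsum("bn,bnl->bl", s_neg, vn)
    clip = 1.0  # bound on any accumulated per-row update
    for rows, upd in (
        (o_idx, -alpha * g_pos * vc),
        (neg_idx.ravel(), (-alpha * g_neg * vc[:, None, :]).reshape(-1, vc.shape[1])),
    ):
        acc = np.zeros_like(W_out)
        np.add.at(acc, rows, upd)
        W_out += np.clip(acc, -clip, clip)
    acc = np.zeros_like(W_in)
    np.add.at(acc, c_idx, -alpha * grad_c)
    W_in += np.clip(acc, -clip, clip)


def sgns_objective(emb_in: np.ndarray, emb_out: np.ndarray,
                   centers: np.ndarray, contexts: np.ndarray,
                   noise: np.ndarray, negatives: int,
                   rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of the (negated) SGNS loss; higher is better."""
    vc, vo = emb_in[centers], emb_out[contexts]
    pos = np.log(_sigmoid((vc * vo).sum(axis=1)) + 1e-12)
    neg_idx = rng.choice(emb_in.shape[0], size=(centers.size, negatives), p=noise)
    s = np.einsum("bl,bnl->bn", vc, emb_out[neg_idx])
    neg = np.log(_sigmoid(-s) + 1e-12).sum(axis=1)
    return float((pos + neg).mean())


def node2vec_embedding(g: KnowledgeGraph, dim: int = 256,
                       walks_per_node: int = 10, walk_length: int = 80,
                       window: int = 5, negatives: int = 5, epochs: int = 5,
                       p: float = 1.0, q: float = 1.0,
                       seed: int = 0) -> InitialEmbedding:
    """Convenience wrapper: walks + skip-gram on a knowledge graph."""
    walks = generate_walks(g, walks_per_node=walks_per_node,
                           walk_length=walk_length, p=p, q=q, seed=seed)
    return train_skipgram(walks, g.nodes, dim=dim, window=window,
                          negatives=negatives, epochs=epochs, seed=seed)


def write_embedding(emb: InitialEmbedding, path) -> None:
    """word2vec-style text format: header 'N L', then 'code v1 ... vL'."""
    with open(path, "w") as fh:
        n, L = emb.matrix.shape
        fh.write(f"{n} {L}\n")
        for code, row in zip(emb.nodes, emb.matrix):
            fh.write(code + " " + " ".join(f"{x:.8g}" for x in row) + "\n")


def read_embedding(path) -> InitialEmbedding:
    with open(path) as fh:
        header = fh.readline().split()
        n, L = int(header[0]), int(header[1])
        nodes, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            nodes.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    matrix = np.asarray(rows)
    if matrix.shape != (n, L):
        raise ValueError(f"embedding file {path}: header {(n, L)} does not "
                         f"match body {matrix.shape}")
    return InitialEmbedding(matrix, nodes)
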