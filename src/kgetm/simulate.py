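"""Synthetic taxonomies, knowledge graphs, EHR corpora and phenotype labels.

Real administrative claims data cannot be redistributed, so every pipeline
stage is exercised on generated data that carries the statistical structure
the model assumes: two tree-structured code taxonomies bridged by
disease-drug links, logistic-normal patient topic mixtures, per-modality
categorical token draws, heavy-tailed (Zipf-like within topic) code
frequencies, and phenotype labels derived from the true mixtures.

Topics are aligned with taxonomy subtrees: each topic owns a disjoint block
of leaf codes under one chapter of each modality, and cross-modality links
join corresponding blocks.  This alignment is what makes the knowledge graph
informative for the model, enabling ablation comparisons.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .corpus import EHRCorpus
from .graph import (CrossLinkSet, KnowledgeGraph, TaxonomyHierarchy,
                    _build_hierarchy, augment_with_ancestors,
                    merge_knowledge_graph)

__all__ = ["GroundTruth", "generate_taxonomies", "generate_corpus",
           "generate_phenotype_labels", "SimulationConfig"]


@dataclass
class SimulationConfig:
    """Default desk-scale study conditions for the synthetic corpus."""

    n_topics: int = 5
    v_icd: int = 50
    v_atc: int = 50
    n_patients: int = 2000
    mean_tokens_icd: float = 30.0
    mean_tokens_atc: float = 30.0
    temperature: float = 0.15       # topic-block separation; smaller = harder
    zipf_exponent: float = 1.0      # within-block heavy tail
    cross_links_per_block: int = 3
    single_topic: bool = False      # one-hot mixtures instead of logistic-normal
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the generator knows that a fitted model must recover."""

    beta_icd: np.ndarray                 # (K, V_icd) simplex rows
    beta_atc: np.ndarray                 # (K, V_atc)
    theta: np.ndarray                    # (D, K) simplex rows
    topic_blocks_icd: list[list[int]]    # vocab indices owned by each topic
    topic_blocks_atc: list[list[int]]
    icd_hierarchy: TaxonomyHierarchy | None = None
    atc_hierarchy: TaxonomyHierarchy | None = None
    cross_links: CrossLinkSet | None = None
    seed: int = 0
    config: SimulationConfig | None = None

    def merged_graph(self, augment: bool = True) -> KnowledgeGraph:
        icd, atc = self.icd_hierarchy, self.atc_hierarchy
        if icd is None or atc is None:
            raise ValueError("ground truth carries no taxonomies")
        if augment:
            icd, atc = augment_with_ancestors(icd), augment_with_ancestors(atc)
        return merge_knowledge_graph(icd, atc, self.cross_links or CrossLinkSet())


# ------------------------------------------------------------- code naming
def _icd_leaf_names(n: int) -> list[str]:
    if n > 900:
        raise ValueError("at most 900 synthetic ICD leaves supported")
    return [f"{100 + i:03d}" for i in range(n)]


def _atc_leaf_names(n: int) -> list[str]:
    # letter + two digits, e.g. A01 ... Z99
    if n > 26 * 99:
        raise ValueError("too many synthetic ATC leaves")
    out = []
    for i in range(n):
        out.append(f"{string.ascii_uppercase[i // 99]}{i % 99 + 1:02d}")
    return out


def _block_taxonomy(leaves: list[str], blocks: list[list[int]], modality: str,
                    root: str, chapter_name) -> TaxonomyHierarchy:
    """Depth-2 taxonomy: root -> one chapter per topic block -> leaf codes."""
    parent_of: dict[str, str] = {}
    nodes = {root}
    for b, block in enumerate(blocks):
        chapter = chapter_name(b, block)
        parent_of[chapter] = root
        nodes.add(chapter)
        for v in block:
            parent_of[leaves[v]] = chapter
            nodes.add(leaves[v])
    return _build_hierarchy(nodes, parent_of, modality)


# ------------------------------------------------------------- taxonomies
def generate_taxonomies(branching: int, depth: int,
                        cross_links_per_leaf_group: int = 1,
                        seed: int = 0
                        ) -> tuple[TaxonomyHierarchy, TaxonomyHierarchy,
                                   CrossLinkSet]:
    """Two complete ``branching**depth``-leaf trees plus cross links.

    Synthetic codes follow the respective syntax (3-digit/decimal ICD-9-like,
    letter-prefixed ATC-like).  Cross links are drawn between corresponding
    leaf groups (leaves sharing a first-level chapter) of the two trees.
    """
    if branching < 2 or depth < 1:
        raise ValueError("branching must be >= 2 and depth >= 1")
    if depth > 4:
        raise ValueError("synthetic code syntax supports depth <= 4")
    rng = np.random.default_rng(seed)
    n_leaves = branching ** depth

    icd_nodes, icd_parent = _complete_tree_codes(
        branching, depth, modality="icd")
    atc_nodes, atc_parent = _complete_tree_codes(
        branching, depth, modality="atc")
    icd_h = _build_hierarchy(set(icd_nodes), icd_parent, "icd")
    atc_h = _build_hierarchy(set(atc_nodes), atc_parent, "atc")

    icd_leaves = sorted(set(icd_nodes) - set(icd_parent.values()))
    atc_leaves = sorted(set(atc_nodes) - set(atc_parent.values()))
    links = CrossLinkSet()
    group = max(1, n_leaves // branching)   # leaves per first-level chapter
    for g in range(branching if depth > 1 else 1):
        lo, hi = g * group, min((g + 1) * group, n_leaves)
        if lo >= hi:
            continue
        for _ in range(cross_links_per_leaf_group):
            links.add(icd_leaves[int(rng.integers(lo, hi))],
                      atc_leaves[int(rng.integers(lo, hi))])
    return icd_h, atc_h, links


def _complete_tree_codes(branching: int, depth: int, modality: str
                         ) -> tuple[list[str], dict[str, str]]:
    """Names and parent map of a complete tree with domain-plausible codes.

    Built top-down so every node's name is derived from its position:
    ICD-like trees use range chapters, 3-digit categories and decimal
    subdivisions; ATC-like trees extend a letter/digit prefix per level.
    """
    if modality == "icd" and depth > 2 and branching > 10:
        raise ValueError("decimal ICD levels support branching <= 10")
    if modality == "atc" and branching > 26:
        raise ValueError("letter ATC levels support branching <= 26")
    parent_of: dict[str, str] = {}
    nodes: list[str] = []
    root = "000-999" if modality == "icd" else "ATC"
    nodes.append(root)

    def icd_name(level: int, path: tuple[int, ...]) -> str:
        # 3-digit categories sit at level min(depth, 2); ranges above,
        # decimals below
        cat_level = min(depth, 2)
        if level < cat_level:
            # range over the 3-digit categories this chapter will contain
            width = branching ** (cat_level - level)
            flat = 0  # flat index of the first 3-digit category in this chapter
            for step in path:
                flat = flat * branching + step
            first = 100 + flat * width
            return f"{first:03d}-{first + width - 1:03d}"
        flat_cat = 0
        for step in path[:cat_level]:
            flat_cat = flat_cat * branching + step
        name = f"{100 + flat_cat:03d}"
        if level > cat_level:
            name += "." + "".join(str(s) for s in path[cat_level:])
        return name

    def atc_name(level: int, path: tuple[int, ...]) -> str:
        name = string.ascii_uppercase[path[0]]
        if level >= 2:
            name += f"{path[1] + 1:02d}"
        for step in path[2:]:
            name += string.ascii_uppercase[step]
        return name

    naming = icd_name if modality == "icd" else atc_name
    frontier: list[tuple[str, tuple[int, ...]]] = [(root, ())]
    for level in range(1, depth + 1):
        nxt = []
        for parent, path in frontier:
            for j in range(branching):
                child_path = path + (j,)
                name = naming(level, child_path)
                parent_of[name] = parent
                nodes.append(name)
                nxt.append((name, child_path))
        frontier = nxt
    return nodes, parent_of


# ------------------------------------------------------------------ corpus
def generate_corpus(config: SimulationConfig | None = None, **overrides
                    ) -> tuple[EHRCorpus, GroundTruth]:
    """Generate a corpus from the assumed generative process.

    Topic-over-code distributions are built by giving each topic a disjoint
    leaf block (one chapter per topic in a depth-2 taxonomy) with
    Zipf-decaying within-block mass; ``temperature`` controls how much mass
    leaks outside the block.  Mixtures are logistic-normal (or one-hot when
    ``single_topic``), token totals per modality are Poisson.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    K, D = config.n_topics, config.n_patients
    if K > config.v_icd or K > config.v_atc:
        raise ValueError("need at least one code per topic per modality")
    rng = np.random.default_rng(config.seed)

    vocab_icd = _icd_leaf_names(config.v_icd)
    vocab_atc = _atc_leaf_names(config.v_atc)
    blocks_icd = [list(chunk) for chunk in
                  np.array_split(np.arange(config.v_icd), K)]
    blocks_atc = [list(chunk) for chunk in
                  np.array_split(np.arange(config.v_atc), K)]

    beta_icd = _block_beta(config.v_icd, blocks_icd, config, rng)
    beta_atc = _block_beta(config.v_atc, blocks_atc, config, rng)

    if config.single_topic:
        assignment = rng.integers(K, size=D)
        theta = np.zeros((D, K))
        theta[np.arange(D), assignment] = 1.0
    else:
        delta = rng.standard_normal((D, K))
        e = np.exp(delta - delta.max(axis=1, keepdims=True))
        theta = e / e.sum(axis=1, keepdims=True)

    rows = []
    for p in range(D):
        mix_icd = theta[p] @ beta_icd
        mix_atc = theta[p] @ beta_atc
        n_icd = int(rng.poisson(config.mean_tokens_icd))
        n_atc = int(rng.poisson(config.mean_tokens_atc))
        if n_icd + n_atc == 0:
            n_icd = 1       # corpus forbids empty records
        row = np.concatenate([
            rng.multinomial(n_icd, mix_icd) if n_icd else np.zeros(config.v_icd),
            rng.multinomial(n_atc, mix_atc) if n_atc else np.zeros(config.v_atc),
        ])
        rows.append(row)
    counts = sp.csr_matrix(np.asarray(rows, dtype=np.int64))
    corpus = EHRCorpus(counts, vocab_icd, vocab_atc)

    # taxonomy: one chapter per topic block, plus cross links joining blocks
    icd_h = _block_taxonomy(
        vocab_icd, blocks_icd, "icd", root="000-999",
        chapter_name=lambda b, blk: f"{vocab_icd[blk[0]]}-{vocab_icd[blk[-1]]}")
    atc_h = _block_taxonomy(
        vocab_atc, blocks_atc, "atc", root="ATC",
        chapter_name=lambda b, blk: f"CH{b:02d}")
    links = CrossLinkSet()
    for b in range(K):
        icd_blk, atc_blk = blocks_icd[b], blocks_atc[b]
        for _ in range(config.cross_links_per_block):
            links.add(vocab_icd[icd_blk[int(rng.integers(len(icd_blk)))]],
                      vocab_atc[atc_blk[int(rng.integers(len(atc_blk)))]])

    truth = GroundTruth(
        beta_icd=beta_icd, beta_atc=beta_atc, theta=theta,
        topic_blocks_icd=blocks_icd, topic_blocks_atc=blocks_atc,
        icd_hierarchy=icd_h, atc_hierarchy=atc_h, cross_links=links,
        seed=config.seed, config=config,
    )
    return corpus, truth


def _block_beta(V: int, blocks: list[list[int]], config: SimulationConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Topic distributions with Zipf mass inside each topic's block and
    temperature-controlled leakage outside it."""
    K = len(blocks)
    beta = np.zeros((K, V))
    for k, block in enumerate(blocks):
        w = np.full(V, np.exp(0.0))
        in_block = np.zeros(V, dtype=bool)
        in_block[block] = True
        ranks = np.ones(V)
        ranks[block] = np.arange(1, len(block) + 1)
        zipf = 1.0 / ranks ** config.zipf_exponent
        w = zipf * np.exp(in_block.astype(float) / max(config.temperature, 1e-8))
        beta[k] = w / w.sum()
    return beta


# ------------------------------------------------------------------ labels
def generate_phenotype_labels(truth: GroundTruth, topic: int,
                              threshold: float | None = None
                              ) -> tuple[np.ndarray, float]:
    """Binary phenotype labels: 1 iff theta_pk exceeds the threshold.

    Defaults to the per-dataset median of theta_.k (prevalence ~ 0.5).
    Returns (labels, prevalence).
    """
    K = truth.theta.shape[1]
    if not 0 <= topic < K:
        raise ValueError(f"topic index {topic} out of range for K={K}")
    col = truth.theta[:, topic]
    if threshold is None:
        threshold = float(np.median(col))
    labels = (col > threshold).astype(int)
    return labels, float(labels.mean())
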