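"""Medical-code knowledge graph construction.

Builds an undirected graph over ICD-9-like diagnosis codes and ATC-like drug
codes from two taxonomy hierarchies (parent-child edge lists) plus a set of
cross-modality disease-drug links.  Each taxonomy can be *augmented* by
connecting every code to all of its ancestors, which shortens information
paths through the otherwise sparsely connected trees.  The merged graph
defines a fixed node ordering (all ICD codes sorted, then all ATC codes
sorted) that downstream embeddings index into.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "TaxonomyHierarchy",
    "CrossLinkSet",
    "KnowledgeGraph",
    "load_hierarchy",
    "augment_with_ancestors",
    "merge_knowledge_graph",
    "shortest_distance",
    "collapse_last_level",
    "UNREACHABLE",
]

#: Sentinel returned by :func:`shortest_distance` for disconnected code pairs.
UNREACHABLE = math.inf


@dataclass
class TaxonomyHierarchy:
    """A rooted code taxonomy: a forest of parent-child relations.

    ``edges`` holds the undirected relation set actually contributed to the
    knowledge graph; after :func:`augment_with_ancestors` it also contains
    code-to-ancestor shortcuts.
    """

    modality: str
    nodes: tuple[str, ...]
    parent_of: dict[str, str]
    depth: dict[str, int]
    edges: set[frozenset] = field(default_factory=set)
    augmented: bool = False

    def __post_init__(self):
        if not self.edges:
            self.edges = {frozenset((c, p)) for c, p in self.parent_of.items()}

    @property
    def roots(self) -> list[str]:
        return sorted(n for n in self.nodes if n not in self.parent_of)

    def ancestors(self, code: str) -> list[str]:
        """All strict ancestors of ``code``, nearest first."""
        out = []
        while code in self.parent_of:
            code = self.parent_of[code]
            out.append(code)
        return out


@dataclass
class CrossLinkSet:
    """Unordered disease-drug link pairs bridging the two taxonomies."""

    links: set[tuple[str, str]] = field(default_factory=set)

    def add(self, icd_code: str, atc_code: str) -> None:
        self.links.add((icd_code, atc_code))

    def __len__(self) -> int:
        return len(self.links)


class KnowledgeGraph:
    """Undirected code graph with typed edges and a reproducible node order.

    Node order is all ICD codes (lexicographic) followed by all ATC codes
    (lexicographic); it defines the row indices of any embedding matrix
    trained on this graph.
    """

    def __init__(self, graph: nx.Graph, node_order: list[str],
                 modality: dict[str, str]):
        self.graph = graph
        self.nodes = list(node_order)
        self.modality = modality
        self.node_index = {c: i for i, c in enumerate(self.nodes)}

    def __len__(self) -> int:
        return len(self.nodes)

    def neighbors(self, code: str) -> list[str]:
        return list(self.graph.neighbors(code))

    def edge_arrays(self):
        """(targets, sources) index arrays for every directed edge including
        self-loops, grouped so that all contributions to a node are contiguous.

        Neighbour lists are sorted by node index, so the arrays (and any
        aggregation over them) do not depend on input enumeration order.
        """
        import numpy as np

        tgt, src = [], []
        for c in self.nodes:
            ci = self.node_index[c]
            group = sorted([self.node_index[n] for n in self.graph.neighbors(c)])
            tgt.extend([ci] * (len(group) + 1))
            src.append(ci)  # self-loop
            src.extend(group)
        return np.asarray(tgt, dtype=np.intp), np.asarray(src, dtype=np.intp)

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# source\ttarget\tedge_type\n")
            for a, b, data in self.graph.edges(data=True):
                fh.write(f"{a}\t{b}\t{data.get('edge_type', 'unknown')}\n")


def load_hierarchy(path, modality: str) -> TaxonomyHierarchy:
    """Read a child<TAB>parent edge-list TSV into a validated taxonomy.

    Rejects empty files, children with two parents, and cycles.  Lines
    starting with '#' are comments.
    """
    parent_of: dict[str, str] = {}
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'child<TAB>parent', got {line!r}")
            child, parent = parts[0].strip(), parts[1].strip()
            if child == parent:
                raise ValueError(f"{path}:{lineno}: self-parent {child!r}")
            if child in parent_of and parent_of[child] != parent:
                raise ValueError(
                    f"{path}:{lineno}: code {child!r} has two parents "
                    f"({parent_of[child]!r}, {parent!r})")
            parent_of[child] = parent
            nodes.update((child, parent))
    if not parent_of:
        raise ValueError(f"{path}: empty hierarchy file")
    return _build_hierarchy(nodes, parent_of, modality)


def _build_hierarchy(nodes: set[str], parent_of: dict[str, str],
                     modality: str) -> TaxonomyHierarchy:
    # cycle check + depth computation by walking to a root
    depth: dict[str, int] = {}

    def resolve(code: str) -> int:
        seen_local = []
        c = code
        while c not in depth:
            if c in seen_local:
                raise ValueError(f"cycle detected in hierarchy at code {c!r}")
            seen_local.append(c)
            if c not in parent_of:  # root
                depth[c] = 0
                break
            c = parent_of[c]
        for s in reversed(seen_local):  # topmost unresolved node first
            if s in parent_of:
                depth[s] = depth[parent_of[s]] + 1
            else:
                depth[s] = 0
        return depth[code]

    for n in nodes:
        resolve(n)
    return TaxonomyHierarchy(
        modality=modality,
        nodes=tuple(sorted(nodes)),
        parent_of=dict(parent_of),
        depth=depth,
    )


def augment_with_ancestors(h: TaxonomyHierarchy) -> TaxonomyHierarchy:
    """Connect every code to all of its strict ancestors.

    The returned taxonomy's edge set is the original parent-child edges plus
    one shortcut per (code, non-parent ancestor) pair.  Idempotent.
    """
    edges = {frozenset((c, p)) for c, p in h.parent_of.items()}
    for code in h.nodes:
        for anc in h.ancestors(code):
            edges.add(frozenset((code, anc)))
    return TaxonomyHierarchy(
        modality=h.modality,
        nodes=h.nodes,
        parent_of=dict(h.parent_of),
        depth=dict(h.depth),
        edges=edges,
        augmented=True,
    )


def merge_knowledge_graph(icd: TaxonomyHierarchy, atc: TaxonomyHierarchy,
                          links: CrossLinkSet) -> KnowledgeGraph:
    """Union the two taxonomies and bridge them with disease-drug links."""
    g = nx.Graph()
    modality = {}
    for h, tag in ((icd, "icd"), (atc, "atc")):
        for n in h.nodes:
            g.add_node(n)
            modality[n] = tag
        for e in h.edges:
            a, b = sorted(e)
            g.add_edge(a, b, edge_type=f"{tag}-{tag}")
    for icd_code, atc_code in sorted(links.links):
        if icd_code not in icd.nodes:
            raise KeyError(f"cross-link references unknown ICD code {icd_code!r}")
        if atc_code not in atc.nodes:
            raise KeyError(f"cross-link references unknown ATC code {atc_code!r}")
        g.add_edge(icd_code, atc_code, edge_type="icd-atc")
    node_order = sorted(icd.nodes) + sorted(atc.nodes)
    return KnowledgeGraph(g, node_order, modality)


def shortest_distance(g: KnowledgeGraph, src: str, dst: str) -> float:
    """Breadth-first shortest hop count; ``UNREACHABLE`` if disconnected."""
    for c in (src, dst):
        if c not in g.node_index:
            raise KeyError(f"unknown code {c!r}")
    try:
        return float(nx.shortest_path_length(g.graph, src, dst))
    except nx.NetworkXNoPath:
        return UNREACHABLE


_ICD_RE = re.compile(r"^[VE]?\d{1,3}(-[VE]?\d{1,3})?(\.\d{1,2})?$")
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


def collapse_last_level(code: str, modality: str) -> str:
    """Drop the finest classification level of a code.

    ICD-9: strip the decimal subdivision ('297.0' -> '297').  ATC: truncate a
    7-character ingredient code to its 5-character chemical subgroup
    ('N05AX08' -> 'N05AX').  Codes already at or above that level are
    returned unchanged.
    """
    modality = modality.lower()
    if modality == "icd":
        if not _ICD_RE.match(code):
            raise ValueError(f"malformed ICD code {code!r}")
        return code.split(".")[0]
    if modality == "atc":
        if not _ATC_RE.match(code):
            raise ValueError(f"malformed ATC code {code!r}")
        return code[:5] if len(code) == 7 else code
    raise ValueError(f"unknown modality {modality!r}")
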