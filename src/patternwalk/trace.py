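"""Walk-based interpretation of predictions.

A predicted protein-pathway link is explained by the sampled walks that
contain both endpoints: nodes shared by several supporting walks are
the intermediates that carried the signal.  The induced subgraph over
those common nodes is exported as Cytoscape-compatible node/edge
tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kg import KnowledgeGraph, UnknownNodeError
from .walker import Walk, WalkCorpus


@dataclass(frozen=True)
class TraceQuery:
    protein: str
    pathway: str
    min_support: int = 5
    max_walks: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.max_walks < self.min_support:
            raise ValueError("max_walks must be >= min_support")


def supporting_walks(corpus: WalkCorpus, query: TraceQuery) -> list[Walk]:
    """All walks containing both endpoints; a seeded subsample when more
    than ``max_walks`` exist."""
    hits = [w for w in corpus.walks if query.protein in w.nodes and query.pathway in w.nodes]
    if len(hits) > query.max_walks:
        rng = np.random.default_rng(query.seed)
        idx = rng.choice(len(hits), size=query.max_walks, replace=False)
        hits = [hits[i] for i in sorted(idx)]
    return hits


def common_nodes(
    walks: Sequence[Walk], min_support: int, endpoints: Sequence[str] = ()
) -> dict[str, int]:
    """Nodes appearing in >= min_support distinct walks, with support counts.

    A node occurring twice inside one walk counts once.  Query endpoints
    are always included.
    """
    support: dict[str, int] = {}
    for walk in walks:
        for node in set(walk.nodes):
            support[node] = support.get(node, 0) + 1
    out = {n: c for n, c in support.items() if c >= min_support}
    for ep in endpoints:
        out.setdefault(ep, support.get(ep, 0))
    return dict(sorted(out.items()))


def export_subgraph(
    graph: KnowledgeGraph,
    nodes,
    out_dir,
    support: dict | None = None,
) -> tuple[str, str]:
    """Write induced-subgraph edge and node attribute tables (TSV).

    ``edges.tsv``: source, target, relation; ``nodes.tsv``: node, type,
    support count.  Both load directly as Cytoscape tables.
    """
    node_set = set(nodes)
    for n in node_set:
        if n not in graph:
            raise UnknownNodeError(f"unknown node {n!r}")
    os.makedirs(out_dir, exist_ok=True)
    edges_path = os.path.join(out_dir, "edges.tsv")
    nodes_path = os.path.join(out_dir, "nodes.tsv")
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\trelation\n")
        for h, r, t in sorted(graph.triples):
            if h in node_set and t in node_set:
                fh.write(f"{h}\t{t}\t{r}\n")
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("node\ttype\tsupport\n")
        for n in sorted(node_set):
            fh.write(f"{n}\t{graph.node_type(n)}\t{(support or {}).get(n, '')}\n")
    return edges_path, nodes_path


def trace_prediction(
    graph: KnowledgeGraph, corpus: WalkCorpus, query: TraceQuery, out_dir
) -> dict:
    """Full interpretation pass: supporting walks -> common nodes -> subgraph export."""
    walks = supporting_walks(corpus, query)
    commons = common_nodes(walks, query.min_support, endpoints=(query.protein, query.pathway))
    present = {n: c for n, c in commons.items() if n in graph}
    edges_path, nodes_path = export_subgraph(graph, present, out_dir, support=commons)
    return {
        "n_supporting_walks": len(walks),
        "common_nodes": commons,
        "edges_path": edges_path,
        "nodes_path": nodes_path,
    }
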