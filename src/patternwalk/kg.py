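"""Heterogeneous knowledge-graph data model.

A knowledge graph is stored as typed nodes plus a multiset of
(head, relation, tail) triples.  Triples are kept directed for
serialization and schema reporting, but all traversal operations
(neighbors, degree, walks) treat edges as undirected: the head is a
neighbor of the tail and vice versa.

Node types form a forest: a ``DarkKinase`` may declare ``Protein`` as its
parent, and pattern matching resolves labels through the hierarchy so
that a DarkKinase node satisfies a Protein constraint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional


class GraphError(Exception):
    """Base class for knowledge-graph errors."""


class GraphParseError(GraphError):
    """A malformed row in a triples or node-type file."""


class ReferentialIntegrityError(GraphError):
    """A triple references a node that was never declared."""


class ValidationError(GraphError):
    """A structurally invalid graph element (e.g. an instance self-loop)."""


class UnknownNodeError(GraphError, KeyError):
    """A lookup on a node id that is not in the graph."""


class UndefinedProfileError(GraphError):
    """Relation profile requested for a degree-zero node."""


class TypeHierarchy:
    """Forest of node-type labels (child -> parent).

    ``ancestors(label)`` yields the label itself followed by each parent up
    to the root, so membership tests like "is this node a Protein?" are
    ``'Protein' in hierarchy.ancestors(node_label)``.
    """

    def __init__(self, parent_of: Optional[Mapping[str, str]] = None):
        self._parent = dict(parent_of or {})
        # reject cycles up front
        for label in self._parent:
            seen = {label}
            cur = self._parent.get(label)
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"type hierarchy contains a cycle through {label!r}")
                seen.add(cur)
                cur = self._parent.get(cur)

    def parent(self, label: str) -> Optional[str]:
        return self._parent.get(label)

    def ancestors(self, label: str) -> tuple[str, ...]:
        """The label itself plus every ancestor, nearest first."""
        out = [label]
        cur = self._parent.get(label)
        while cur is not None:
            out.append(cur)
            cur = self._parent.get(cur)
        return tuple(out)

    def is_a(self, label: str, ancestor: str) -> bool:
        return ancestor in self.ancestors(label)

    def items(self):
        return self._parent.items()

    def __eq__(self, other):
        return isinstance(other, TypeHierarchy) and self._parent == other._parent

    @classmethod
    def load(cls, path) -> "TypeHierarchy":
        parent_of = {}
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise GraphParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
                parent_of[parts[0]] = parts[1]
        return cls(parent_of)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for child, parent in sorted(self._parent.items()):
                fh.write(f"{child}\t{parent}\n")


@dataclass(frozen=True)
class SchemaGraph:
    """Type-level projection of an instance graph: (source type, relation, target type)."""

    node_types: frozenset[str]
    edges: frozenset[tuple[str, str, str]]

    def has_loop(self, type_label: str) -> bool:
        return any(s == t == type_label for s, _, t in self.edges)


class KnowledgeGraph:
    """Typed nodes + directed triples with undirected traversal indices."""

    def __init__(
        self,
        node_types: Mapping[str, str],
        triples: Iterable[tuple[str, str, str]] = (),
        hierarchy: Optional[TypeHierarchy] = None,
    ):
        self._node_types: dict[str, str] = dict(node_types)
        self.hierarchy = hierarchy or TypeHierarchy()
        self._triples: list[tuple[str, str, str]] = []
        self._adj: dict[str, list[tuple[str, str]]] = {n: [] for n in self._node_types}
        for h, r, t in triples:
            self.add_edge(h, r, t)

    # -- construction -------------------------------------------------

    def add_edge(self, head: str, relation: str, tail: str) -> None:
        for endpoint in (head, tail):
            if endpoint not in self._node_types:
                raise ReferentialIntegrityError(
                    f"triple ({head!r}, {relation!r}, {tail!r}) references undeclared node {endpoint!r}"
                )
        if head == tail:
            raise ValidationError(f"self-loop triple on node {head!r} rejected")
        self._triples.append((head, relation, tail))
        self._adj[head].append((relation, tail))
        self._adj[tail].append((relation, head))
        self._sorted = False

    def _ensure_sorted(self) -> None:
        if not getattr(self, "_sorted", False):
            for lst in self._adj.values():
                lst.sort()
            self._sorted = True

    # -- basic accessors ----------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._node_types))

    @property
    def triples(self) -> tuple[tuple[str, str, str], ...]:
        return tuple(self._triples)

    def __contains__(self, node: str) -> bool:
        return node in self._node_types

    def __len__(self) -> int:
        return len(self._node_types)

    @property
    def n_edges(self) -> int:
        return len(self._triples)

    def node_type(self, node: str) -> str:
        try:
            return self._node_types[node]
        except KeyError:
            raise UnknownNodeError(f"unknown node {node!r}") from None

    def nodes_of_type(self, type_label: str, resolve: bool = True) -> tuple[str, ...]:
        """Nodes whose label equals ``type_label`` (or a descendant of it if ``resolve``)."""
        if resolve:
            return tuple(
                n for n in self.nodes if self.hierarchy.is_a(self._node_types[n], type_label)
            )
        return tuple(n for n in self.nodes if self._node_types[n] == type_label)

    # -- traversal indices --------------------------------------------

    def neighbors(
        self, node: str, relation: Optional[str] = None
    ) -> tuple[tuple[str, str], ...]:
        """Incident (relation, neighbor) pairs, sorted; parallel edges reported separately."""
        if node not in self._node_types:
            raise UnknownNodeError(f"unknown node {node!r}")
        self._ensure_sorted()
        pairs = self._adj[node]
        if relation is not None:
            pairs = [p for p in pairs if p[0] == relation]
        return tuple(pairs)

    def degree(self, node: str) -> int:
        """Count of incident edges (parallel edges counted individually)."""
        if node not in self._node_types:
            raise UnknownNodeError(f"unknown node {node!r}")
        return len(self._adj[node])

    def relation_profile(self, node: str) -> dict[str, float]:
        """g(r): proportion of the node's incident edges carrying each relation."""
        deg = self.degree(node)
        if deg == 0:
            raise UndefinedProfileError(f"relation profile undefined for degree-0 node {node!r}")
        counts = Counter(r for r, _ in self._adj[node])
        return {r: c / deg for r, c in sorted(counts.items())}

    def relation_counts(self, node: str) -> dict[str, int]:
        if node not in self._node_types:
            raise UnknownNodeError(f"unknown node {node!r}")
        return dict(Counter(r for r, _ in self._adj[node]))

    # -- schema --------------------------------------------------------

    def schema_view(self) -> SchemaGraph:
        edges = frozenset(
            (self._node_types[h], r, self._node_types[t]) for h, r, t in self._triples
        )
        return SchemaGraph(frozenset(self._node_types.values()), edges)

    # -- editing -------------------------------------------------------

    def without_edges(self, removed: Iterable[tuple[str, str, str]]) -> "KnowledgeGraph":
        """A copy with the given triples removed (multiset semantics)."""
        to_remove = Counter(removed)
        kept = []
        for triple in self._triples:
            if to_remove.get(triple, 0) > 0:
                to_remove[triple] -= 1
            else:
                kept.append(triple)
        leftovers = [t for t, c in to_remove.items() if c > 0]
        if leftovers:
            raise ValidationError(f"cannot remove absent triples: {leftovers[:3]}")
        return KnowledgeGraph(self._node_types, kept, self.hierarchy)

    # -- I/O -----------------------------------------------------------

    @classmethod
    def load(
        cls,
        triples_path,
        node_types_path,
        hierarchy_path=None,
    ) -> "KnowledgeGraph":
        """Load from tab-separated triples + node-type files (``#`` comments allowed)."""
        node_types: dict[str, str] = {}
        with open(node_types_path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise GraphParseError(
                        f"{node_types_path}:{lineno}: expected 2 columns, got {len(parts)}"
                    )
                node_types[parts[0]] = parts[1]
        hierarchy = TypeHierarchy.load(hierarchy_path) if hierarchy_path else None
        graph = cls(node_types, hierarchy=hierarchy)
        with open(triples_path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise GraphParseError(
                        f"{triples_path}:{lineno}: expected 3 columns, got {len(parts)}"
                    )
                graph.add_edge(*parts)
        return graph

    def save(self, triples_path, node_types_path) -> None:
        with open(node_types_path, "w", encoding="utf-8") as fh:
            for node in self.nodes:
                fh.write(f"{node}\t{self._node_types[node]}\n")
        with open(triples_path, "w", encoding="utf-8") as fh:
            for h, r, t in sorted(self._triples):
                fh.write(f"{h}\t{r}\t{t}\n")

    # -- reporting -----------------------------------------------------

    def stats(self) -> dict:
        """Per-type node counts, per-relation edge counts, mean degree per type."""
        type_counts = Counter(self._node_types.values())
        rel_counts = Counter(r for _, r, _ in self._triples)
        mean_degree = {}
        for type_label in sorted(type_counts):
            members = [n for n, t in self._node_types.items() if t == type_label]
            mean_degree[type_label] = (
                sum(self.degree(n) for n in members) / len(members) if members else 0.0
            )
        return {
            "n_nodes": len(self._node_types),
            "n_edges": len(self._triples),
            "nodes_per_type": dict(sorted(type_counts.items())),
            "edges_per_relation": dict(sorted(rel_counts.items())),
            "mean_degree_per_type": mean_degree,
        }

    def fingerprint(self) -> str:
        """Stable digest of the node set and edge multiset."""
        import hashlib

        h = hashlib.sha256()
        for node in self.nodes:
            h.update(f"N\t{node}\t{self._node_types[node]}\n".encode())
        for triple in sorted(self._triples):
            h.update(("E\t" + "\t".join(triple) + "\n").encode())
        return h.hexdigest()
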