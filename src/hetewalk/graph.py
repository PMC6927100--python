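"""Typed, weighted heterogeneous graph: schema, data model and edge-list I/O.

A heterogeneous biological network mixes node types (gene, disease, miRNA)
and relation types (similarity, association, interaction), each edge carrying
a confidence/similarity weight in (0, 1].  The graph is undirected: every
relation in the source networks is a symmetric similarity or association.

The central structure is a type-partitioned adjacency index
``(node, neighbor_type) -> [(neighbor, weight, relation)]`` — the quantity a
meta-path-controlled walker needs at every step, since a step restricted to
type t normalises edge weights over exactly that slice of the neighborhood.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "GraphError",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "Schema",
    "HeteroGraph",
    "load_graph",
    "write_graph",
    "induced_subgraph",
]


class GraphError(Exception):
    """Base class for all graph-layer errors."""


class SchemaError(GraphError):
    """A node type or relation not declared in the schema."""


class ValidationError(GraphError):
    """An edge list violating the graph invariants (weights, duplicates...)."""


class ParseError(GraphError):
    """A malformed edge-list line; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Schema:
    """Allowed node types and typed relations of a heterogeneous network.

    Relations are unordered in their endpoint types; several relation labels
    may connect the same type pair (e.g. both a similarity and an association
    between genes), but each (type_a, type_b, label) triple is unique.
    """

    node_types: frozenset[str]
    relations: frozenset[tuple[str, str, str]]  # canonicalised (type_a<=type_b, label)

    def __init__(self, node_types, relations):
        nts = frozenset(node_types)
        if not nts or any(not t for t in nts):
            raise SchemaError("node types must be non-empty strings")
        rels = frozenset(_canon_pair(a, b) + (label,) for a, b, label in relations)
        for a, b, label in rels:
            if a not in nts or b not in nts:
                raise SchemaError(f"relation ({a}, {b}, {label}) uses undeclared node type")
        object.__setattr__(self, "node_types", nts)
        object.__setattr__(self, "relations", rels)

    def has_relation(self, type_a: str, type_b: str, label: str) -> bool:
        a, b = _canon_pair(type_a, type_b)
        return (a, b, label) in self.relations

    def labels_between(self, type_a: str, type_b: str) -> list[str]:
        a, b = _canon_pair(type_a, type_b)
        return sorted(lab for (x, y, lab) in self.relations if (x, y) == (a, b))

    def neighbor_types(self, t: str) -> list[str]:
        out = set()
        for a, b, _ in self.relations:
            if a == t:
                out.add(b)
            if b == t:
                out.add(a)
        return sorted(out)

    @classmethod
    def from_yaml(cls, path) -> "Schema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "node_types" not in doc or "relations" not in doc:
            raise SchemaError(f"{path}: schema file must define node_types and relations")
        return cls(doc["node_types"], [tuple(r) for r in doc["relations"]])

    def to_yaml(self, path) -> None:
        doc = {
            "node_types": sorted(self.node_types),
            "relations": [list(r) for r in sorted(self.relations)],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, default_flow_style=None)


@dataclass
class _Edge:
    u: str
    v: str
    label: str
    weight: float


class HeteroGraph:
    """Undirected, typed, weighted multigraph.

    Each edge is stored once under the canonical (min(u,v), max(u,v), label)
    key and indexed from both endpoints.  Weights lie in (0, 1]; zero-weight
    edges are rejected outright since they are unreachable under
    weight-proportional sampling and would only poison denominators.
    """

    def __init__(self, schema: Schema):
        self.schema = schema
        self._types: dict[str, str] = {}
        self._edges: dict[tuple[str, str, str], float] = {}
        # node -> neighbor type -> list of (neighbor, weight, label)
        self._adj: dict[str, dict[str, list[tuple[str, float, str]]]] = {}
        self._version = 0
        self._cum_cache: dict = {}

    # -- construction -------------------------------------------------

    def add_node(self, node: str, ntype: str) -> None:
        if ntype not in self.schema.node_types:
            raise SchemaError(f"node type {ntype!r} not in schema")
        prev = self._types.get(node)
        if prev is not None:
            if prev != ntype:
                raise ValidationError(
                    f"conflicting type declarations for node {node!r}: {prev!r} vs {ntype!r}"
                )
            return
        self._types[node] = ntype
        self._adj[node] = {}
        self._version += 1

    def add_edge(self, u: str, v: str, label: str, weight: float) -> None:
        if u == v:
            raise ValidationError(f"self-loop on node {u!r} rejected")
        for n in (u, v):
            if n not in self._types:
                raise KeyError(f"unknown node {n!r}; declare nodes before edges")
        tu, tv = self._types[u], self._types[v]
        if not self.schema.has_relation(tu, tv, label):
            raise SchemaError(f"relation ({tu}, {tv}, {label}) not declared in schema")
        if not (0.0 < weight <= 1.0):
            raise ValidationError(f"edge weight {weight} outside (0, 1]")
        key = _canon_pair(u, v) + (label,)
        if key in self._edges:
            raise ValidationError(f"duplicate edge ({u}, {v}, {label})")
        self._edges[key] = float(weight)
        self._adj[u].setdefault(tv, []).append((v, float(weight), label))
        self._adj[v].setdefault(tu, []).append((u, float(weight), label))
        self._version += 1

    def remove_edge(self, u: str, v: str, label: str) -> None:
        key = _canon_pair(u, v) + (label,)
        if key not in self._edges:
            raise KeyError(f"no edge ({u}, {v}, {label})")
        del self._edges[key]
        tu, tv = self._types[u], self._types[v]
        self._adj[u][tv] = [e for e in self._adj[u][tv] if not (e[0] == v and e[2] == label)]
        self._adj[v][tu] = [e for e in self._adj[v][tu] if not (e[0] == u and e[2] == label)]
        self._version += 1

    def copy(self) -> "HeteroGraph":
        g = HeteroGraph(self.schema)
        g._types = dict(self._types)
        g._edges = dict(self._edges)
        g._adj = {n: {t: list(lst) for t, lst in d.items()} for n, d in self._adj.items()}
        return g

    # -- queries ------------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self._types

    def __len__(self) -> int:
        return len(self._types)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node_type(self, node: str) -> str:
        try:
            return self._types[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def nodes(self) -> list[str]:
        return sorted(self._types)

    def nodes_of_type(self, t: str) -> list[str]:
        return sorted(n for n, nt in self._types.items() if nt == t)

    def edges(self) -> Iterator[_Edge]:
        for (u, v, label), w in sorted(self._edges.items()):
            yield _Edge(u, v, label, w)

    def has_edge(self, u: str, v: str, label: str | None = None) -> bool:
        if label is not None:
            return _canon_pair(u, v) + (label,) in self._edges
        a, b = _canon_pair(u, v)
        return any((x, y) == (a, b) for (x, y, _) in self._edges)

    def degree(self, node: str) -> int:
        self.node_type(node)
        return sum(len(lst) for lst in self._adj[node].values())

    def neighbors_of_type(
        self, node: str, t: str, label: str | None = None
    ) -> list[tuple[str, float]]:
        """Neighbors of ``node`` with type ``t`` as (id, weight), sorted by id.

        With ``label`` given, only edges carrying that relation label count.
        A neighbor connected through several relation labels appears once per
        qualifying edge.
        """
        self.node_type(node)
        entries = self._adj[node].get(t, [])
        if label is not None:
            entries = [e for e in entries if e[2] == label]
        return sorted((nid, w) for nid, w, _ in entries)

    def transition_arrays(
        self, node: str, t: str, label: str | None = None
    ) -> tuple[list[str], np.ndarray]:
        """Eligible next nodes and cumulative weights for sampling; cached."""
        key = (node, t, label, self._version)
        hit = self._cum_cache.get(key)
        if hit is not None:
            return hit
        if len(self._cum_cache) > 1_000_000:  # stale-version entries
            self._cum_cache.clear()
        nbrs = self.neighbors_of_type(node, t, label)
        ids = [n for n, _ in nbrs]
        cum = np.cumsum([w for _, w in nbrs])
        self._cum_cache[key] = (ids, cum)
        return ids, cum

    def edge_list(self) -> list[tuple[str, str, str, float]]:
        """Canonical sorted edge list (u <= v), the round-trip representation."""
        return [(u, v, lab, w) for (u, v, lab), w in sorted(self._edges.items())]


def node_stream_key(node: str) -> int:
    """Stable 32-bit key for deriving per-node random substreams."""
    return zlib.crc32(node.encode("utf-8"))


_COLUMNS = ("src_id", "src_type", "dst_id", "dst_type", "relation", "weight")


def load_graph(path, schema: Schema) -> HeteroGraph:
    """Read a 6-column edge-list TSV into a validated HeteroGraph.

    Columns: src_id, src_type, dst_id, dst_type, relation, weight.  Lines
    starting with '#' are comments.  Every violation — malformed line, weight
    outside (0, 1], conflicting node types, duplicate edge, undeclared
    relation — raises with the 1-based line number.
    """
    g = HeteroGraph(schema)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(
                    f"expected 6 tab-separated columns, found {len(parts)}", lineno
                )
            src, src_t, dst, dst_t, relation, weight_s = parts
            try:
                weight = float(weight_s)
            except ValueError:
                raise ParseError(f"unparseable weight {weight_s!r}", lineno) from None
            try:
                g.add_node(src, src_t)
                g.add_node(dst, dst_t)
                g.add_edge(src, dst, relation, weight)
            except GraphError as exc:
                raise type(exc)(f"line {lineno}: {exc}") from None
    return g


def write_graph(g: HeteroGraph, path) -> None:
    """Write the canonical edge list as TSV; load_graph(write_graph(g)) == g."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(_COLUMNS) + "\n")
        for u, v, label, w in g.edge_list():
            fh.write(
                f"{u}\t{g.node_type(u)}\t{v}\t{g.node_type(v)}\t{label}\t{w!r}\n"
            )


def induced_subgraph(g: HeteroGraph, types: set[str] | list[str]) -> HeteroGraph:
    """Subnetwork on a subset of node types (e.g. drop genes to probe how much
    the heterogeneous bridge contributes)."""
    keep = set(types)
    schema = Schema(
        keep, [(a, b, lab) for a, b, lab in g.schema.relations if a in keep and b in keep]
    )
    sub = HeteroGraph(schema)
    for n in g.nodes():
        if g.node_type(n) in keep:
            sub.add_node(n, g.node_type(n))
    for e in g.edges():
        if g.node_type(e.u) in keep and g.node_type(e.v) in keep:
            sub.add_edge(e.u, e.v, e.label, e.weight)
    return sub
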