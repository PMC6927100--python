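"""Meta paths: representation, candidate enumeration and the walk-based
selection measure.

A meta path is an ordered sequence of node types (optionally annotated with
relation labels), e.g. Gene -sim-> Gene -assoc-> Disease, written "GGD".
Different meta paths carry different composite semantics, and the choice
matters: a path whose walks spread over many nodes captures more of the
network.  The selection measure counts *isolated walking nodes* — nodes
visited no more than m times when m walks are launched per start node —

    C(P; m) = sum_{v_i in V} I(t_i <= m)

and smaller is better.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import HeteroGraph, Schema

__all__ = [
    "MetaPath",
    "MeasureEntry",
    "enumerate_metapaths",
    "isolated_walk_measure",
    "select_metapath",
]

DEFAULT_MAX_EDGES = 3  # long meta paths add noise, not link structure
DEFAULT_WALKS_M = 10


@dataclass(frozen=True)
class MetaPath:
    """Ordered node-type sequence, optionally relation-labelled per step."""

    node_types: tuple[str, ...]
    relation_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "node_types", tuple(self.node_types))
        if self.relation_labels is not None:
            object.__setattr__(self, "relation_labels", tuple(self.relation_labels))
        if len(self.node_types) < 2:
            raise ValueError("a meta path needs at least two node types")
        if self.relation_labels is not None and len(self.relation_labels) != len(
            self.node_types
        ) - 1:
            raise ValueError("need exactly one relation label per step")

    def __len__(self) -> int:
        return len(self.node_types)

    @property
    def string_form(self) -> str:
        """Type-initial shorthand, e.g. ('gene','gene','disease') -> 'GGD'."""
        return "".join(t[0].upper() for t in self.node_types)

    def __str__(self) -> str:
        return self.string_form

    def reversed(self) -> "MetaPath":
        labels = self.relation_labels[::-1] if self.relation_labels else None
        return MetaPath(self.node_types[::-1], labels)

    def validate_against(self, schema: Schema) -> None:
        for k in range(len(self.node_types) - 1):
            a, b = self.node_types[k], self.node_types[k + 1]
            labels = schema.labels_between(a, b)
            if not labels:
                raise ValueError(f"no schema relation between {a!r} and {b!r}")
            if self.relation_labels is not None and self.relation_labels[k] not in labels:
                raise ValueError(
                    f"relation {self.relation_labels[k]!r} not declared between "
                    f"{a!r} and {b!r}"
                )

    @classmethod
    def from_string(cls, s: str, schema: Schema) -> "MetaPath":
        """Parse a type-initial string like 'GGD' against the schema.

        Requires type initials to be unique within the schema.  Labels are
        attached when a single relation connects each consecutive pair.
        """
        by_initial: dict[str, str] = {}
        for t in sorted(schema.node_types):
            ini = t[0].upper()
            if ini in by_initial:
                raise ValueError(
                    f"ambiguous initial {ini!r} ({by_initial[ini]!r} vs {t!r}); "
                    "construct the MetaPath explicitly"
                )
            by_initial[ini] = t
        try:
            types = tuple(by_initial[c.upper()] for c in s)
        except KeyError as exc:
            raise ValueError(f"unknown type initial {exc.args[0]!r} in {s!r}") from None
        mp = cls(types, _unique_labels(types, schema))
        mp.validate_against(schema)
        return mp


def _unique_labels(types: tuple[str, ...], schema: Schema) -> tuple[str, ...] | None:
    labels = []
    for k in range(len(types) - 1):
        cands = schema.labels_between(types[k], types[k + 1])
        if len(cands) != 1:
            return None
        labels.append(cands[0])
    return tuple(labels)


@dataclass(frozen=True)
class MeasureEntry:
    """Selection-measure record for one candidate meta path."""

    path: MetaPath
    isolated_count: int
    walks_per_node: int
    seed: int


def enumerate_metapaths(
    schema: Schema, src: str, dst: str, max_edges: int = DEFAULT_MAX_EDGES
) -> list[MetaPath]:
    """All type-paths from ``src`` to ``dst`` with 1..max_edges schema steps.

    Repeated types and back-tracking (e.g. G->D->G->D) are legitimate
    composite relations and are kept; only exact string repeats are
    deduplicated.  Sorted by string form.  Unreachable dst yields [].
    """
    if src not in schema.node_types or dst not in schema.node_types:
        raise ValueError(f"{src!r} or {dst!r} not a schema node type")
    if max_edges < 1:
        raise ValueError("max_edges must be >= 1")
    found: dict[str, MetaPath] = {}
    stack: list[tuple[str, ...]] = [(src,)]
    while stack:
        prefix = stack.pop()
        for nxt in schema.neighbor_types(prefix[-1]):
            cand = prefix + (nxt,)
            if nxt == dst:
                mp = MetaPath(cand, _unique_labels(cand, schema))
                found.setdefault(mp.string_form, mp)
            if len(cand) - 1 < max_edges:
                stack.append(cand)
    return [found[k] for k in sorted(found)]


def isolated_walk_measure(
    g: HeteroGraph,
    p: MetaPath,
    m: int = DEFAULT_WALKS_M,
    seed: int = 0,
    count_starts: bool = True,
) -> MeasureEntry:
    """Run m walks per start node under ``p`` and count isolated nodes.

    Every node visit counts toward t_i — walk starts included by default, so
    a start-type node is isolated exactly when no other walk ever reaches it.
    Truncated walks contribute the visits of their realised prefix.
    """
    from .walker import generate_corpus  # deferred: walker imports MetaPath

    if m < 1:
        raise ValueError("m must be >= 1")
    p.validate_against(g.schema)
    corpus = generate_corpus(g, p, walks_per_node=m, seed=seed, include_reverse=False)
    counts = corpus.visit_counts()
    if not count_starts:
        for w in corpus.walks:
            counts[w.node_ids[0]] -= 1
    isolated = sum(1 for n in g.nodes() if counts.get(n, 0) <= m)
    return MeasureEntry(p, isolated, m, seed)


def select_metapath(reports: list[MeasureEntry]) -> MetaPath:
    """Smallest isolated count wins; ties fall to the lexicographically
    smallest string form."""
    if not reports:
        raise ValueError("no measure reports to select from")
    best = min(reports, key=lambda r: (r.isolated_count, r.path.string_form))
    return best.path
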