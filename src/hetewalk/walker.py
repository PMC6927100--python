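"""Meta-path-controlled, weight-biased random walks.

A meta path A1 -> A2 -> ... -> Am fixes the node type at every walk position.
From the current node the walker may only step to a neighbor of the next
type on the path (through the path's relation label when one is given), with
probability proportional to the edge weight:

    Pr(v_j | v_i; P) = w_ij / sum_{phi(v_k) = A_{k+1}} w_ik

A walk therefore has at most m nodes — the template is traversed once, not
cycled — and stops early at a dead end (a node with no neighbor of the
required type), which is kept as a truncated walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import HeteroGraph, node_stream_key
from .metapath import MetaPath

__all__ = ["Walk", "WalkCorpus", "transition_distribution", "walk", "generate_corpus"]


@dataclass(frozen=True)
class Walk:
    node_ids: tuple[str, ...]
    complete: bool

    def __len__(self) -> int:
        return len(self.node_ids)


@dataclass
class WalkCorpus:
    """All walks generated for one meta path at a given walks-per-node budget."""

    walks: list[Walk]
    metapath: MetaPath
    walks_per_node: int
    seed: int
    include_reverse: bool = True
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.walks)

    def visit_counts(self) -> dict[str, int]:
        """Times each node occurs across all walks (walk starts included)."""
        counts: dict[str, int] = {}
        for w in self.walks:
            for n in w.node_ids:
                counts[n] = counts.get(n, 0) + 1
        return counts


def transition_distribution(
    g: HeteroGraph, v: str, next_type: str, relation: str | None = None
) -> list[tuple[str, float]]:
    """Exact next-step distribution from ``v`` restricted to ``next_type``.

    Probabilities are edge weights normalised over the eligible neighbors;
    the empty list signals a dead end (all transitions have probability 0).
    """
    nbrs = g.neighbors_of_type(v, next_type, relation)
    total = sum(w for _, w in nbrs)
    if not nbrs:
        return []
    return [(nid, w / total) for nid, w in nbrs]


def walk(g: HeteroGraph, p: MetaPath, start: str, rng: np.random.Generator) -> Walk:
    """One walk from ``start`` along meta path ``p``; truncated at dead ends."""
    if g.node_type(start) != p.node_types[0]:
        raise ValueError(
            f"start node {start!r} has type {g.node_type(start)!r}, "
            f"meta path begins with {p.node_types[0]!r}"
        )
    seq = [start]
    cur = start
    for k in range(1, len(p.node_types)):
        label = p.relation_labels[k - 1] if p.relation_labels else None
        ids, cum = g.transition_arrays(cur, p.node_types[k], label)
        if not ids:
            return Walk(tuple(seq), complete=False)
        u = rng.random() * cum[-1]
        cur = ids[int(np.searchsorted(cum, u, side="right"))]
        seq.append(cur)
    return Walk(tuple(seq), complete=True)


def _substream(seed: int, direction: int, node: str, walk_index: int) -> np.random.Generator:
    # keyed on (seed, direction, node, index): reproducible regardless of
    # start-node iteration order or scheduling
    ss = np.random.SeedSequence([seed, direction, node_stream_key(node), walk_index])
    return np.random.Generator(np.random.PCG64(ss))


def generate_corpus(
    g: HeteroGraph,
    p: MetaPath,
    walks_per_node: int,
    seed: int,
    include_reverse: bool = True,
) -> WalkCorpus:
    """``walks_per_node`` walks from every node of the path's first type.

    With ``include_reverse`` (default), the reversed path is walked from every
    node of the terminal type as well, so both endpoint types originate
    sequences.  Deterministic given ``seed``.
    """
    if walks_per_node < 1:
        raise ValueError("walks_per_node must be >= 1")
    corpus = WalkCorpus([], p, walks_per_node, seed, include_reverse)
    plans = [(0, p)]
    if include_reverse:
        plans.append((1, p.reversed()))
    for direction, path in plans:
        starts = g.nodes_of_type(path.node_types[0])
        if not starts:
            corpus.warnings.append(
                f"no nodes of start type {path.node_types[0]!r}; corpus slice empty"
            )
            continue
        for s in starts:
            for i in range(walks_per_node):
                corpus.walks.append(walk(g, path, s, _substream(seed, direction, s, i)))
    return corpus
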