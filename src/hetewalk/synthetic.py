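"""Synthetic typed networks with planted cross-type associations.

The generator emulates the structure of an integrated disease–gene–miRNA
network: three node types, six relation families (within-type similarity or
interaction plus the three cross-type associations), and the three weight
regimes seen in real source databases — constant 1.0 (curated links),
two-level 0.3/1.0 (weak vs strong experimental evidence), and continuous
(0, 1] similarity scores.

Ground truth comes from a planted-partition construction: latent blocks span
all node types, within-block pairs link with probability p_in and cross-block
pairs with p_out << p_in, encoding the working assumption that entities in
close network proximity tend to be associated.  A fraction of the
within-block cross-type associations of a target relation is deleted and
returned as held-out positives; cross-block pairs supply unambiguous
negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import HeteroGraph, Schema

__all__ = [
    "RelationSpec",
    "PlantedNetworkSpec",
    "PlantedNetwork",
    "generate",
    "default_spec",
    "sparse_bridge_spec",
    "degenerate_fixtures",
    "sample_negative_pairs",
]

WEIGHT_MODELS = ("constant", "two_level", "uniform")


@dataclass(frozen=True)
class RelationSpec:
    """One relation family: endpoint types, label, block-wise edge
    probabilities and weight regime."""

    type_a: str
    type_b: str
    label: str
    p_in: float
    p_out: float
    weight_model: str = "constant"

    def __post_init__(self):
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError(
                f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        if self.weight_model not in WEIGHT_MODELS:
            raise ValueError(f"weight_model must be one of {WEIGHT_MODELS}")


@dataclass
class PlantedNetworkSpec:
    counts: dict[str, int]
    relations: list[RelationSpec]
    n_blocks: int = 3
    held_out_relation: tuple[str, str, str] | None = None
    held_out_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if any(c < self.n_blocks for c in self.counts.values()):
            raise ValueError("every type needs at least n_blocks nodes")
        if not (0.0 <= self.held_out_fraction < 1.0):
            raise ValueError("held_out_fraction must lie in [0, 1)")

    def schema(self) -> Schema:
        return Schema(
            set(self.counts), [(r.type_a, r.type_b, r.label) for r in self.relations]
        )


@dataclass
class PlantedNetwork:
    """Generated graph, the deleted ground-truth associations, and the latent
    block of every node (needed to sample cross-block negatives)."""

    graph: HeteroGraph
    held_out: set[tuple[str, str, str]]  # (u, v, label), u of held_out_relation's type_a
    blocks: dict[str, int]
    spec: PlantedNetworkSpec


def default_spec(
    n_per_type: int = 60,
    n_blocks: int = 3,
    p_in: float = 0.3,
    p_out: float = 0.02,
    held_out_fraction: float = 0.2,
    seed: int = 0,
) -> PlantedNetworkSpec:
    """Three types, six relation families, mixed weight regimes; the held-out
    relation is the gene–disease association."""
    rel = lambda a, b, lab, wm: RelationSpec(a, b, lab, p_in, p_out, wm)
    return PlantedNetworkSpec(
        counts={"gene": n_per_type, "disease": n_per_type, "mirna": n_per_type},
        relations=[
            rel("gene", "gene", "sim", "constant"),
            rel("mirna", "mirna", "sim", "uniform"),
            rel("disease", "disease", "sim", "uniform"),
            rel("gene", "disease", "assoc", "uniform"),
            rel("gene", "mirna", "assoc", "two_level"),
            rel("mirna", "disease", "assoc", "constant"),
        ],
        n_blocks=n_blocks,
        held_out_relation=("gene", "disease", "assoc"),
        held_out_fraction=held_out_fraction,
        seed=seed,
    )


def sparse_bridge_spec(
    n_per_type: int = 60,
    n_blocks: int = 3,
    seed: int = 0,
) -> PlantedNetworkSpec:
    """Network with scarce miRNA–disease associations mediated by genes.

    The miRNA–disease layer is made genuinely sparse (p_in=0.05, 70% of the
    within-block associations held out, leaving roughly one residual anchor
    per miRNA) while gene similarity and the two gene-anchored association
    layers stay dense — the regime in which integrated real networks show
    their advantage, since miRNA/disease similarity alone cannot align the
    two types' communities and the gene layer bridges them indirectly.
    """
    rel = RelationSpec
    return PlantedNetworkSpec(
        counts={"gene": n_per_type, "disease": n_per_type, "mirna": n_per_type},
        relations=[
            rel("gene", "gene", "sim", 0.3, 0.02, "constant"),
            rel("mirna", "mirna", "sim", 0.3, 0.02, "uniform"),
            rel("disease", "disease", "sim", 0.3, 0.02, "uniform"),
            rel("gene", "disease", "assoc", 0.3, 0.02, "uniform"),
            rel("gene", "mirna", "assoc", 0.3, 0.02, "two_level"),
            rel("mirna", "disease", "assoc", 0.05, 0.002, "constant"),
        ],
        n_blocks=n_blocks,
        held_out_relation=("mirna", "disease", "assoc"),
        held_out_fraction=0.7,
        seed=seed,
    )


def _draw_weight(model: str, rng: np.random.Generator) -> float:
    if model == "constant":
        return 1.0
    if model == "two_level":
        # strong:weak evidence mix of roughly 1:2
        return 1.0 if rng.random() < 1.0 / 3.0 else 0.3
    return float(1.0 - rng.random())  # uniform over (0, 1]


def generate(spec: PlantedNetworkSpec) -> PlantedNetwork:
    """Sample the planted-partition network and carve out held-out truth.

    Nodes of each type are spread round-robin over blocks; every eligible
    pair is an independent Bernoulli draw at p_in (same block) or p_out.
    Deterministic given spec.seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9E37]))
    g = HeteroGraph(spec.schema())
    blocks: dict[str, int] = {}
    names: dict[str, list[str]] = {}
    for t in sorted(spec.counts):
        names[t] = [f"{t}{i:03d}" for i in range(spec.counts[t])]
        for i, n in enumerate(names[t]):
            g.add_node(n, t)
            blocks[n] = i % spec.n_blocks

    within_by_rel: dict[tuple[str, str, str], list[tuple[str, str]]] = {}
    for r in spec.relations:
        key = (r.type_a, r.type_b, r.label)
        within_by_rel[key] = []
        if r.type_a == r.type_b:
            ns = names[r.type_a]
            pairs = [(ns[i], ns[j]) for i in range(len(ns)) for j in range(i + 1, len(ns))]
        else:
            pairs = [(a, b) for a in names[r.type_a] for b in names[r.type_b]]
        n_edges = 0
        draws = rng.random(len(pairs))
        for (a, b), u in zip(pairs, draws):
            same = blocks[a] == blocks[b]
            if u < (r.p_in if same else r.p_out):
                g.add_edge(a, b, r.label, _draw_weight(r.weight_model, rng))
                n_edges += 1
                if same and r.type_a != r.type_b:
                    within_by_rel[key].append((a, b))
        if n_edges == 0:
            raise ValueError(
                f"relation {key} generated no edges; raise p_in/p_out or the type counts"
            )

    held_out: set[tuple[str, str, str]] = set()
    if spec.held_out_relation is not None and spec.held_out_fraction > 0:
        key = spec.held_out_relation
        if key not in within_by_rel:
            raise ValueError(f"held_out_relation {key} is not a declared relation")
        cand = sorted(within_by_rel[key])
        n_hold = int(round(spec.held_out_fraction * len(cand)))
        for i in rng.choice(len(cand), size=n_hold, replace=False):
            u, v = cand[i]
            g.remove_edge(u, v, key[2])
            held_out.add((u, v, key[2]))
    return PlantedNetwork(g, held_out, blocks, spec)


def sample_negative_pairs(
    net: PlantedNetwork,
    type_a: str,
    type_b: str,
    n: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """n cross-block (type_a, type_b) pairs with no edge and no held-out
    association — true negatives by construction."""
    g = net.graph
    as_, bs = g.nodes_of_type(type_a), g.nodes_of_type(type_b)
    held = {frozenset((u, v)) for u, v, _ in net.held_out}
    out, seen = [], set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise RuntimeError("not enough cross-block negative pairs available")
        a = as_[rng.integers(len(as_))]
        b = bs[rng.integers(len(bs))]
        key = frozenset((a, b))
        if (
            net.blocks[a] == net.blocks[b]
            or key in seen
            or key in held
            or g.has_edge(a, b)
        ):
            continue
        seen.add(key)
        out.append((a, b))
    return out


def degenerate_fixtures() -> dict[str, HeteroGraph]:
    """Tiny hand-built graphs with closed-form expectations.

    forced_chain : d1—d2—g1, all weights 1; the only D->D->G walk from d1 is
                   (d1, d2, g1), reproducing the canonical 3-pair extraction
                   example.
    dead_end     : d1—d2 only; a D->D->G walk truncates after two nodes.
    star10       : gene hub g1 linked to diseases d01..d10, uniform weight —
                   a G->D step is uniform over the ten leaves.
    two_component: two disconnected gene–disease squares; no walk crosses
                   components, so cross-component pairs never co-occur.
    k11          : single gene–disease edge; every G->D walk is forced.
    """
    schema = Schema(
        {"gene", "disease"},
        [("gene", "gene", "sim"), ("disease", "disease", "sim"), ("gene", "disease", "assoc")],
    )
    out: dict[str, HeteroGraph] = {}

    g = HeteroGraph(schema)
    for n, t in [("d1", "disease"), ("d2", "disease"), ("g1", "gene")]:
        g.add_node(n, t)
    g.add_edge("d1", "d2", "sim", 1.0)
    g.add_edge("d2", "g1", "assoc", 1.0)
    out["forced_chain"] = g

    g = HeteroGraph(schema)
    g.add_node("d1", "disease")
    g.add_node("d2", "disease")
    g.add_node("g1", "gene")  # isolated gene: d2 has no gene neighbor
    g.add_edge("d1", "d2", "sim", 1.0)
    out["dead_end"] = g

    g = HeteroGraph(schema)
    g.add_node("g1", "gene")
    for i in range(1, 11):
        g.add_node(f"d{i:02d}", "disease")
        g.add_edge("g1", f"d{i:02d}", "assoc", 1.0)
    out["star10"] = g

    g = HeteroGraph(schema)
    for comp in ("a", "b"):
        for i in (1, 2):
            g.add_node(f"g_{comp}{i}", "gene")
            g.add_node(f"d_{comp}{i}", "disease")
        g.add_edge(f"g_{comp}1", f"g_{comp}2", "sim", 1.0)
        g.add_edge(f"d_{comp}1", f"d_{comp}2", "sim", 1.0)
        g.add_edge(f"g_{comp}1", f"d_{comp}1", "assoc", 1.0)
        g.add_edge(f"g_{comp}2", f"d_{comp}2", "assoc", 1.0)
    out["two_component"] = g

    g = HeteroGraph(schema)
    g.add_node("g1", "gene")
    g.add_node("d1", "disease")
    g.add_edge("g1", "d1", "assoc", 1.0)
    out["k11"] = g
    return out
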