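import numpy as np
import pytest

from hetewalk import HeteroGraph, Schema, degenerate_fixtures


@pytest.fixture(scope="session")
def tri_schema() -> Schema:
    """The three-type disease/gene/miRNA schema with its six relation
    families: within-type similarity (or interaction) plus the three
    cross-type associations."""
    return Schema(
        {"gene", "disease", "mirna"},
        [
            ("gene", "gene", "sim"),
            ("mirna", "mirna", "sim"),
            ("disease", "disease", "sim"),
            ("gene", "disease", "assoc"),
            ("gene", "mirna", "assoc"),
            ("mirna", "disease", "assoc"),
        ],
    )


@pytest.fixture(scope="session")
def fixtures() -> dict[str, HeteroGraph]:
    return degenerate_fixtures()


@pytest.fixture
def weighted_toy(tri_schema) -> HeteroGraph:
    """Six nodes; d1 has disease neighbors with weights 0.2/0.6 so the
    biased step distribution is exactly (0.25, 0.75)."""
    g = HeteroGraph(tri_schema)
    for n, t in [
        ("d1", "disease"),
        ("d2", "disease"),
        ("d3", "disease"),
        ("g1", "gene"),
        ("g2", "gene"),
        ("g3", "gene"),
    ]:
        g.add_node(n, t)
    g.add_edge("d1", "d2", "sim", 0.2)
    g.add_edge("d1", "d3", "sim", 0.6)
    g.add_edge("d2", "g1", "assoc", 1.0)
    g.add_edge("d3", "g2", "assoc", 0.5)
    g.add_edge("d3", "g3", "assoc", 0.5)
    g.add_edge("g1", "g2", "sim", 1.0)
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
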