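"""Build a tiny typed edge list, load it with schema validation, inspect it.

The edge-list format carries one edge per line (src, src_type, dst,
dst_type, relation, weight in (0,1]); the loader rejects anything the schema
does not declare and reports the offending line number.
"""

import tempfile
from pathlib import Path

from hetewalk import Schema, load_graph

schema = Schema(
    {"gene", "disease", "mirna"},
    [
        ("gene", "gene", "sim"),
        ("gene", "disease", "assoc"),
        ("mirna", "disease", "assoc"),
    ],
)

edges = """\
# src  src_type  dst  dst_type  relation  weight
TP53\tgene\tBRCA1\tgene\tsim\t1.0
TP53\tgene\tOMIM:114480\tdisease\tassoc\t0.82
BRCA1\tgene\tOMIM:114480\tdisease\tassoc\t0.95
hsa-mir-21\tmirna\tOMIM:114480\tdisease\tassoc\t1.0
""".replace("  ", "\t")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "edges.tsv"
    path.write_text(edges)
    g = load_graph(path, schema)

print(f"nodes: {len(g)}, edges: {g.n_edges}")
for t in sorted(schema.node_types):
    print(f"  {t}: {g.nodes_of_type(t)}")
print("gene neighbors of OMIM:114480:", g.neighbors_of_type("OMIM:114480", "gene"))
# The typed neighbor slice is what a meta-path walk normalises over: the two
# genes above would be chosen with probability 0.82/1.77 and 0.95/1.77.
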