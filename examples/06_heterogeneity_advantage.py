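"""Quantify what the gene layer adds to miRNA-disease prediction.

On a network whose miRNA-disease associations are scarce, the two-type
(miRNA + disease) subnetwork must align the two types' communities from a
handful of anchor edges, while the full three-type network can route walks
through the dense gene layer.  Both pipelines are scored on the same
held-out positives and negatives.
"""

import numpy as np

from hetewalk import (
    TrainConfig,
    evaluate_planted,
    generate,
    induced_subgraph,
    sample_negative_pairs,
    sparse_bridge_spec,
)

seed = 1
net = generate(sparse_bridge_spec(seed=seed))
pos = [(u, v) for u, v, _ in sorted(net.held_out)]
rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4E9]))
neg = sample_negative_pairs(net, "mirna", "disease", len(pos), rng)
print(f"{len(pos)} held-out miRNA-disease associations, "
      f"{net.graph.n_edges} edges in the full network")

cfg = TrainConfig(dim=32, epochs=5, walks_per_node=10)
full = evaluate_planted(net, cfg, seed=seed, negatives=neg)
sub = evaluate_planted(
    net, cfg, seed=seed,
    graph=induced_subgraph(net.graph, {"mirna", "disease"}),
    negatives=neg,
)
print(f"full 3-type network : AUROC {full.auroc:.3f} (meta path {full.selected_path})")
print(f"miRNA+disease only  : AUROC {sub.auroc:.3f} (meta path {sub.selected_path})")
# The gap is the value of integrating the gene layer: indirect
# miRNA-gene-disease context substitutes for missing direct associations.
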