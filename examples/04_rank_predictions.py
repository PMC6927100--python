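"""Rank candidate gene associations for one disease by cosine similarity.

Genes already linked to the disease are removed from the list but keep the
rank they held before removal, so a high-ranking *novel* candidate is easy
to spot — those are the pairs worth experimental follow-up.
"""

from hetewalk import (
    MetaPath,
    TrainConfig,
    default_spec,
    generate,
    generate_corpus,
    rank_candidates,
    train,
)

net = generate(default_spec(seed=1))
path = MetaPath(("gene", "gene", "disease", "disease"), ("sim", "assoc", "sim"))
corpus = generate_corpus(net.graph, path, walks_per_node=10, seed=1)
emb = train(corpus, net.graph, TrainConfig(dim=32, epochs=5, seed=1))

disease = "disease053"  # has several deleted (held-out) associations
ranked = rank_candidates(emb, disease, "gene", net.graph, exclude_known=True)
print(f"top novel gene candidates for {disease} (original rank in brackets):")
for gene, score in ranked.candidates[:8]:
    planted = "planted!" if (gene, disease, "assoc") in net.held_out else ""
    print(f"  [{ranked.original_ranks[gene]:3d}] {gene}  cosine={score:+.3f}  {planted}")
# 'planted!' marks candidates whose association was deleted before training:
# the embedding recovers them from indirect meta-path context alone.
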