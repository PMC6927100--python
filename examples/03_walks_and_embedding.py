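"""Generate a walk corpus along a meta path and train node embeddings.

Walks follow the path's type template with weight-proportional steps; every
co-occurring node pair in a walk becomes a positive training pair, contrasted
against 5 same-type negatives under the skip-gram objective.
"""

from hetewalk import MetaPath, TrainConfig, default_spec, generate, generate_corpus, train

net = generate(default_spec(seed=1))
path = MetaPath(("gene", "gene", "disease", "disease"), ("sim", "assoc", "sim"))

corpus = generate_corpus(net.graph, path, walks_per_node=10, seed=1)
complete = sum(w.complete for w in corpus.walks)
print(f"meta path {path.string_form}: {len(corpus)} walks, {complete} complete")

cfg = TrainConfig(dim=32, epochs=5, walks_per_node=10, seed=1)
emb = train(corpus, net.graph, cfg)
hist = emb.metadata["objective_history"]
print(f"embedded {len(emb)} nodes in {emb.dim} dimensions "
      f"from {emb.metadata['n_pairs']} training pairs")
print("mean pair objective per epoch:",
      " ".join(f"{h:.3f}" for h in hist))
# The objective (log-likelihood of positives vs sampled negatives) should
# climb epoch over epoch; vectors land in one space shared by all node types.
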