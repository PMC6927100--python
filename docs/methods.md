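# Methods

## Model and assumptions

`hetewalk` embeds a typed, weighted, undirected network into ℝ^d by
maximizing, for every node, the likelihood of the nodes it co-occurs with
in meta-path-controlled random walks. The working assumption is proximity ⇒
association: entities near each other in the integrated network — even
without a direct link — are likely related, and the embedding turns that
graph-proximity into vector-space proximity that is comparable across node
types (raw edge weights from different sources are not).

Three modelling commitments follow the method as published and are worth
stating explicitly:

- **Walks traverse the meta path once.** A walk under A₁→⋯→A_m has at most
  m nodes; the template is not cycled. Dead-end walks are kept truncated
  and still contribute their prefix to training — discarding them would
  silently under-train sparsely connected types.
- **All-pairs extraction, no window.** Every pair of distinct co-occurring
  nodes in a walk is a positive sample (a 3-node walk gives 3 unordered
  pairs, emitted in both orientations). Walks are short, so each
  co-occurrence is a deliberate composite relation, not a windowed
  approximation.
- **One vector per node.** The same x⃗ serves as center and context; there
  is no separate context matrix.

### Transition law

From node v at position k, the next node is drawn among neighbors of the
required type A_{k+1} with probability w/Σw (zero for wrong-type neighbors
and non-neighbors). When the meta path carries relation labels and several
labels connect v to the next type, only edges with the required label are
eligible; in the motivating 3-type network each type pair has a single
relation, so the two behaviours coincide.

### Meta-path selection

C(𝒫; m) counts nodes visited ≤ m times when m walks start from every node
of the path's first type. Start visits count toward tᵢ, so a start node is
isolated exactly when no *other* walk reaches it; the alternative
(excluding starts) is available via `count_starts=False`. Truncated walks
contribute the visits they actually made. Candidates are all schema type
paths between the endpoint types with at most 3 edges (longer paths add
little link structure and much noise); repeated types and backtracking
patterns are legitimate and kept, with exact string duplicates removed.

On planted-partition networks the measure behaves as intended: it
rank-correlates with downstream held-out AUROC, and the pipeline that
enumerates candidates and selects by minimum C consistently outperforms any
fixed short path (see `tests/test_acceptance.py`).

### Training

SGD over shuffled positive pairs with K = 5 uniform same-type negatives per
pair (excluding the context node itself; negatives are *not* required to be
non-neighbors, and no degree^0.75 reweighting is applied — negatives answer
"not this particular node", which is the meaningful contrast in a typed
network). Training negatives are drawn from same-type nodes present in the
walk vocabulary, since a negative must own a vector to receive its
gradient. Defaults: d = 128, 10 walks per node and meta path, 5 epochs,
learning rate decaying linearly 0.025 → 1e-4, vectors initialized uniformly
in [−0.5/d, 0.5/d]. Epoch count and schedule are convention; both are
config-exposed. The log-sigmoid is computed via `−logaddexp(0, −x)` and is
stable for any float64 dot product. A per-epoch mean objective, evaluated
against a frozen negative draw so epochs are comparable, is recorded in the
embedding metadata.

### Evaluation protocol

`cross_validate` repeats: split the target relation's known associations at
the training ratio, delete test edges from the graph, regenerate walks and
retrain from scratch on the reduced graph (no leakage, asserted), then
score test edges and an equal number of freshly sampled type-matched
non-edges by cosine and compute AUROC (Mann–Whitney, half-credit ties). A
node missing from the embedding — e.g. isolated by edge removal — scores 0
and is flagged rather than dropped, keeping the positive and negative
counts equal. Reported is the per-repeat list and its mean.

## Synthetic study conditions

The generator plants latent blocks spanning all three node types: within a
relation, same-block pairs link with p_in and cross-block pairs with p_out.
Blocks crossing types is what gives bridging meta paths real signal. Three
weight regimes mirror real source databases: constant 1.0 (curated
associations and interactions), two-level 1.0/0.3 at roughly 1:2 odds
(strong vs weak experimental evidence), continuous (0, 1] (similarity
scores). Held-out ground truth is drawn only from within-block cross-type
edges (true positives by construction); evaluation negatives only from
cross-block non-edges.

Two named conditions are frozen:

- **`default_spec`** — 60 nodes/type, 3 blocks, p_in = 0.3, p_out = 0.02
  for all six relations, 20% of within-block gene–disease associations held
  out. With d = 32 embeddings the full selection-plus-training pipeline
  recovers the held-out associations at mean AUROC ≈ 0.96 over three seeds;
  random-vector embeddings sit at chance.
- **`sparse_bridge_spec`** — same skeleton but the miRNA–disease layer at
  p_in = 0.05, p_out = 0.002 with 70% held out, leaving roughly one
  residual anchor association per miRNA. This reproduces the regime of real
  integrated networks, whose miRNA–disease layer is orders of magnitude
  sparser than its similarity layers. Here the miRNA+disease-only
  subnetwork cannot reliably align the two types' communities from so few
  anchors, while the full network routes walks through the dense gene
  layer: the 3-type pipeline won all 10 paired seeds at these conditions
  (mean margin ≈ +0.19 AUROC).

What the generator does *not* emulate: heavy-tailed degree distributions,
overlapping or hierarchical communities, correlated weights, and the ID
heterogeneity of real source databases. Passing these tests therefore
demonstrates that the machinery is correct and that the method's claimed
qualitative behaviours hold under its own proximity assumption — not that
any particular real-data AUROC would be attained.

## Numerical and design choices

- Problem sizes throughout (60 nodes/type, d = 32 in tests, 10 walks/node)
  are chosen so every experiment is exactly reproducible on a laptop core
  in seconds to minutes; defaults for real use remain d = 128.
- Determinism: every walk draws from a generator keyed on
  (seed, direction, CRC32(node id), walk index), so corpora are independent
  of iteration order; training, splitting and negative sampling all derive
  from explicit seeds. Same seed ⇒ bit-identical embeddings and scores.
- Ranking ties break on node id; selection-measure ties on the path's
  string form — both to keep outputs stable under reordering.
- Edges with weight outside (0, 1] are rejected at load time (a 0-weight
  edge is unreachable under the transition law and would only poison
  denominators); duplicate (u, v, relation) lines are an error rather than
  a silent dedup, to surface data-integration bugs.
- "Cosine distance" is implemented as cosine similarity ranked descending —
  proximity means association.
- The 10-equal-subsets phrasing of the protocol is realized as a random
  split at the given training ratio per repeat; a separate 10-fold
  partitioner is not implemented.
- Walks start from both endpoint types of the meta path by default
  (`include_reverse=True`), honouring "walks start from every node";
  mid-path starts are not implemented.

## Known limitations

- Training is a Python/NumPy SGD loop: fine at study scale (~10⁴–10⁵ pairs
  per epoch), not tuned for million-edge networks.
- Negative sampling is uniform; frequency-smoothed sampling is not offered.
- Meta paths with wildcards, learned path weights, and multi-path joint
  training are out of scope; one path per corpus.
- The edge-list format cannot represent isolated nodes, so write/load
  round-trips preserve the edge set, not edgeless nodes.
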