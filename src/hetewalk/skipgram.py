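"""Skip-gram embedding with type-matched negative sampling.

Nodes co-occurring in a walk should sit close in the embedding space.  The
softmax objective Pr(v_j | v_i) ∝ exp(x_i · x_j) is approximated per
positive pair (v_i, v_j) by negative sampling:

    log sigma(x_i . x_j) + sum_{n=1}^{K} log sigma(-x_i . x_n)

with sigma the logistic function and the K negatives v_n drawn uniformly
from nodes of the *same type* as v_j (excluding v_j itself) — type-matching
keeps the contrast meaningful in a heterogeneous network, where "not this
gene" is informative and "not this node of any type" is not.

Positive pairs are all ordered pairs of distinct nodes within a walk: walks
are short (the meta-path length), so every co-occurrence is a genuine
composite relation, not a windowed approximation.  A single vector per node
serves as both center and context.  Training is plain SGD with a linearly
decaying learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import HeteroGraph
from .walker import Walk, WalkCorpus

__all__ = [
    "TrainConfig",
    "TrainingPair",
    "EmbeddingTable",
    "extract_pairs",
    "sample_negatives",
    "pair_log_likelihood",
    "pair_gradients",
    "train",
]


@dataclass
class TrainConfig:
    """Hyper-parameters; defaults follow common embedding practice
    (d=128, K=5 negatives, 10 walks per node and meta path)."""

    dim: int = 128
    negatives: int = 5
    walks_per_node: int = 10
    epochs: int = 5
    initial_learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1 or self.negatives < 1 or self.epochs < 1:
            raise ValueError("dim, negatives and epochs must all be >= 1")
        if self.initial_learning_rate <= 0:
            raise ValueError("initial_learning_rate must be positive")


@dataclass(frozen=True)
class TrainingPair:
    """A positive (center, context) pair with its K type-matched negatives."""

    center: str
    context: str
    negatives: tuple[str, ...]

    def __post_init__(self):
        if self.center == self.context:
            raise ValueError("center and context must differ")
        if any(n == self.context for n in self.negatives):
            raise ValueError("a negative equals the context node")


class EmbeddingTable:
    """node id -> d-dimensional vector, with training metadata."""

    def __init__(self, ids: list[str], matrix: np.ndarray, metadata: dict | None = None):
        if matrix.ndim != 2 or matrix.shape[0] != len(ids):
            raise ValueError("matrix must be (n_ids, dim)")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("embedding vectors must be finite")
        self.ids = list(ids)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.index = {nid: i for i, nid in enumerate(self.ids)}
        self.metadata = dict(metadata or {})

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, node: str) -> bool:
        return node in self.index

    def vector(self, node: str) -> np.ndarray:
        try:
            return self.matrix[self.index[node]]
        except KeyError:
            raise KeyError(f"node {node!r} not in embedding") from None

    def save(self, path) -> None:
        """word2vec text format: '<vocab> <dim>' header, then one node per
        line; 17 significant digits round-trip float64 exactly."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)} {self.dim}\n")
            for nid, row in zip(self.ids, self.matrix):
                fh.write(nid + " " + " ".join(f"{x:.17g}" for x in row) + "\n")

    @classmethod
    def load(cls, path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed word2vec header")
            n, d = int(header[0]), int(header[1])
            ids, rows = [], []
            for lineno, line in enumerate(fh, start=2):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != d + 1:
                    raise ValueError(
                        f"{path}:{lineno}: expected {d} components, got {len(parts) - 1}"
                    )
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(ids) != n:
            raise ValueError(f"{path}: header declares {n} rows, found {len(ids)}")
        return cls(ids, np.array(rows, dtype=np.float64))


def extract_pairs(w: Walk) -> list[tuple[str, str]]:
    """All ordered co-occurrence pairs from one walk.

    Every unordered pair of distinct positions with distinct node ids is
    emitted in both orientations, so each node in the pair receives a center
    update.  A 3-node walk yields 3 unordered pairs (6 ordered); a length-1
    dead-end walk yields none.
    """
    ids = w.node_ids
    out: list[tuple[str, str]] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if ids[i] != ids[j]:
                out.append((ids[i], ids[j]))
                out.append((ids[j], ids[i]))
    return out


def sample_negatives(
    g: HeteroGraph, context: str, K: int, rng: np.random.Generator
) -> list[str]:
    """K nodes drawn uniformly with replacement from context's type, never
    the context itself."""
    pool = [n for n in g.nodes_of_type(g.node_type(context)) if n != context]
    if not pool:
        raise ValueError(
            f"cannot sample negatives: {context!r} is the only node of its type"
        )
    return [pool[i] for i in rng.integers(len(pool), size=K)]


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    # stable for |x| up to the float64 range: log sigma(x) = -log(1 + e^-x)
    return -np.logaddexp(0.0, -np.asarray(x, dtype=np.float64))


def pair_log_likelihood(emb: EmbeddingTable, pair: TrainingPair) -> float:
    """log sigma(x_i.x_j) + sum_n log sigma(-x_i.x_n) for one training pair."""
    xc = emb.vector(pair.center)
    xo = emb.vector(pair.context)
    ll = float(_log_sigmoid(xc @ xo))
    for nid in pair.negatives:
        ll += float(_log_sigmoid(-(xc @ emb.vector(nid))))
    return ll


def pair_gradients(
    xc: np.ndarray, xo: np.ndarray, Xn: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the pair objective w.r.t. center, context and
    the K negative vectors (ascent direction)."""
    from scipy.special import expit

    g_pos = 1.0 - expit(xc @ xo)  # = sigma(-xc.xo)
    s_neg = expit(Xn @ xc)  # sigma(xc.xn), shape (K,)
    g_center = g_pos * xo - s_neg @ Xn
    g_context = g_pos * xc
    g_negs = -np.outer(s_neg, xc)
    return g_center, g_context, g_negs


@dataclass
class _PairArrays:
    centers: np.ndarray  # int index into vocab
    contexts: np.ndarray


def _corpus_pairs(corpus: WalkCorpus, index: dict[str, int]) -> _PairArrays:
    ci, oi = [], []
    for w in corpus.walks:
        for c, o in extract_pairs(w):
            ci.append(index[c])
            oi.append(index[o])
    return _PairArrays(np.array(ci, dtype=np.int64), np.array(oi, dtype=np.int64))


def _mean_objective(
    X: np.ndarray, pairs: _PairArrays, negs: np.ndarray
) -> float:
    pos = np.einsum("ij,ij->i", X[pairs.centers], X[pairs.contexts])
    neg = np.einsum("ij,ikj->ik", X[pairs.centers], X[negs])
    return float(np.mean(_log_sigmoid(pos) + _log_sigmoid(-neg).sum(axis=1)))


def train(corpus: WalkCorpus, g: HeteroGraph, cfg: TrainConfig) -> EmbeddingTable:
    """SGD over all walk co-occurrence pairs with K fresh type-matched
    negatives per update.

    Vectors start uniform in [-0.5/d, 0.5/d]; the learning rate decays
    linearly from the initial value to the configured floor over the full
    schedule of epochs x pairs.  A per-epoch mean objective (evaluated on a
    frozen negative draw so epochs are comparable) is recorded in the
    returned table's metadata under 'objective_history'.
    """
    if not corpus.walks or all(len(w) < 2 for w in corpus.walks):
        raise ValueError("corpus is empty or contains no multi-node walks")
    from scipy.special import expit

    vocab = sorted({n for w in corpus.walks for n in w.node_ids})
    index = {n: i for i, n in enumerate(vocab)}
    pairs = _corpus_pairs(corpus, index)
    n_pairs = len(pairs.centers)

    # same-type negative pools, restricted to nodes that own a vector
    pools: dict[str, np.ndarray] = {}
    for t in sorted(g.schema.node_types):
        members = [index[n] for n in g.nodes_of_type(t) if n in index]
        if members:
            pools[t] = np.array(members, dtype=np.int64)
    type_of = np.empty(len(vocab), dtype=object)
    for n, i in index.items():
        type_of[i] = g.node_type(n)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5B1B]))
    X = (rng.random((len(vocab), cfg.dim)) - 0.5) / cfg.dim

    def draw_negs(context_idx: int, k: int) -> np.ndarray:
        pool = pools[type_of[context_idx]]
        out = pool[rng.integers(len(pool), size=k)]
        while True:
            bad = out == context_idx
            if not bad.any():
                return out
            out[bad] = pool[rng.integers(len(pool), size=int(bad.sum()))]

    # frozen negatives for monitoring only
    monitor_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x3A7]))
    mon_negs = np.empty((n_pairs, cfg.negatives), dtype=np.int64)
    for r in range(n_pairs):
        pool = pools[type_of[pairs.contexts[r]]]
        draw = pool[monitor_rng.integers(len(pool), size=cfg.negatives)]
        while (draw == pairs.contexts[r]).any():
            bad = draw == pairs.contexts[r]
            draw[bad] = pool[monitor_rng.integers(len(pool), size=int(bad.sum()))]
        mon_negs[r] = draw

    history = [_mean_objective(X, pairs, mon_negs)]
    total = cfg.epochs * n_pairs
    step = 0
    lr0, lr_min = cfg.initial_learning_rate, cfg.min_learning_rate
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for r in order:
            c, o = pairs.centers[r], pairs.contexts[r]
            negs = draw_negs(o, cfg.negatives)
            lr = max(lr_min, lr0 * (1.0 - step / total))
            xc = X[c]
            g_pos = 1.0 - expit(xc @ X[o])
            s_neg = expit(X[negs] @ xc)
            grad_c = g_pos * X[o] - s_neg @ X[negs]
            X[o] += lr * (g_pos * xc)
            X[negs] -= lr * np.outer(s_neg, xc)
            X[c] += lr * grad_c
            step += 1
        history.append(_mean_objective(X, pairs, mon_negs))

    meta = {
        "metapath": corpus.metapath.string_form,
        "config": {
            "dim": cfg.dim,
            "negatives": cfg.negatives,
            "epochs": cfg.epochs,
            "initial_learning_rate": cfg.initial_learning_rate,
            "seed": cfg.seed,
        },
        "objective_history": history,
        "n_pairs": n_pairs,
    }
    return EmbeddingTable(vocab, X, meta)
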