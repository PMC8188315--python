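"""From-scratch Node2vec over the patient network.

Second-order biased random walks explore the graph: stepping from ``cur`` after
arriving from ``prev``, a candidate ``next`` is weighted 1/p if it returns to
``prev``, 1 if it stays at distance 1 from ``prev``, and 1/q otherwise, so p
controls return probability and q interpolates between breadth-first (q > 1)
and depth-first (q < 1) exploration.  The walk corpus is then fed to a skip-gram
model with negative sampling (plain numpy SGD), maximizing the likelihood of
observing each node's walk neighborhood; patient-node rows of the learned input
matrix become the topological feature vectors.

Everything is deterministic under ``EmbeddingConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .features import FeatureMatrix, Provenance
from .rdf_graph import NodeId, NodeType, PatientGraph

#: Hyperparameter grid explored by pipeline.grid_search.
GRID_NUM_WALKS = (10, 40)
GRID_RETURN_P = (0.5, 1.0, 2.0)
GRID_IN_OUT_Q = (0.5, 1.0, 2.0)
GRID_DIMENSION = tuple(range(10, 101, 10))
GRID_WINDOW = (5, 10)
GRID_WALK_LENGTH = (40, 80)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Node2vec hyperparameters.

    Defaults sit at the middle of the standard grid: 10 walks per node of length
    80, window 10, dimension 50, unbiased walks (p = q = 1).  Optimizer settings
    follow common word2vec practice: 5 negative samples from the unigram^(3/4)
    distribution, initial learning rate 0.025 with linear decay, 5 epochs,
    uniform initialization in [-0.5/d, 0.5/d].
    """

    num_walks: int = 10
    return_p: float = 1.0
    in_out_q: float = 1.0
    dimension: int = 50
    window: int = 10
    walk_length: int = 80
    epochs: int = 5
    negative_samples: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.num_walks, self.dimension, self.window, self.walk_length) < 1:
            raise ValueError("num_walks, dimension, window and walk_length must be >= 1")
        if self.return_p <= 0 or self.in_out_q <= 0:
            raise ValueError("return_p and in_out_q must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class WalkCorpus:
    """A bag of random walks, stored as index sequences over ``node_order``."""

    node_order: tuple[NodeId, ...]
    walks: tuple[np.ndarray, ...]

    def iter_node_walks(self) -> Iterator[tuple[NodeId, ...]]:
        for w in self.walks:
            yield tuple(self.node_order[i] for i in w)

    def export(self, path: str | Path) -> None:
        """One walk per line, space-separated node ids."""
        with Path(path).open("w") as fh:
            for w in self.walks:
                fh.write(" ".join(str(self.node_order[i]) for i in w) + "\n")


@dataclass(frozen=True)
class EmbeddingMatrix:
    node_order: tuple[NodeId, ...]
    vectors: np.ndarray  # |V| x d float64

    def vector(self, node: NodeId) -> np.ndarray:
        return self.vectors[self.node_order.index(node)]

    def to_tsv(self, path: str | Path) -> None:
        """node_id followed by the d vector components, one node per line."""
        d = self.vectors.shape[1]
        with Path(path).open("w") as fh:
            fh.write("node_id\t" + "\t".join(f"dim_{j}" for j in range(d)) + "\n")
            for node, vec in zip(self.node_order, self.vectors):
                fh.write(str(node) + "\t" + "\t".join(f"{v:.8g}" for v in vec) + "\n")


class _IndexedGraph:
    """CSR-style view of a PatientGraph with sorted neighbor arrays."""

    def __init__(self, graph: PatientGraph):
        self.node_order: list[NodeId] = graph.node_order()
        self.index = {n: i for i, n in enumerate(self.node_order)}
        adj = graph.adjacency()
        nbr_lists = [
            np.array(sorted(self.index[m] for m in adj[n]), dtype=np.int64)
            for n in self.node_order
        ]
        self.degrees = np.array([len(a) for a in nbr_lists], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.degrees)])
        self.flat = (
            np.concatenate(nbr_lists) if nbr_lists else np.empty(0, dtype=np.int64)
        )

    def neighbors(self, i: int) -> np.ndarray:
        return self.flat[self.offsets[i] : self.offsets[i + 1]]


def transition_weight(
    prev: NodeId | None,
    cur: NodeId,
    nxt: NodeId,
    graph: PatientGraph,
    config: EmbeddingConfig,
) -> float:
    """Unnormalized second-order bias weight for the step cur -> nxt given prev.

    First step (``prev is None``) weights all neighbors 1.  Raises if ``nxt`` is
    not adjacent to ``cur``.
    """
    adj = graph.adjacency()
    if nxt not in adj.get(cur, ()):
        raise ValueError(f"{nxt} is not adjacent to {cur}")
    if prev is None:
        return 1.0
    if cur not in adj.get(prev, ()):
        raise ValueError(f"walk state invalid: {prev} is not adjacent to {cur}")
    if nxt == prev:
        return 1.0 / config.return_p
    if nxt in adj[prev]:
        return 1.0
    return 1.0 / config.in_out_q


def transition_distribution(
    prev: NodeId | None, cur: NodeId, graph: PatientGraph, config: EmbeddingConfig
) -> dict[NodeId, float]:
    """Normalized next-step distribution from state (prev, cur)."""
    adj = graph.adjacency()
    weights = {
        n: transition_weight(prev, cur, n, graph, config) for n in adj.get(cur, ())
    }
    total = sum(weights.values())
    return {n: w / total for n, w in weights.items()}


def generate_walks(graph: PatientGraph, config: EmbeddingConfig) -> WalkCorpus:
    """γ biased random walks of length ≤ t from every node, reproducibly.

    Isolated nodes yield length-1 walks.  With p = q = 1 the walk reduces to a
    first-order simple random walk and is sampled by a vectorized fast path;
    the general second-order case samples proportionally to
    :func:`transition_weight`.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot walk an empty graph")
    ig = _IndexedGraph(graph)
    rng = np.random.default_rng(config.seed)
    if config.return_p == 1.0 and config.in_out_q == 1.0:
        walks = _first_order_walks(ig, config, rng)
    else:
        walks = _second_order_walks(ig, config, rng)
    return WalkCorpus(tuple(ig.node_order), tuple(walks))


def _first_order_walks(
    ig: _IndexedGraph, config: EmbeddingConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    n = len(ig.node_order)
    t = config.walk_length
    starts = np.tile(np.arange(n, dtype=np.int64), config.num_walks)
    steps = np.full((starts.size, t), -1, dtype=np.int64)
    steps[:, 0] = starts
    active = ig.degrees[starts] > 0
    cur = starts.copy()
    for s in range(1, t):
        if not active.any():
            break
        a = np.flatnonzero(active)
        deg = ig.degrees[cur[a]]
        pick = (rng.random(a.size) * deg).astype(np.int64)
        nxt = ig.flat[ig.offsets[cur[a]] + pick]
        cur[a] = nxt
        steps[a, s] = nxt
    return [row[row >= 0] for row in steps]


def _second_order_walks(
    ig: _IndexedGraph, config: EmbeddingConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    inv_p = 1.0 / config.return_p
    inv_q = 1.0 / config.in_out_q
    walks: list[np.ndarray] = []
    for _ in range(config.num_walks):
        for start in range(len(ig.node_order)):
            walk = [start]
            if ig.degrees[start] == 0:
                walks.append(np.array(walk, dtype=np.int64))
                continue
            prev = -1
            cur = start
            for _step in range(config.walk_length - 1):
                nbrs = ig.neighbors(cur)
                if prev < 0:
                    pick = int(rng.random() * nbrs.size)
                else:
                    w = np.full(nbrs.size, inv_q)
                    w[np.isin(nbrs, ig.neighbors(prev), assume_unique=True)] = 1.0
                    w[nbrs == prev] = inv_p
                    cw = np.cumsum(w)
                    pick = int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))
                    pick = min(pick, nbrs.size - 1)
                prev, cur = cur, int(nbrs[pick])
                walk.append(cur)
            walks.append(np.array(walk, dtype=np.int64))
    return walks


def _skipgram_pairs(walks: Sequence[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for w in walks:
        for off in range(1, window + 1):
            if w.size <= off:
                continue
            a, b = w[:-off], w[off:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    return np.concatenate(centers), np.concatenate(contexts)


def train_skipgram(corpus: WalkCorpus, config: EmbeddingConfig) -> EmbeddingMatrix:
    """Skip-gram with negative sampling on the walk corpus.

    Plain sequential SGD over (center, context) pairs — the scheme word2vec
    uses — with the inner loop compiled by numba for speed.  Negatives are
    drawn from the unigram distribution raised to 3/4.  Nodes in
    ``corpus.node_order`` that never co-occur keep their initialization vector.
    """
    if len(corpus.walks) == 0:
        raise ValueError("empty walk corpus")
    n_nodes = len(corpus.node_order)
    d = config.dimension
    rng = np.random.default_rng([config.seed, 7])
    w_in = ((rng.random((n_nodes, d)) - 0.5) / d).astype(np.float32)
    w_out = np.zeros((n_nodes, d), dtype=np.float32)

    centers, contexts = _skipgram_pairs(corpus.walks, config.window)
    if centers.size == 0:
        return EmbeddingMatrix(corpus.node_order, w_in.astype(np.float64))

    counts = np.zeros(n_nodes)
    for w in corpus.walks:
        counts += np.bincount(w, minlength=n_nodes)
    neg_cdf = np.cumsum(counts**0.75)
    neg_cdf /= neg_cdf[-1]

    _sgns_inner(
        w_in,
        w_out,
        centers.astype(np.int64),
        contexts.astype(np.int64),
        neg_cdf,
        config.epochs,
        config.negative_samples,
        config.learning_rate,
        int(config.seed) % (2**31 - 1),
    )
    return EmbeddingMatrix(corpus.node_order, w_in.astype(np.float64))


from numba import njit  # noqa: E402  (kept next to the kernel it compiles)


@njit(cache=True)
def _sgns_inner(w_in, w_out, centers, contexts, neg_cdf, epochs, k, lr0, seed):
    n = centers.shape[0]
    d = w_in.shape[1]
    v = neg_cdf.shape[0]
    np.random.seed(seed)
    total = epochs * n
    done = 0
    grad_c = np.zeros(d, dtype=np.float32)
    for _ep in range(epochs):
        order = np.random.permutation(n)
        for ii in range(n):
            i = order[ii]
            lr = lr0 * (1.0 - done / total)
            if lr < lr0 * 1e-4:
                lr = lr0 * 1e-4
            c = centers[i]
            for j in range(d):
                grad_c[j] = 0.0
            for t in range(k + 1):
                if t == 0:
                    tgt = contexts[i]
                    label = 1.0
                else:
                    r = np.random.random()
                    lo, hi = 0, v - 1
                    while lo < hi:
                        mid = (lo + hi) // 2
                        if neg_cdf[mid] < r:
                            lo = mid + 1
                        else:
                            hi = mid
                    tgt = lo
                    label = 0.0
                s = 0.0
                for j in range(d):
                    s += w_in[c, j] * w_out[tgt, j]
                if s > 10.0:
                    sig = 1.0
                elif s < -10.0:
                    sig = 0.0
                else:
                    sig = 1.0 / (1.0 + np.exp(-s))
                g = (sig - label) * lr
                for j in range(d):
                    grad_c[j] += g * w_out[tgt, j]
                    w_out[tgt, j] -= g * w_in[c, j]
            for j in range(d):
                w_in[c, j] -= grad_c[j]
            done += 1


def embed_patients(
    graph: PatientGraph,
    config: EmbeddingConfig,
    patient_order: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Walks + skip-gram, returning only patient-node rows as a FeatureMatrix.

    ``patient_order`` fixes the row order by patient id (defaults to sorted
    patient nodes).  Feature names are ``n2v_0 .. n2v_{d-1}``.
    """
    corpus = generate_walks(graph, config)
    emb = train_skipgram(corpus, config)
    index = {n: i for i, n in enumerate(emb.node_order)}
    if patient_order is None:
        patient_order = [n.key for n in graph.patient_nodes()]
    rows = []
    for pid in patient_order:
        node = NodeId(NodeType.PATIENT, pid)
        if node not in index:
            raise KeyError(f"patient {pid!r} is not a node of the graph")
        rows.append(emb.vectors[index[node]])
    names = tuple(f"n2v_{j}" for j in range(config.dimension))
    return FeatureMatrix(
        tuple(patient_order),
        names,
        np.asarray(rows, dtype=np.float64),
        (Provenance.N2V,) * config.dimension,
    )
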