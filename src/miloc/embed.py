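"""Network embedding by biased random walks + skip-gram (node2vec).

The sequence-similarity network is walked with edge-weight bias; the three
bipartite association networks are unweighted.  Walks are second-order: from
edge (t -> v) the unnormalized probability of stepping to x is w(v,x)/p if
x == t, w(v,x) if x is adjacent to t, and w(v,x)/q otherwise.  With p == q == 1
this reduces to a first-order weighted walk, which is sampled by a faster
pre-computed-CDF path.

The skip-gram model is trained with negative sampling (unigram^0.75 noise
distribution) in deterministic, single-threaded numpy; word2vec-style linear
learning-rate decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .datatypes import EntityIndex, ValidationError, WeightedGraph

logger = logging.getLogger("miloc")


@njit(cache=False)
def _sgns_epoch(pairs, negs, order, W_in, W_out, lr0, lr_min, done0, total):
    """Word2vec-style sequential SGD over one shuffled epoch (in place)."""
    n_pairs = pairs.shape[0]
    K = negs.shape[1]
    dim = W_in.shape[1]
    gc = np.empty(dim, dtype=np.float32)
    for t in range(n_pairs):
        idx = order[t]
        c = pairs[idx, 0]
        lr = lr0 * (1.0 - (done0 + t) / total)
        if lr < lr_min:
            lr = lr_min
        for d in range(dim):
            gc[d] = 0.0
        for k in range(K + 1):
            o = pairs[idx, 1] if k == 0 else negs[idx, k - 1]
            s = 0.0
            for d in range(dim):
                s += W_in[c, d] * W_out[o, d]
            if s > 60.0:
                p = 1.0
            elif s < -60.0:
                p = 0.0
            else:
                p = 1.0 / (1.0 + np.exp(-s))
            label = 1.0 if k == 0 else 0.0
            g = (p - label) * lr
            for d in range(dim):
                gc[d] += g * W_out[o, d]
                W_out[o, d] -= g * W_in[c, d]
        for d in range(dim):
            W_in[c, d] -= gc[d]


@dataclass
class WalkCorpus:
    """Random-walk corpus over graph node indices."""

    walks: list[np.ndarray]
    node_ids: tuple[str, ...]
    p: float
    q: float
    walks_per_node: int
    walk_length: int
    seed: int


def generate_walks(
    graph: WeightedGraph,
    p: float = 1.0,
    q: float = 1.0,
    walks_per_node: int = 10,
    walk_length: int = 80,
    seed: int = 0,
) -> WalkCorpus:
    """Simulate ``walks_per_node`` biased walks from every node."""
    if p <= 0 or q <= 0:
        raise ValidationError("node2vec p and q must be positive")
    if len(graph) == 0:
        raise ValidationError("cannot walk an empty graph")
    rng = np.random.default_rng(seed)
    n = len(graph)
    adj = graph.adjacency
    indptr, indices, data = adj.indptr, adj.indices, adj.data
    # per-node cumulative weights for O(log d) first-order sampling
    cdfs = [np.cumsum(data[indptr[i]:indptr[i + 1]]) for i in range(n)]
    first_order = p == 1.0 and q == 1.0
    dense_adj = None
    if not first_order:
        dense_adj = np.zeros((n, n), dtype=bool)
        dense_adj[adj.nonzero()] = True

    walks: list[np.ndarray] = []
    for _ in range(walks_per_node):
        for start in range(n):
            walk = [start]
            cur = start
            prev = -1
            for _ in range(walk_length - 1):
                lo, hi = indptr[cur], indptr[cur + 1]
                if lo == hi:  # isolated node: walk ends immediately
                    break
                nbrs = indices[lo:hi]
                if first_order or prev < 0:
                    cdf = cdfs[cur]
                    nxt = nbrs[np.searchsorted(cdf, rng.random() * cdf[-1], side="right")]
                else:
                    w = data[lo:hi].copy()
                    back = nbrs == prev
                    common = dense_adj[prev][nbrs]
                    w[back] /= p
                    w[~back & ~common] /= q
                    cdf = np.cumsum(w)
                    nxt = nbrs[np.searchsorted(cdf, rng.random() * cdf[-1], side="right")]
                walk.append(int(nxt))
                prev, cur = cur, int(nxt)
            walks.append(np.array(walk, dtype=np.int64))
    return WalkCorpus(walks, graph.node_ids, p, q, walks_per_node, walk_length, seed)


def _training_pairs(corpus: WalkCorpus, window: int) -> np.ndarray:
    """(center, context) index pairs from all windows of all walks."""
    pairs = []
    for walk in corpus.walks:
        L = len(walk)
        for offset in range(1, window + 1):
            if L <= offset:
                continue
            a, b = walk[:-offset], walk[offset:]
            pairs.append(np.column_stack([a, b]))
            pairs.append(np.column_stack([b, a]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(pairs, axis=0)


def skipgram_embed(
    corpus: WalkCorpus,
    dim: int = 128,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    seed: int = 0,
    initial_lr: float = 0.025,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Train skip-gram with negative sampling on a walk corpus.

    Returns the input-embedding matrix (one row per graph node, corpus order)
    and the node id tuple.  Nodes absent from the corpus keep a zero row.
    """
    if not corpus.walks:
        raise ValidationError("empty walk corpus")
    n = len(corpus.node_ids)
    rng = np.random.default_rng(seed)
    pairs = _training_pairs(corpus, window)
    if len(pairs) == 0:
        logger.warning("walk corpus yields no context pairs; returning zero embedding")
        return np.zeros((n, dim)), corpus.node_ids

    counts = np.bincount(np.concatenate([w for w in corpus.walks]), minlength=n)
    absent = np.flatnonzero(counts == 0)
    if absent.size:
        logger.warning("%d node(s) absent from walk corpus; zero rows", absent.size)
    noise = counts.astype(float) ** 0.75
    noise /= noise.sum()

    W_in = ((rng.random((n, dim)) - 0.5) / dim).astype(np.float32)
    W_out = np.zeros((n, dim), dtype=np.float32)
    total_steps = epochs * len(pairs)
    done = 0
    min_lr = 1e-4 * initial_lr / 0.025
    noise_cdf = np.cumsum(noise)
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        negs = np.searchsorted(
            noise_cdf, rng.random((len(pairs), negative))
        ).astype(np.int64)
        _sgns_epoch(pairs, negs, order, W_in, W_out,
                    float(initial_lr), float(min_lr), float(done),
                    float(total_steps))
        done += len(pairs)
    W_in[absent] = 0.0
    return W_in.astype(float), corpus.node_ids


def embed_network(
    graph: WeightedGraph,
    mirna_index: EntityIndex,
    dim: int,
    p: float = 1.0,
    q: float = 1.0,
    walks_per_node: int = 10,
    walk_length: int = 80,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Embed a network and return the miRNA rows in master-index order.

    For bipartite association networks the partner rows are discarded.
    miRNAs missing from the graph get a zero row (logged).
    """
    est = Node2VecEmbedder(
        dim=dim, p=p, q=q, walks_per_node=walks_per_node,
        walk_length=walk_length, window=window, epochs=epochs,
        negative=negative, random_state=seed,
    ).fit(graph)
    pos = {v: i for i, v in enumerate(est.node_ids_)}
    out = np.zeros((len(mirna_index), dim))
    missing = []
    for i, m in enumerate(mirna_index.ids):
        if m in pos:
            out[i] = est.embedding_[pos[m]]
        else:
            missing.append(m)
    if missing:
        logger.warning("%d miRNA(s) missing from graph; zero rows", len(missing))
    return out


class Node2VecEmbedder:
    """sklearn-style estimator wrapping walks + skip-gram.

    Parameters follow the common node2vec defaults.  After ``fit`` the learned
    vectors are available as ``embedding_`` (rows aligned with ``node_ids_``).
    """

    def __init__(self, dim: int = 128, p: float = 1.0, q: float = 1.0,
                 walks_per_node: int = 10, walk_length: int = 80,
                 window: int = 5, epochs: int = 5, negative: int = 5,
                 random_state: int = 0):
        self.dim = dim
        self.p = p
        self.q = q
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.window = window
        self.epochs = epochs
        self.negative = negative
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "dim", "p", "q", "walks_per_node", "walk_length", "window",
            "epochs", "negative", "random_state")}

    def set_params(self, **params) -> "Node2VecEmbedder":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, graph: WeightedGraph, y=None) -> "Node2VecEmbedder":
        corpus = generate_walks(
            graph, p=self.p, q=self.q, walks_per_node=self.walks_per_node,
            walk_length=self.walk_length, seed=self.random_state,
        )
        self.embedding_, self.node_ids_ = skipgram_embed(
            corpus, dim=self.dim, window=self.window, epochs=self.epochs,
            negative=self.negative, seed=self.random_state + 1,
        )
        self.corpus_ = corpus
        return self
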