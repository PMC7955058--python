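"""Service embeddings: biased second-order random walks + skip-gram training.

Walks follow the node2vec scheme: from edge ``(prev, curr)`` the unnormalized
weight toward neighbor ``x`` is ``w(curr, x) * alpha`` with ``alpha = 1/p``
when ``x == prev``, ``1`` when ``x`` is adjacent to ``prev``, and ``1/q``
otherwise.  The walk corpus is then fed to skip-gram with negative sampling
(noise distribution = unigram^0.75 over the corpus), implemented directly in
numpy so training is deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ehr_data import EmbeddingTable
from .errors import ConfigError, ContractError
from .service_graph import CooccurrenceGraph

NOISE_POWER = 0.75


@dataclass(frozen=True)
class WalkConfig:
    p: float = 1.0
    q: float = 1.0
    num_walks: int = 10
    walk_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ConfigError("walk parameters p and q must be positive")
        if self.num_walks < 1 or self.walk_length < 1:
            raise ConfigError("num_walks and walk_length must be >= 1")


@dataclass(frozen=True)
class SkipgramConfig:
    dim: int = 128
    window: int = 5
    negatives: int = 10
    epochs: int = 5
    learning_rate: float = 0.025
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ConfigError("dim must be >= 1")
        if self.negatives < 0:
            raise ConfigError("negatives must be >= 0")
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")


def transition_distribution(
    graph: CooccurrenceGraph, prev: str | None, curr: str, config: WalkConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Next-step distribution over the neighbors of ``curr``.

    ``prev`` is ``None`` at the start of a walk, giving a first-order step
    proportional to edge weights.  Returns ``(neighbor_indices, probs)``;
    probs sum to 1 within 1e-12.  An isolated ``curr`` returns empty arrays.
    """
    ci = graph.index(curr)
    nbrs, weights = graph.neighbors(ci)
    if len(nbrs) == 0:
        return nbrs, np.empty(0)
    weights = weights.astype(np.float64)
    if prev is None:
        probs = weights / weights.sum()
        return nbrs, probs
    pi = graph.index(prev)
    if graph.weight(pi, ci) == 0:
        raise ContractError(f"prev {prev!r} is not adjacent to curr {curr!r}")
    prev_nbrs = set(graph.neighbors(pi)[0].tolist())
    alpha = np.empty(len(nbrs))
    for k, x in enumerate(nbrs):
        if x == pi:
            alpha[k] = 1.0 / config.p
        elif x in prev_nbrs:
            alpha[k] = 1.0
        else:
            alpha[k] = 1.0 / config.q
    unnorm = weights * alpha
    return nbrs, unnorm / unnorm.sum()


class _TransitionCache:
    """Lazily cached transition distributions keyed by (prev, curr) index."""

    def __init__(self, graph: CooccurrenceGraph, config: WalkConfig) -> None:
        self.graph = graph
        self.config = config
        self._first: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._second: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def first_order(self, curr: int) -> tuple[np.ndarray, np.ndarray]:
        if curr not in self._first:
            self._first[curr] = transition_distribution(
                self.graph, None, self.graph.services[curr], self.config
            )
        return self._first[curr]

    def second_order(self, prev: int, curr: int) -> tuple[np.ndarray, np.ndarray]:
        key = (prev, curr)
        if key not in self._second:
            self._second[key] = transition_distribution(
                self.graph,
                self.graph.services[prev],
                self.graph.services[curr],
                self.config,
            )
        return self._second[key]


def simulate_walks(graph: CooccurrenceGraph, config: WalkConfig) -> list[list[str]]:
    """Generate ``num_walks`` biased walks from every node, seed-reproducible.

    Walks stop early at isolated nodes (no self-loop inflation).
    """
    rng = np.random.default_rng(config.seed)
    cache = _TransitionCache(graph, config)
    n = graph.n_services
    walks: list[list[str]] = []
    for _ in range(config.num_walks):
        order = rng.permutation(n)
        for start in order:
            walk = [int(start)]
            while len(walk) < config.walk_length:
                curr = walk[-1]
                if len(walk) == 1:
                    nbrs, probs = cache.first_order(curr)
                else:
                    nbrs, probs = cache.second_order(walk[-2], curr)
                if len(nbrs) == 0:
                    break
                nxt = nbrs[rng.choice(len(nbrs), p=probs)]
                walk.append(int(nxt))
            walks.append([graph.services[i] for i in walk])
    return walks


def _corpus_pairs(
    walks_idx: list[np.ndarray], window: int
) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for walk in walks_idx:
        L = len(walk)
        for pos in range(L):
            lo, hi = max(0, pos - window), min(L, pos + window + 1)
            for ctx in range(lo, hi):
                if ctx != pos:
                    centers.append(walk[pos])
                    contexts.append(walk[ctx])
    return (
        np.asarray(centers, dtype=np.int64),
        np.asarray(contexts, dtype=np.int64),
    )


def train_skipgram(
    walks: list[list[str]],
    config: SkipgramConfig,
    vocabulary: list[str] | None = None,
) -> EmbeddingTable:
    """Skip-gram with negative sampling over a walk corpus.

    Every service in ``vocabulary`` (default: all codes in the corpus)
    receives a vector; services absent from all walks keep their seeded
    random initialization after a warning.  SGD with linearly decaying
    learning rate; deterministic given the seed.
    """
    if not walks or all(len(w) == 0 for w in walks):
        raise ContractError("walk corpus is empty")
    corpus_vocab = sorted({tok for walk in walks for tok in walk})
    vocab = list(vocabulary) if vocabulary is not None else corpus_vocab
    missing = set(corpus_vocab) - set(vocab)
    if missing:
        raise ContractError(f"walks contain services outside the vocabulary: {sorted(missing)[:5]}")
    absent = sorted(set(vocab) - set(corpus_vocab))
    if absent:
        warnings.warn(
            f"{len(absent)} service(s) absent from all walks keep random vectors",
            stacklevel=2,
        )
    index = {s: i for i, s in enumerate(vocab)}
    walks_idx = [np.array([index[t] for t in w], dtype=np.int64) for w in walks]
    V, d = len(vocab), config.dim

    rng = np.random.default_rng(config.seed)
    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    if config.epochs == 0:
        return EmbeddingTable(ids=vocab, vectors=w_in)

    counts = np.bincount(np.concatenate(walks_idx), minlength=V).astype(np.float64)
    noise = counts**NOISE_POWER
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)
    noise_cdf[-1] = 1.0

    centers, contexts = _corpus_pairs(walks_idx, config.window)
    n_pairs = len(centers)
    # keep per-row update multiplicity bounded: a batch much larger than the
    # vocabulary applies many same-row gradients at once and can diverge
    batch_size = min(config.batch_size, max(8, 2 * V))
    total_updates = max(n_pairs * config.epochs, 1)
    done = 0
    for _ in range(config.epochs):
        perm = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = perm[lo : lo + batch_size]
            c, o = centers[sel], contexts[sel]
            lr = config.learning_rate * max(1.0 - done / total_updates, 1e-4)
            v = w_in[c]  # (B, d)
            u = w_out[o]
            g_pos = _sigmoid(np.einsum("bd,bd->b", v, u)) - 1.0
            grad_v = g_pos[:, None] * u
            grad_u = g_pos[:, None] * v
            if config.negatives > 0:
                # negatives shared across the batch: turns the noise update
                # into two small matmuls instead of a scatter-add
                neg = np.searchsorted(noise_cdf, rng.random(config.negatives))
                un = w_out[neg]  # (k, d)
                g_neg = _sigmoid(v @ un.T)  # (B, k)
                grad_v += g_neg @ un
                # noise rows see the whole batch; average to keep the
                # per-row step on the per-pair scale
                np.add.at(w_out, neg, -lr * (g_neg.T @ v) / len(sel))
            np.add.at(w_in, c, -lr * grad_v)
            np.add.at(w_out, o, -lr * grad_u)
            done += len(sel)
    return EmbeddingTable(ids=vocab, vectors=w_in)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def embed_services(
    graph: CooccurrenceGraph,
    walk_config: WalkConfig | None = None,
    sg_config: SkipgramConfig | None = None,
) -> EmbeddingTable:
    """Convenience wrapper: walks then skip-gram, covering isolated nodes."""
    walk_config = walk_config or WalkConfig()
    sg_config = sg_config or SkipgramConfig(seed=walk_config.seed)
    walks = simulate_walks(graph, walk_config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_skipgram(walks, sg_config, vocabulary=graph.services)
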