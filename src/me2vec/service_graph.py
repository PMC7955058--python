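"""Weighted service co-occurrence graph from non-overlapping time windows.

Per patient, the journey is cut into half-open windows
``[t0, t0+T), [t0+T, t0+2T), ...`` anchored at that patient's first service
day.  Within a window every unordered pair of distinct service codes
increments the adjacency, and counts from all patients are summed.  Smaller
``T`` yields a sparser adjacency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ehr_data import JourneyTable
from .errors import FormatError, ParameterError

DEFAULT_WINDOW_DAYS = 8
DEFAULT_WINDOW_MINUTES = 60


@dataclass
class CooccurrenceGraph:
    """Symmetric non-negative service-service co-occurrence adjacency."""

    services: list[str]
    adjacency: sp.csr_array
    window_T: int

    def __post_init__(self) -> None:
        n = len(self.services)
        self.adjacency = sp.csr_array(self.adjacency)
        if self.adjacency.shape != (n, n):
            raise FormatError("adjacency shape does not match service count")
        if len(set(self.services)) != n:
            raise FormatError("duplicate service codes")
        if self.adjacency.diagonal().any():
            raise FormatError("adjacency diagonal must be zero")
        if (self.adjacency != self.adjacency.T).nnz:
            raise FormatError("adjacency must be symmetric")
        if self.adjacency.nnz and self.adjacency.data.min() < 0:
            raise FormatError("adjacency entries must be non-negative")
        self._index = {s: i for i, s in enumerate(self.services)}

    @property
    def n_services(self) -> int:
        return len(self.services)

    def index(self, service: str) -> int:
        return self._index[service]

    def neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Neighbor indices and edge weights of node ``i``."""
        row = self.adjacency[[i], :].tocoo()
        return row.coords[1], row.data

    def weight(self, i: int, j: int) -> float:
        return self.adjacency[i, j]


def build_cooccurrence(
    journeys: JourneyTable, T: int, pair_counting: str = "product"
) -> CooccurrenceGraph:
    """Accumulate windowed co-occurrence counts into a :class:`CooccurrenceGraph`.

    ``pair_counting`` selects the within-window increment for a pair of
    distinct codes: ``"product"`` adds the product of their occurrence counts
    (multiset reading), ``"binary"`` adds 1 per window in which both appear.
    """
    if T < 1:
        raise ParameterError(f"window length T must be >= 1, got {T}")
    if pair_counting not in ("product", "binary"):
        raise ParameterError(f"unknown pair_counting mode {pair_counting!r}")
    services = journeys.services
    index = {s: i for i, s in enumerate(services)}
    n = len(services)

    pair_weights: Counter[tuple[int, int]] = Counter()
    frame = journeys.frame
    if len(frame):
        first_day = frame.groupby("patient_id")["date"].transform("min")
        window = (frame["date"] - first_day) // T
        grouped = frame.groupby(["patient_id", window], sort=False)["service_code"]
        for _, codes in grouped:
            counts = Counter(codes)
            if len(counts) < 2:
                continue
            for (a, ca), (b, cb) in combinations(sorted(counts.items()), 2):
                w = ca * cb if pair_counting == "product" else 1
                pair_weights[(index[a], index[b])] += w

    if pair_weights:
        ij = np.array(list(pair_weights.keys()), dtype=np.int64)
        data = np.array(list(pair_weights.values()), dtype=np.int64)
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        adj = sp.coo_array((np.concatenate([data, data]), (rows, cols)), shape=(n, n))
        adj = adj.tocsr()
    else:
        adj = sp.csr_array((n, n), dtype=np.int64)
    return CooccurrenceGraph(services=services, adjacency=adj, window_T=T)


def graph_density(graph: CooccurrenceGraph) -> float:
    """Fraction of off-diagonal upper-triangle entries that are nonzero."""
    n = graph.n_services
    possible = n * (n - 1) // 2
    if possible == 0:
        return 0.0
    nonzero_pairs = sp.triu(graph.adjacency, k=1).nnz
    return nonzero_pairs / possible


def write_cooccurrence(graph: CooccurrenceGraph, edges_path, vocab_path) -> None:
    """Weighted upper-triangle edge list TSV plus a vocabulary file fixing order."""
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    frame = pd.DataFrame(
        {
            "service_a": [graph.services[i] for i in coo.row],
            "service_b": [graph.services[j] for j in coo.col],
            "weight": coo.data,
        }
    )
    frame.to_csv(edges_path, sep="\t", index=False)
    with open(vocab_path, "w", encoding="utf-8") as fh:
        fh.write(f"# T={graph.window_T}\n")
        for s in graph.services:
            fh.write(s + "\n")


def read_cooccurrence(edges_path, vocab_path) -> CooccurrenceGraph:
    with open(vocab_path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# T="):
            raise FormatError("vocabulary file must start with '# T=<window>'")
        window_T = int(header[4:])
        services = [line.strip() for line in fh if line.strip()]
    index = {s: i for i, s in enumerate(services)}
    frame = pd.read_csv(edges_path, sep="\t", dtype={"service_a": str, "service_b": str})
    n = len(services)
    rows = frame["service_a"].map(index).to_numpy()
    cols = frame["service_b"].map(index).to_numpy()
    data = frame["weight"].to_numpy()
    adj = sp.coo_array(
        (np.concatenate([data, data]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    return CooccurrenceGraph(services=services, adjacency=adj, window_T=window_T)
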