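"""Patient embeddings via duplication & annotation + a KL proximity loss.

The patient-service-doctor record stream is first viewed as a bipartite
multigraph (patient -> service edges attributed with the doctor).  Each
service node is split per distinct doctor attribute into a "hybrid"
(service, doctor) node, which turns the multigraph into a simple weighted
patient-hybrid bipartite graph with no edge attributes and no loss of
structural information.

Hybrid vectors are a trainable linear map of the frozen concatenated
service and doctor embeddings:  h = W_a [s || d] + b_a.  Patient vectors
and (W_a, b_a) are optimized by minimizing, per patient, the KL divergence
between the edge-weight empirical context distribution and the softmax
context probability of hybrids given the patient — either exactly (full
softmax; small graphs / oracle tests) or with negative sampling (noise
hybrids drawn proportional to weighted degree^0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ehr_data import EmbeddingTable, JourneyTable
from .errors import ConfigError, ContractError, Me2VecError, ParameterError
from .optim import Adam

HYBRID_SEP = "||"


@dataclass
class PatientMultigraph:
    """Edges (patient, service, doctor, weight); weight = record count."""

    patients: list[str]
    edges: pd.DataFrame  # columns: patient_id, service_code, doctor_id, weight

    def __post_init__(self) -> None:
        cols = ["patient_id", "service_code", "doctor_id", "weight"]
        if list(self.edges.columns) != cols:
            self.edges = self.edges.loc[:, cols]
        if len(self.edges) and (self.edges["weight"] <= 0).any():
            raise Me2VecError("multigraph weights must be positive")
        key = self.edges[["patient_id", "service_code", "doctor_id"]]
        if key.duplicated().any():
            raise Me2VecError("duplicate (patient, service, doctor) edge")

    @property
    def total_weight(self) -> int:
        return int(self.edges["weight"].sum())


@dataclass
class HybridBipartiteGraph:
    """Simple weighted patient-hybrid bipartite graph."""

    patients: list[str]
    hybrids: list[tuple[str, str]]  # (service_code, doctor_id)
    weights: sp.csr_array  # (n_patients, n_hybrids)

    def __post_init__(self) -> None:
        self.weights = sp.csr_array(self.weights)
        if self.weights.shape != (len(self.patients), len(self.hybrids)):
            raise Me2VecError("weight matrix shape mismatch")
        self._pindex = {p: i for i, p in enumerate(self.patients)}

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())

    @property
    def hybrid_ids(self) -> list[str]:
        return [f"{s}{HYBRID_SEP}{d}" for s, d in self.hybrids]

    def patient_edges(self, patient: str) -> tuple[np.ndarray, np.ndarray]:
        k = self._pindex[patient]
        lo, hi = self.weights.indptr[k], self.weights.indptr[k + 1]
        return self.weights.indices[lo:hi], self.weights.data[lo:hi]


@dataclass
class AnnotationParams:
    W_a: np.ndarray  # (p_out, p_service + p_doctor)
    b_a: np.ndarray  # (p_out,)

    def __post_init__(self) -> None:
        if self.W_a.ndim != 2 or self.b_a.shape != (self.W_a.shape[0],):
            raise ConfigError("inconsistent annotation parameter shapes")

    @property
    def out_dim(self) -> int:
        return self.W_a.shape[0]


@dataclass(frozen=True)
class PatientEmbedConfig:
    dim: int = 128
    negatives: int = 10
    epochs: int = 20
    learning_rate: float = 0.01
    batch_size: int = 256
    seed: int = 0
    exact: bool = False

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ConfigError("dim must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if not self.exact and self.negatives < 1:
            raise ParameterError("negatives must be >= 1 in sampled mode")


def build_patient_multigraph(journeys: JourneyTable) -> PatientMultigraph:
    counts = (
        journeys.frame.groupby(["patient_id", "service_code", "doctor_id"])
        .size()
        .rename("weight")
        .reset_index()
    )
    counts = counts.loc[:, ["patient_id", "service_code", "doctor_id", "weight"]]
    return PatientMultigraph(patients=journeys.patients, edges=counts)


def duplicate_annotate(mg: PatientMultigraph) -> HybridBipartiteGraph:
    """Split each service per distinct doctor attribute into hybrid nodes.

    The result is simple (one edge per (patient, hybrid)), conserves total
    edge weight, and has exactly one hybrid per distinct (service, doctor)
    pair in the multigraph.
    """
    edges = mg.edges
    hybrids = sorted(
        set(zip(edges["service_code"], edges["doctor_id"]))
    )
    h_index = {h: i for i, h in enumerate(hybrids)}
    p_index = {p: i for i, p in enumerate(mg.patients)}
    rows = edges["patient_id"].map(p_index).to_numpy(dtype=np.int64)
    cols = np.array(
        [h_index[(s, d)] for s, d in zip(edges["service_code"], edges["doctor_id"])],
        dtype=np.int64,
    ) if len(edges) else np.empty(0, dtype=np.int64)
    weights = sp.coo_array(
        (edges["weight"].to_numpy(dtype=np.int64), (rows, cols)),
        shape=(len(mg.patients), len(hybrids)),
    ).tocsr()
    return HybridBipartiteGraph(patients=mg.patients, hybrids=hybrids, weights=weights)


def hybrid_features(
    hybrids: list[tuple[str, str]],
    service_emb: EmbeddingTable,
    doctor_emb: EmbeddingTable,
) -> np.ndarray:
    """Concatenated [s || d] feature rows, one per hybrid."""
    feats = np.empty((len(hybrids), service_emb.dim + doctor_emb.dim))
    for i, (s, d) in enumerate(hybrids):
        if s not in service_emb:
            raise Me2VecError(f"service {s!r} missing from embedding table")
        if d not in doctor_emb:
            raise Me2VecError(f"doctor {d!r} missing from embedding table")
        feats[i, : service_emb.dim] = service_emb.vector(s)
        feats[i, service_emb.dim :] = doctor_emb.vector(d)
    return feats


def hybrid_vectors(
    hybrids: list[tuple[str, str]],
    service_emb: EmbeddingTable,
    doctor_emb: EmbeddingTable,
    params: AnnotationParams,
) -> EmbeddingTable:
    """h = W_a [s || d] + b_a for each hybrid."""
    X = hybrid_features(hybrids, service_emb, doctor_emb)
    H = X @ params.W_a.T + params.b_a
    ids = [f"{s}{HYBRID_SEP}{d}" for s, d in hybrids]
    return EmbeddingTable(ids=ids, vectors=H)


def empirical_context(
    graph: HybridBipartiteGraph, patient: str
) -> tuple[np.ndarray, np.ndarray]:
    """Edge-weight empirical distribution over the patient's hybrid neighbors."""
    idx, w = graph.patient_edges(patient)
    if len(idx) == 0:
        raise ContractError(f"patient {patient!r} has no hybrid edges")
    w = w.astype(np.float64)
    return idx, w / w.sum()


def _log_softmax_rows(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def _empirical_matrix(graph: HybridBipartiteGraph) -> np.ndarray:
    W = graph.weights.toarray().astype(np.float64)
    sums = W.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        k = int(np.argmax(sums[:, 0] == 0))
        raise ContractError(f"patient {graph.patients[k]!r} has no hybrid edges")
    return W / sums


def exact_patient_loss(
    graph: HybridBipartiteGraph,
    patient_vectors: np.ndarray,
    hybrid_vectors: np.ndarray,
) -> float:
    """Full-softmax KL objective (the brute-force training oracle).

    L = -sum over edges of  p_hat(h|k) * log softmax_h(h . p_k),
    with the softmax normalized over ALL hybrid nodes.
    """
    P = np.asarray(patient_vectors, dtype=np.float64)
    H = np.asarray(hybrid_vectors, dtype=np.float64)
    logits = P @ H.T
    if not np.isfinite(logits).all():
        raise Me2VecError("non-finite dot products in patient loss")
    log_p2 = _log_softmax_rows(logits)
    p_hat = _empirical_matrix(graph)
    return float(-(p_hat * log_p2).sum())


def exact_gradients(
    graph: HybridBipartiteGraph,
    P: np.ndarray,
    X: np.ndarray,
    params: AnnotationParams,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and full-batch gradients wrt (P, W_a, b_a) of the exact objective."""
    H = X @ params.W_a.T + params.b_a
    logits = P @ H.T
    log_p2 = _log_softmax_rows(logits)
    p2 = np.exp(log_p2)
    p_hat = _empirical_matrix(graph)
    loss = float(-(p_hat * log_p2).sum())
    D = p2 - p_hat  # (n_pat, n_hyb)
    gP = D @ H
    gH = D.T @ P
    gW = gH.T @ X
    gb = gH.sum(axis=0)
    return loss, gP, gW, gb


def negative_sampling_gradients(
    P: np.ndarray,
    X: np.ndarray,
    params: AnnotationParams,
    pat_idx: np.ndarray,
    pos_idx: np.ndarray,
    neg_idx: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the noise-contrastive objective for a batch of edges.

    Per edge: -log sigma(h+ . p) - sum_n log sigma(-h- . p).
    Returns (loss, gP, gW_a, gb_a) with gP dense over all patients.
    """
    H = X @ params.W_a.T + params.b_a
    p = P[pat_idx]  # (B, d)
    hp = H[pos_idx]
    hn = H[neg_idx]  # (B, k, d)
    s_pos = _sigmoid(np.einsum("bd,bd->b", p, hp))
    s_neg = _sigmoid(np.einsum("bkd,bd->bk", hn, p))
    loss = float(-(np.log(np.maximum(s_pos, 1e-300)).sum()
                   + np.log(np.maximum(1.0 - s_neg, 1e-300)).sum()))
    g_pos = s_pos - 1.0  # (B,)
    gP = np.zeros_like(P)
    g_p = g_pos[:, None] * hp + np.einsum("bk,bkd->bd", s_neg, hn)
    np.add.at(gP, pat_idx, g_p)
    # gradients wrt hybrid vectors, scattered back through the linear map
    gH = np.zeros_like(H)
    np.add.at(gH, pos_idx, g_pos[:, None] * p)
    np.add.at(gH, neg_idx.ravel(), (s_neg[:, :, None] * p[:, None, :]).reshape(-1, P.shape[1]))
    gW = gH.T @ X
    gb = gH.sum(axis=0)
    return loss, gP, gW, gb


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_annotation_params(
    rng: np.random.Generator, in_dim: int, out_dim: int
) -> AnnotationParams:
    scale = np.sqrt(1.0 / in_dim)
    return AnnotationParams(
        W_a=rng.normal(0.0, scale, size=(out_dim, in_dim)),
        b_a=np.zeros(out_dim),
    )


def train_patient_embeddings(
    graph: HybridBipartiteGraph,
    service_emb: EmbeddingTable,
    doctor_emb: EmbeddingTable,
    config: PatientEmbedConfig | None = None,
) -> tuple[EmbeddingTable, AnnotationParams]:
    """Jointly optimize patient vectors and the annotation map (W_a, b_a).

    Hybrid vectors are always re-derived from the frozen service/doctor
    embeddings through the trainable linear map.  In sampled mode, edges are
    drawn proportional to weight and noise hybrids proportional to weighted
    degree^0.75; in exact mode, full-batch gradient descent on the exact
    softmax objective (small graphs only).
    """
    config = config or PatientEmbedConfig()
    rng = np.random.default_rng(config.seed)
    X = hybrid_features(graph.hybrids, service_emb, doctor_emb)
    n_pat = len(graph.patients)
    P = rng.normal(0.0, 1.0 / np.sqrt(config.dim), size=(n_pat, config.dim))
    params = init_annotation_params(rng, X.shape[1], config.dim)
    if config.epochs == 0 or graph.total_weight == 0:
        return EmbeddingTable(ids=graph.patients, vectors=P), params

    if config.exact:
        for _ in range(config.epochs):
            _, gP, gW, gb = exact_gradients(graph, P, X, params)
            P -= config.learning_rate * gP
            params.W_a -= config.learning_rate * gW
            params.b_a -= config.learning_rate * gb
        return EmbeddingTable(ids=graph.patients, vectors=P), params

    coo = graph.weights.tocoo()
    edge_pat, edge_hyb = coo.coords
    edge_w = coo.data.astype(np.float64)
    edge_cdf = np.cumsum(edge_w / edge_w.sum())
    edge_cdf[-1] = 1.0
    degree = np.asarray(graph.weights.sum(axis=0)).reshape(-1).astype(np.float64)
    noise = degree**0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    noise_cdf[-1] = 1.0
    n_edges = len(edge_w)
    optimizer = Adam(lr=config.learning_rate)
    param_dict = {"P": P, "W_a": params.W_a, "b_a": params.b_a}
    for _ in range(config.epochs):
        sample = np.searchsorted(edge_cdf, rng.random(n_edges))
        for lo in range(0, n_edges, config.batch_size):
            sel = sample[lo : lo + config.batch_size]
            neg = np.searchsorted(noise_cdf, rng.random((len(sel), config.negatives)))
            _, gP, gW, gb = negative_sampling_gradients(
                P, X, params, edge_pat[sel], edge_hyb[sel], neg
            )
            optimizer.step(param_dict, {"P": gP, "W_a": gW, "b_a": gb})
    return EmbeddingTable(ids=graph.patients, vectors=P), params


def write_hybrid_vocabulary(graph: HybridBipartiteGraph, path) -> None:
    frame = pd.DataFrame(
        {
            "hybrid_id": graph.hybrid_ids,
            "service_code": [s for s, _ in graph.hybrids],
            "doctor_id": [d for _, d in graph.hybrids],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
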