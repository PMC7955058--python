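"""Doctor embeddings from a single graph-attention layer.

Doctors are embedded by an auxiliary supervised task: predict each doctor's
primary specialty from the services they administered.  A doctor's vector is
initialized as the weighted average of its service vectors, then updated by
a K-head attention layer over its service neighborhood; service vectors are
frozen inputs.  The trained classifier doubles as a specialty imputer for
doctors whose specialty is missing.

Forward pass, per head k, for doctor j with service neighbors i:

    e_ij   = LeakyReLU(a_k . [W_k d_j || W_k s_i])      (slope 0.2)
    alpha  = softmax over the neighborhood
    head_k = act(sum_i alpha_ij W_k s_i)                (act = ELU default)
    d'_j   = concat_k head_k

All gradients are hand-derived; the optimizer is Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .ehr_data import MISSING_SPECIALTY, EmbeddingTable, JourneyTable
from .errors import ConfigError, ContractError, Me2VecError, TrainingError
from .optim import Adam

LEAKY_SLOPE = 0.2


@dataclass
class DoctorServiceGraph:
    """Weighted bipartite doctor-service graph with per-doctor specialty labels."""

    doctors: list[str]
    services: list[str]
    weights: sp.csr_array  # (n_doctors, n_services), positive integer counts
    specialty: dict[str, str]

    def __post_init__(self) -> None:
        self.weights = sp.csr_array(self.weights)
        if self.weights.shape != (len(self.doctors), len(self.services)):
            raise Me2VecError("weight matrix shape mismatch")
        if self.weights.nnz and self.weights.data.min() <= 0:
            raise Me2VecError("edge weights must be positive")
        degs = self.weights.indptr[1:] - self.weights.indptr[:-1]
        if len(self.doctors) and (degs == 0).any():
            empty = self.doctors[int(np.argmax(degs == 0))]
            raise Me2VecError(f"doctor {empty} has no service edges")

    def doctor_edges(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.weights.indptr[j], self.weights.indptr[j + 1]
        return self.weights.indices[lo:hi], self.weights.data[lo:hi]


@dataclass
class GatParams:
    W: np.ndarray  # (K, p_head, p)
    a: np.ndarray  # (K, 2 * p_head)
    classifier_W: np.ndarray  # (n_classes, K * p_head)
    classifier_b: np.ndarray  # (n_classes,)
    classes: list[str]
    leaky_slope: float = LEAKY_SLOPE
    activation: str = "elu"
    # input features are divided by this during training/inference so large
    # service-vector norms cannot saturate the attention softmax
    feature_scale: float = 1.0

    def __post_init__(self) -> None:
        K, p_head, _ = self.W.shape
        if self.a.shape != (K, 2 * p_head):
            raise ConfigError("attention vector shape must be (K, 2*p_head)")
        if self.classifier_W.shape[1] != K * p_head:
            raise ConfigError("classifier input dim must be K*p_head")

    @property
    def n_heads(self) -> int:
        return self.W.shape[0]

    @property
    def out_dim(self) -> int:
        return self.W.shape[0] * self.W.shape[1]


@dataclass(frozen=True)
class GatConfig:
    heads: int = 4
    epochs: int = 200
    learning_rate: float = 1e-2
    seed: int = 0
    patience: int = 40
    val_fraction: float = 0.1
    activation: str = "elu"
    refeed_queries: bool = True

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise ConfigError("heads must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")


def build_doctor_service_graph(journeys: JourneyTable) -> DoctorServiceGraph:
    """Edge weight = number of (doctor, service) rows; specialty by majority,
    ties broken lexicographically."""
    frame = journeys.frame
    doctors = journeys.doctors
    services = journeys.services
    d_index = {d: i for i, d in enumerate(doctors)}
    s_index = {s: i for i, s in enumerate(services)}
    counts = frame.groupby(["doctor_id", "service_code"]).size()
    rows = np.array([d_index[d] for d, _ in counts.index], dtype=np.int64)
    cols = np.array([s_index[s] for _, s in counts.index], dtype=np.int64)
    weights = sp.coo_array(
        (counts.to_numpy(dtype=np.int64), (rows, cols)),
        shape=(len(doctors), len(services)),
    ).tocsr()

    specialty: dict[str, str] = {}
    spec_counts = frame.groupby(["doctor_id", "specialty"]).size()
    for doctor in doctors:
        sub = spec_counts.loc[doctor]
        specialty[doctor] = min(sub.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return DoctorServiceGraph(doctors, services, weights, specialty)


def init_doctor_vectors(
    graph: DoctorServiceGraph, service_emb: EmbeddingTable
) -> EmbeddingTable:
    """d_j = sum_i w_ij s_i / sum_i w_ij (weighted average of service vectors)."""
    missing = [s for s in graph.services if s not in service_emb]
    if missing:
        raise Me2VecError(f"service(s) missing from embedding table: {missing[:5]}")
    S = service_emb.matrix(graph.services)
    W = graph.weights.astype(np.float64)
    sums = W @ S
    totals = np.asarray(W.sum(axis=1)).reshape(-1)
    return EmbeddingTable(ids=graph.doctors, vectors=sums / totals[:, None])


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "identity":
        return x
    raise ConfigError(f"unknown activation {kind!r}")


def _act_grad(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))
    if kind == "relu":
        return (x > 0).astype(np.float64)
    if kind == "identity":
        return np.ones_like(x)
    raise ConfigError(f"unknown activation {kind!r}")


def attention_forward(
    d_j: np.ndarray, neighbor_vecs: np.ndarray, params: GatParams
) -> tuple[np.ndarray, np.ndarray]:
    """One multi-head attention aggregation.

    Returns ``(d_prime, alpha)`` where ``alpha`` has shape
    ``(K, n_neighbors)`` and each head's row sums to 1.
    """
    neighbor_vecs = np.atleast_2d(np.asarray(neighbor_vecs, dtype=np.float64))
    if neighbor_vecs.shape[0] == 0:
        raise ContractError("attention requires at least one neighbor")
    K, p_head, _ = params.W.shape
    outs, alphas = [], []
    for k in range(K):
        Wk = params.W[k]
        a1, a2 = params.a[k, :p_head], params.a[k, p_head:]
        u = Wk @ d_j
        Z = neighbor_vecs @ Wk.T
        t = a1 @ u + Z @ a2
        e = np.where(t > 0, t, params.leaky_slope * t)
        e = e - e.max()
        ex = np.exp(e)
        alpha = ex / ex.sum()
        m = alpha @ Z
        outs.append(_act(m, params.activation))
        alphas.append(alpha)
    return np.concatenate(outs), np.stack(alphas)


def _forward_all(
    graph: DoctorServiceGraph,
    queries: np.ndarray,
    S: np.ndarray,
    params: GatParams,
) -> np.ndarray:
    out = np.empty((len(graph.doctors), params.out_dim))
    for j in range(len(graph.doctors)):
        svc_idx, _ = graph.doctor_edges(j)
        out[j], _ = attention_forward(queries[j], S[svc_idx], params)
    return out


def _init_params(
    rng: np.random.Generator, p: int, heads: int, classes: list[str], activation: str
) -> GatParams:
    if p % heads != 0:
        raise ConfigError(f"embedding dim {p} not divisible by {heads} heads")
    p_head = p // heads
    scale = np.sqrt(2.0 / (p + p_head))
    return GatParams(
        W=rng.normal(0.0, scale, size=(heads, p_head, p)),
        a=rng.normal(0.0, 0.1, size=(heads, 2 * p_head)),
        classifier_W=rng.normal(0.0, np.sqrt(1.0 / p), size=(len(classes), heads * p_head)),
        classifier_b=np.zeros(len(classes)),
        classes=list(classes),
        activation=activation,
    )


def _doctor_loss_and_grads(
    d_j: np.ndarray,
    neighbor_vecs: np.ndarray,
    label: int,
    params: GatParams,
    grads: dict[str, np.ndarray],
) -> tuple[float, bool]:
    """Accumulate CE loss/gradients for one doctor; returns (loss, correct)."""
    K, p_head, _ = params.W.shape
    act = params.activation
    # forward with cached intermediates
    per_head = []
    d_prime = np.empty(K * p_head)
    for k in range(K):
        Wk = params.W[k]
        a1, a2 = params.a[k, :p_head], params.a[k, p_head:]
        u = Wk @ d_j
        Z = neighbor_vecs @ Wk.T
        t = a1 @ u + Z @ a2
        e = np.where(t > 0, t, params.leaky_slope * t)
        es = e - e.max()
        ex = np.exp(es)
        alpha = ex / ex.sum()
        m = alpha @ Z
        d_prime[k * p_head : (k + 1) * p_head] = _act(m, act)
        per_head.append((u, Z, t, alpha, m))
    logits = params.classifier_W @ d_prime + params.classifier_b
    logits -= logits.max()
    probs = np.exp(logits)
    probs /= probs.sum()
    loss = -np.log(max(probs[label], 1e-300))
    correct = int(np.argmax(logits)) == label

    dlogits = probs.copy()
    dlogits[label] -= 1.0
    grads["classifier_W"] += np.outer(dlogits, d_prime)
    grads["classifier_b"] += dlogits
    g_dprime = params.classifier_W.T @ dlogits
    for k in range(K):
        u, Z, t, alpha, m = per_head[k]
        a1, a2 = params.a[k, :p_head], params.a[k, p_head:]
        g_o = g_dprime[k * p_head : (k + 1) * p_head]
        g_m = g_o * _act_grad(m, act)
        g_alpha = Z @ g_m
        gZ = alpha[:, None] * g_m[None, :]
        g_e = alpha * (g_alpha - alpha @ g_alpha)
        g_t = g_e * np.where(t > 0, 1.0, params.leaky_slope)
        grads["a"][k, :p_head] += g_t.sum() * u
        grads["a"][k, p_head:] += Z.T @ g_t
        g_u = g_t.sum() * a1
        gZ += np.outer(g_t, a2)
        grads["W"][k] += np.outer(g_u, d_j) + gZ.T @ neighbor_vecs
    return float(loss), correct


def train_gat(
    graph: DoctorServiceGraph,
    service_emb: EmbeddingTable,
    config: GatConfig | None = None,
) -> tuple[EmbeddingTable, GatParams, dict]:
    """Train the attention layer + specialty classifier; embed all doctors.

    Doctors whose specialty is the UNKNOWN sentinel are embedded but excluded
    from the loss.  Early stopping on a held-out doctor split.
    """
    config = config or GatConfig()
    rng = np.random.default_rng(config.seed)
    init = init_doctor_vectors(graph, service_emb)
    S = service_emb.matrix(graph.services)
    p = service_emb.dim
    norms = np.linalg.norm(S, axis=1)
    feature_scale = float(np.sqrt(np.mean(norms**2))) or 1.0
    S = S / feature_scale

    labeled = [
        j
        for j, d in enumerate(graph.doctors)
        if graph.specialty[d] != MISSING_SPECIALTY
    ]
    classes = sorted({graph.specialty[graph.doctors[j]] for j in labeled})
    if len(classes) < 2:
        raise TrainingError("need at least 2 distinct known specialties to train")
    class_index = {c: i for i, c in enumerate(classes)}
    labels = {j: class_index[graph.specialty[graph.doctors[j]]] for j in labeled}

    params = _init_params(rng, p, config.heads, classes, config.activation)
    params.feature_scale = feature_scale
    param_dict = {
        "W": params.W,
        "a": params.a,
        "classifier_W": params.classifier_W,
        "classifier_b": params.classifier_b,
    }

    # stratified train/val split over labeled doctors
    train_idx, val_idx = [], []
    for c in range(len(classes)):
        members = np.array([j for j in labeled if labels[j] == c])
        members = members[rng.permutation(len(members))]
        n_val = int(np.floor(config.val_fraction * len(members)))
        val_idx.extend(members[:n_val].tolist())
        train_idx.extend(members[n_val:].tolist())
    train_idx.sort()
    val_idx.sort()

    queries = init.vectors / feature_scale
    optimizer = Adam(lr=config.learning_rate)
    best = {
        "score": -np.inf,
        "params": _copy_params(params),
        "queries": queries.copy(),
        "epoch": -1,
    }
    history = []
    stale = 0
    for epoch in range(config.epochs):
        grads = {k: np.zeros_like(v) for k, v in param_dict.items()}
        total_loss = 0.0
        n_correct = 0
        for j in train_idx:
            svc_idx, _ = graph.doctor_edges(j)
            loss, ok = _doctor_loss_and_grads(
                queries[j], S[svc_idx], labels[j], params, grads
            )
            total_loss += loss
            n_correct += ok
        for g in grads.values():
            g /= max(len(train_idx), 1)
        optimizer.step(param_dict, grads)

        val_acc = _accuracy(graph, queries, S, params, labels, val_idx)
        avg_loss = total_loss / max(len(train_idx), 1)
        # train-loss tiebreaker: a tiny validation set plateaus in coarse
        # steps and would otherwise trip early stopping mid-optimization
        score = val_acc - 0.01 * avg_loss if val_idx else -avg_loss
        history.append(
            {
                "epoch": epoch,
                "train_loss": total_loss / max(len(train_idx), 1),
                "train_acc": n_correct / max(len(train_idx), 1),
                "val_acc": val_acc,
            }
        )
        if config.refeed_queries and params.out_dim == p:
            queries = _forward_all(graph, queries, S, params)
        if score > best["score"] + 1e-12:
            best = {
                "score": score,
                "params": _copy_params(params),
                "queries": queries.copy(),
                "epoch": epoch,
            }
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break

    if config.epochs > 0 and best["epoch"] >= 0:
        params = best["params"]
        queries = best["queries"]
    final = _forward_all(graph, queries, S, params)
    report = {
        "classes": classes,
        "n_train": len(train_idx),
        "n_val": len(val_idx),
        "val_accuracy": _accuracy(graph, queries, S, params, labels, val_idx),
        "train_accuracy": _accuracy(graph, queries, S, params, labels, train_idx),
        "history": history,
    }
    return EmbeddingTable(ids=graph.doctors, vectors=final), params, report


def _copy_params(params: GatParams) -> GatParams:
    return replace(
        params,
        W=params.W.copy(),
        a=params.a.copy(),
        classifier_W=params.classifier_W.copy(),
        classifier_b=params.classifier_b.copy(),
        classes=list(params.classes),
    )


def _accuracy(graph, queries, S, params, labels, idx) -> float:
    if not idx:
        return float("nan")
    n_ok = 0
    for j in idx:
        svc_idx, _ = graph.doctor_edges(j)
        d_prime, _ = attention_forward(queries[j], S[svc_idx], params)
        logits = params.classifier_W @ d_prime + params.classifier_b
        n_ok += int(np.argmax(logits)) == labels[j]
    return n_ok / len(idx)


def impute_specialty(
    doctor_edges: list[tuple[str, float]],
    service_emb: EmbeddingTable,
    params: GatParams,
) -> tuple[str, np.ndarray]:
    """Predict a specialty for an unlabeled doctor from its service edges.

    Forms the weighted-average init vector, applies the attention layer and
    the trained classifier head; returns (argmax label, class probabilities).
    """
    if not doctor_edges:
        raise ContractError("doctor has no service edges")
    for svc, _ in doctor_edges:
        if svc not in service_emb:
            raise Me2VecError(f"unseen service code {svc!r}")
    vecs = np.stack([service_emb.vector(s) for s, _ in doctor_edges])
    vecs = vecs / params.feature_scale
    w = np.array([float(wt) for _, wt in doctor_edges])
    if (w <= 0).any():
        raise ContractError("edge weights must be positive")
    d_init = (w[:, None] * vecs).sum(axis=0) / w.sum()
    d_prime, _ = attention_forward(d_init, vecs, params)
    logits = params.classifier_W @ d_prime + params.classifier_b
    logits -= logits.max()
    probs = np.exp(logits)
    probs /= probs.sum()
    return params.classes[int(np.argmax(probs))], probs
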