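"""Evaluation protocols: node classification, link prediction, binary
outcomes, and a PCA projection utility.

Node classification follows the standard embedding-evaluation recipe:
L2-regularized logistic regression on the embedding vectors at several
training ratios, averaged over repeated stratified splits, scored with
micro- and macro-F1.  Link prediction removes a fraction of patient-doctor
edges while keeping each residual component connected, samples an equal
number of negative non-edges, and scores an LR on concatenated embeddings
with cross-validated ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import (
    StratifiedKFold,
    cross_val_predict,
    train_test_split,
)

from .ehr_data import EmbeddingTable
from .errors import ContractError, Me2VecError, ParameterError

DEFAULT_C = 1.0


@dataclass
class ClassificationReport:
    ratios: list[float]
    micro_f1: dict[float, float]
    macro_f1: dict[float, float]
    n_repeats: int
    seed: int


@dataclass
class LinkSplit:
    residual_edges: list[tuple[str, str]]
    positive_test_edges: list[tuple[str, str]]
    negative_test_edges: list[tuple[str, str]]
    removal_fraction: float
    patients: list[str] = field(default_factory=list)
    doctors: list[str] = field(default_factory=list)


def _lr(seed: int | None = None, C: float = DEFAULT_C) -> LogisticRegression:
    # lbfgs with default l2 penalty; C exposed via config
    return LogisticRegression(C=C, max_iter=2000, solver="lbfgs", random_state=seed)


def node_classification_eval(
    emb: EmbeddingTable,
    labels: dict[str, str],
    ratios: list[float] | None = None,
    repeats: int = 10,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> ClassificationReport:
    """Average micro/macro F1 of an L2 LR probe across training ratios."""
    ratios = list(ratios) if ratios is not None else [0.2, 0.4, 0.6, 0.8]
    for r in ratios:
        if not (0 < r < 1):
            raise ParameterError(f"training ratio {r} outside (0, 1)")
    ids = [i for i in emb.ids if i in labels]
    missing = set(labels) - set(emb.ids)
    if missing:
        raise Me2VecError(f"labeled entities missing embeddings: {sorted(missing)[:5]}")
    X = emb.matrix(ids)
    y = np.array([labels[i] for i in ids])
    if len(np.unique(y)) < 2:
        raise ParameterError("need at least 2 classes for node classification")
    rng = np.random.default_rng(seed)
    micro: dict[float, float] = {}
    macro: dict[float, float] = {}
    for ratio in ratios:
        mi, ma = [], []
        for _ in range(repeats):
            split_seed = int(rng.integers(2**31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, train_size=ratio, stratify=y, random_state=split_seed
            )
            clf = _lr(split_seed, C).fit(X_tr, y_tr)
            pred = clf.predict(X_te)
            mi.append(f1_score(y_te, pred, average="micro"))
            ma.append(f1_score(y_te, pred, average="macro"))
        micro[ratio] = float(np.mean(mi))
        macro[ratio] = float(np.mean(ma))
    return ClassificationReport(
        ratios=ratios, micro_f1=micro, macro_f1=macro, n_repeats=repeats, seed=seed
    )


def link_prediction_split(
    edges: list[tuple[str, str]],
    fraction: float = 0.10,
    seed: int = 0,
    max_tries_factor: int = 50,
) -> LinkSplit:
    """Remove ``fraction`` of edges keeping residual components connected.

    Edge removals that would disconnect the removed edge's component are
    rejected; negatives are sampled uniformly (without replacement) from
    patient-doctor non-edges of the original graph.
    """
    edges = [(str(p), str(d)) for p, d in edges]
    if len(set(edges)) != len(edges):
        raise ParameterError("duplicate edges in patient-doctor edge list")
    if len(edges) < 10:
        raise ParameterError("need at least 10 edges for a link split")
    if not (0 < fraction <= 0.5):
        raise ParameterError("removal fraction must lie in (0, 0.5]")
    patients = sorted({p for p, _ in edges})
    doctors = sorted({d for _, d in edges})
    quota = int(round(fraction * len(edges)))
    rng = np.random.default_rng(seed)

    g = nx.Graph()
    g.add_nodes_from((("p", p) for p in patients))
    g.add_nodes_from((("d", d) for d in doctors))
    g.add_edges_from((("p", p), ("d", d)) for p, d in edges)

    removed: list[tuple[str, str]] = []
    candidates = list(edges)
    order = rng.permutation(len(candidates))
    for i in order:
        if len(removed) == quota:
            break
        p, d = candidates[i]
        u, v = ("p", p), ("d", d)
        g.remove_edge(u, v)
        if nx.has_path(g, u, v):
            removed.append((p, d))
        else:
            g.add_edge(u, v)
    if len(removed) < quota:
        raise Me2VecError(
            f"connectivity allows removing only {len(removed)} of {quota} edges"
        )

    edge_set = set(edges)
    n_possible = len(patients) * len(doctors) - len(edge_set)
    if n_possible < quota:
        raise Me2VecError("not enough non-edges to sample negatives")
    negatives: set[tuple[str, str]] = set()
    tries = 0
    while len(negatives) < quota:
        tries += 1
        if tries > max_tries_factor * max(quota, 1) + 1000:
            raise Me2VecError("negative sampling did not converge")
        p = patients[int(rng.integers(len(patients)))]
        d = doctors[int(rng.integers(len(doctors)))]
        if (p, d) not in edge_set and (p, d) not in negatives:
            negatives.add((p, d))

    residual = [e for e in edges if e not in set(removed)]
    return LinkSplit(
        residual_edges=residual,
        positive_test_edges=removed,
        negative_test_edges=sorted(negatives),
        removal_fraction=fraction,
        patients=patients,
        doctors=doctors,
    )


def link_prediction_eval(
    split: LinkSplit,
    patient_emb: EmbeddingTable,
    doctor_emb: EmbeddingTable,
    seed: int = 0,
    folds: int = 5,
    C: float = DEFAULT_C,
) -> float:
    """Cross-validated ROC AUC of an LR on concatenated pair embeddings.

    The caller must have trained the embeddings on the residual graph only.
    """
    overlap = set(split.positive_test_edges) & set(split.negative_test_edges)
    if overlap:
        raise ContractError(f"positive/negative pair overlap: {sorted(overlap)[:3]}")
    pairs = split.positive_test_edges + split.negative_test_edges
    y = np.array([1] * len(split.positive_test_edges) + [0] * len(split.negative_test_edges))
    X = np.stack(
        [
            np.concatenate([patient_emb.vector(p), doctor_emb.vector(d)])
            for p, d in pairs
        ]
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_predict(_lr(seed, C), X, y, cv=cv, method="predict_proba")[:, 1]
    return float(roc_auc_score(y, scores))


def binary_outcome_eval(
    emb: EmbeddingTable,
    labels: dict[str, int],
    folds: int = 10,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> tuple[float, float]:
    """Stratified k-fold CV logistic regression; returns (PR-AUC, ROC-AUC)."""
    ids = [i for i in emb.ids if i in labels]
    X = emb.matrix(ids)
    y = np.array([int(labels[i]) for i in ids])
    if len(np.unique(y)) < 2:
        raise ParameterError("binary outcome evaluation needs both classes")
    # never let a fold end up single-class (AUC undefined)
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ParameterError("minority class too small for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pr, roc = [], []
    for train, test in cv.split(X, y):
        clf = _lr(seed, C).fit(X[train], y[train])
        scores = clf.predict_proba(X[test])[:, 1]
        pr.append(average_precision_score(y[test], scores))
        roc.append(roc_auc_score(y[test], scores))
    return float(np.mean(pr)), float(np.mean(roc))


def pca_project(emb: EmbeddingTable, k: int = 2) -> EmbeddingTable:
    """Mean-centered projection onto the top-k principal components."""
    if k > emb.dim:
        raise ParameterError(f"k={k} exceeds embedding dim {emb.dim}")
    if len(emb) < k:
        raise ParameterError(f"need at least {k} vectors for a {k}-D projection")
    pca = PCA(n_components=k, svd_solver="full")
    projected = pca.fit_transform(emb.vectors)
    return EmbeddingTable(ids=list(emb.ids), vectors=projected)
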