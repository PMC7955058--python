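"""Structural and planted-recovery checks runnable from scratch.

Each function here recomputes one verifiable property of the pipeline —
closed-form oracles, walk-law consistency, multigraph simplification
audits, and end-to-end recovery of planted synthetic structure — and
returns the measured quantities.  The test suite asserts on these numbers;
``scripts/acceptance.py`` prints them.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chisquare, spearmanr

from .doctor_embedding import (
    GatConfig,
    GatParams,
    attention_forward,
    build_doctor_service_graph,
    train_gat,
)
from .ehr_data import EmbeddingTable, JourneyTable
from .errors import Me2VecError
from .evaluation import (
    binary_outcome_eval,
    link_prediction_eval,
    link_prediction_split,
)
from .patient_embedding import (
    AnnotationParams,
    HybridBipartiteGraph,
    PatientEmbedConfig,
    PatientMultigraph,
    build_patient_multigraph,
    duplicate_annotate,
    exact_gradients,
    exact_patient_loss,
    train_patient_embeddings,
)
from .service_embedding import (
    SkipgramConfig,
    WalkConfig,
    simulate_walks,
    train_skipgram,
    transition_distribution,
)
from .service_graph import CooccurrenceGraph, build_cooccurrence
from .synthetic_ehr import SimConfig, generate_cohort

import scipy.sparse as sp


# ---------------------------------------------------------------------------
# toy multigraph: one service seen by two doctors, another seen twice by one


def duplication_toy() -> dict:
    """Worked toy: ECG administered by two distinct doctors must split into
    two hybrid nodes; a gene test administered twice via one doctor must not
    be duplicated.  Total edge weight is conserved."""
    edges = pd.DataFrame(
        [
            ("patA", "ECG", "doc1", 1),
            ("patB", "ECG", "doc2", 1),
            ("patA", "gene", "doc3", 1),
            ("patB", "gene", "doc3", 1),
        ],
        columns=["patient_id", "service_code", "doctor_id", "weight"],
    )
    mg = PatientMultigraph(patients=["patA", "patB"], edges=edges)
    hg = duplicate_annotate(mg)
    n_ecg = sum(1 for s, _ in hg.hybrids if s == "ECG")
    n_gene = sum(1 for s, _ in hg.hybrids if s == "gene")
    return {
        "n_ecg_hybrids": n_ecg,
        "n_gene_hybrids": n_gene,
        "total_weight_in": mg.total_weight,
        "total_weight_out": hg.total_weight,
    }


# ---------------------------------------------------------------------------
# closed-form oracles


def attention_normalization_error(n_cases: int = 100, seed: int = 0) -> float:
    """Max |sum(alpha) - 1| per head over random doctor neighborhoods."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        p = int(rng.integers(2, 17))
        heads = int(rng.integers(1, 5))
        p_head = int(rng.integers(1, 9))
        n = int(rng.integers(1, 12))
        params = GatParams(
            W=rng.normal(size=(heads, p_head, p)),
            a=rng.normal(size=(heads, 2 * p_head)),
            classifier_W=rng.normal(size=(3, heads * p_head)),
            classifier_b=np.zeros(3),
            classes=["a", "b", "c"],
        )
        _, alpha = attention_forward(rng.normal(size=p), rng.normal(size=(n, p)), params)
        worst = max(worst, float(np.abs(alpha.sum(axis=1) - 1.0).max()))
    return worst


def _reference_loss_double_loop(graph: HybridBipartiteGraph, P, H) -> float:
    """Independent double-loop softmax/KL computation (naive reference)."""
    total = 0.0
    for k, patient in enumerate(graph.patients):
        idx, w = graph.patient_edges(patient)
        denom = sum(math.exp(float(np.dot(P[k], H[l]))) for l in range(len(graph.hybrids)))
        wsum = float(w.sum())
        for pos, l in enumerate(idx):
            p_hat = float(w[pos]) / wsum
            p2 = math.exp(float(np.dot(P[k], H[l]))) / denom
            total -= p_hat * math.log(p2)
    return total


def random_hybrid_graph(
    rng: np.random.Generator,
    n_patients: int,
    n_services: int,
    n_doctors: int,
    edge_prob: float = 0.5,
) -> tuple[PatientMultigraph, HybridBipartiteGraph]:
    rows = []
    for k in range(n_patients):
        n_edges = 0
        while n_edges == 0:  # every patient needs >= 1 edge
            for s in range(n_services):
                for d in range(n_doctors):
                    if rng.random() < edge_prob:
                        rows.append((f"p{k}", f"s{s}", f"d{d}", int(rng.integers(1, 5))))
                        n_edges += 1
    edges = pd.DataFrame(
        rows, columns=["patient_id", "service_code", "doctor_id", "weight"]
    )
    mg = PatientMultigraph(patients=sorted({r[0] for r in rows}), edges=edges)
    return mg, duplicate_annotate(mg)


def exact_loss_max_deviation(n_graphs: int = 20, seed: int = 0) -> float:
    """Max |exact_patient_loss - naive double-loop| over random tiny graphs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        mg, hg = random_hybrid_graph(
            rng,
            n_patients=int(rng.integers(1, 4)),
            n_services=int(rng.integers(1, 4)),
            n_doctors=int(rng.integers(1, 3)),
        )
        dim = int(rng.integers(1, 5))
        P = rng.normal(scale=0.7, size=(len(hg.patients), dim))
        H = rng.normal(scale=0.7, size=(len(hg.hybrids), dim))
        worst = max(
            worst,
            abs(exact_patient_loss(hg, P, H) - _reference_loss_double_loop(hg, P, H)),
        )
    return worst


def _line_graph(weights: dict[tuple[str, str], int]) -> CooccurrenceGraph:
    services = sorted({a for a, _ in weights} | {b for _, b in weights})
    index = {s: i for i, s in enumerate(services)}
    n = len(services)
    adj = np.zeros((n, n), dtype=np.int64)
    for (a, b), w in weights.items():
        adj[index[a], index[b]] = w
        adj[index[b], index[a]] = w
    return CooccurrenceGraph(services=services, adjacency=sp.csr_array(adj), window_T=1)


def transition_fixture_errors() -> float:
    """Max deviation of transition probabilities from hand-computed values on
    path and triangle fixtures for p in {0.5, 1, 4} (q = 1/p paired)."""
    worst = 0.0
    path = _line_graph({("A", "B"): 1, ("B", "C"): 1})
    triangle = _line_graph({("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1})
    for p in (0.5, 1.0, 4.0):
        q = 1.0 / p
        cfg = WalkConfig(p=p, q=q)
        nbrs, probs = transition_distribution(path, "A", "B", cfg)
        expected = {"A": (1 / p) / (1 / p + 1 / q), "C": (1 / q) / (1 / p + 1 / q)}
        got = {path.services[i]: pr for i, pr in zip(nbrs, probs)}
        worst = max(worst, max(abs(got[s] - expected[s]) for s in expected))
        # triangle: C is adjacent to prev=A, so its factor is 1
        cfg1 = WalkConfig(p=p, q=1.0)
        nbrs, probs = transition_distribution(triangle, "A", "B", cfg1)
        expected = {"A": (1 / p) / (1 / p + 1), "C": 1 / (1 / p + 1)}
        got = {triangle.services[i]: pr for i, pr in zip(nbrs, probs)}
        worst = max(worst, max(abs(got[s] - expected[s]) for s in expected))
    return worst


# ---------------------------------------------------------------------------
# walk law


def walk_law_chisquare(seed: int = 0, min_steps: int = 10_000) -> dict:
    """Compare empirical next-step frequencies on a fixed 5-node weighted
    graph against the analytic transition distribution (second-order walk)."""
    graph = _line_graph(
        {
            ("A", "B"): 3,
            ("A", "C"): 1,
            ("B", "C"): 2,
            ("B", "D"): 1,
            ("C", "D"): 4,
            ("D", "E"): 2,
            ("C", "E"): 1,
        }
    )
    cfg = WalkConfig(p=2.0, q=0.5, num_walks=40, walk_length=70, seed=seed)
    walks = simulate_walks(graph, cfg)
    total_steps = sum(len(w) - 1 for w in walks)
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for walk in walks:
        for i in range(2, len(walk)):
            ctx = (walk[i - 2], walk[i - 1])
            counts.setdefault(ctx, {})[walk[i]] = counts.get(ctx, {}).get(walk[i], 0) + 1
    p_values = []
    stat_total, dof_total = 0.0, 0
    for (prev, curr), obs in counts.items():
        n_obs = sum(obs.values())
        if n_obs < 200:
            continue
        nbrs, probs = transition_distribution(graph, prev, curr, cfg)
        names = [graph.services[i] for i in nbrs]
        observed = np.array([obs.get(s, 0) for s in names], dtype=float)
        expected = probs * n_obs
        keep = expected >= 5
        if keep.sum() < 2:
            continue
        observed = np.append(observed[keep], observed[~keep].sum())
        expected = np.append(expected[keep], expected[~keep].sum())
        if expected[-1] == 0:
            observed, expected = observed[:-1], expected[:-1]
        res = chisquare(observed, expected)
        p_values.append(float(res.pvalue))
        stat_total += float(res.statistic)
        dof_total += len(observed) - 1
    combined_p = float(chi2_dist.sf(stat_total, dof_total))
    return {
        "total_steps": total_steps,
        "min_p": min(p_values),
        "combined_p": combined_p,
        "n_contexts": len(p_values),
    }


# ---------------------------------------------------------------------------
# structural audits


def duplication_audit(n_graphs: int = 50, seed: int = 0) -> dict:
    """Brute-force audit of the multigraph simplification on random inputs."""
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        mg, hg = random_hybrid_graph(
            rng,
            n_patients=int(rng.integers(1, 11)),
            n_services=int(rng.integers(1, 9)),
            n_doctors=int(rng.integers(1, 5)),
            edge_prob=float(rng.uniform(0.1, 0.6)),
        )
        expected_hybrids = {
            (s, d) for s, d in zip(mg.edges["service_code"], mg.edges["doctor_id"])
        }
        if set(hg.hybrids) != expected_hybrids:
            return {"ok": False, "reason": "hybrid set mismatch"}
        if hg.total_weight != mg.total_weight:
            return {"ok": False, "reason": "weight not conserved"}
        # simplicity: csr holds one stored entry per (patient, hybrid)
        coo = hg.weights.tocoo()
        pairs = list(zip(coo.coords[0].tolist(), coo.coords[1].tolist()))
        if len(pairs) != len(set(pairs)):
            return {"ok": False, "reason": "parallel edges survived"}
    return {"ok": True, "n_graphs": n_graphs}


def link_split_audit(n_graphs: int = 20, seed: int = 0) -> dict:
    """Audit every LinkSplit invariant on random bipartite graphs."""
    rng = np.random.default_rng(seed)
    checked = 0
    for g in range(n_graphs):
        n_p, n_d = int(rng.integers(15, 40)), int(rng.integers(10, 30))
        edges = {
            (f"p{i}", f"d{rng.integers(n_d)}") for i in range(n_p)
        }  # ensure every patient has an edge
        target = int(rng.integers(3 * n_p, 6 * n_p))
        while len(edges) < target:
            edges.add((f"p{rng.integers(n_p)}", f"d{rng.integers(n_d)}"))
        edges = sorted(edges)
        try:
            split = link_prediction_split(edges, 0.1, seed=seed + g)
        except Me2VecError:
            continue  # quota unreachable on this draw; not an invariant breach
        quota = int(round(0.1 * len(edges)))
        edge_set = set(edges)
        pos = set(split.positive_test_edges)
        neg = set(split.negative_test_edges)
        res = set(split.residual_edges)
        assert len(pos) == quota and len(neg) == quota
        assert not (pos & res) and not (neg & edge_set) and not (pos & neg)
        assert res | pos == edge_set
        _assert_components_preserved(edges, split.residual_edges)
        checked += 1
    return {"ok": True, "n_checked": checked}


def _assert_components_preserved(original, residual) -> None:
    import networkx as nx

    g0, g1 = nx.Graph(), nx.Graph()
    g0.add_edges_from((("p", p), ("d", d)) for p, d in original)
    g1.add_nodes_from(g0.nodes)
    g1.add_edges_from((("p", p), ("d", d)) for p, d in residual)
    comp0 = {frozenset(c) for c in nx.connected_components(g0)}
    comp1 = {frozenset(c) for c in nx.connected_components(g1)}
    assert comp0 == comp1, "residual graph changed the component structure"


# ---------------------------------------------------------------------------
# planted-structure recovery (the synthetic end-to-end battery)


def planted_cohort_battery(seed: int = 0) -> dict:
    """Train the full hierarchy on a 500-patient planted cohort and measure
    every recovery statistic in one pass."""
    sim = SimConfig(
        n_patients=500,
        n_doctors=50,
        n_services=100,
        n_specialties=5,
        n_conditions=5,
        services_per_patient_mean=30.0,
        seed=seed,
    )
    journeys, truth = generate_cohort(sim)
    graph = build_cooccurrence(journeys, T=8)
    walks = simulate_walks(
        graph, WalkConfig(num_walks=10, walk_length=40, seed=seed)
    )
    service_emb = train_skipgram(
        walks,
        SkipgramConfig(dim=128, epochs=8, batch_size=128, seed=seed),
        vocabulary=graph.services,
    )

    # (c) spatial isolation: frequency vs distance to centroid
    freq = journeys.frame["service_code"].value_counts()
    f = np.array([freq.get(s, 0) for s in service_emb.ids])
    centroid = service_emb.vectors.mean(axis=0)
    dist = np.linalg.norm(service_emb.vectors - centroid, axis=1)
    spatial_rho = float(spearmanr(f, dist).statistic)

    # (a) specialty recovery vs permutation null
    doc_graph = build_doctor_service_graph(journeys)
    _, _, report = train_gat(
        doc_graph, service_emb, GatConfig(seed=seed, epochs=300)
    )
    doctor_emb, _, _ = train_gat(
        doc_graph, service_emb, GatConfig(seed=seed, epochs=300, val_fraction=0.0)
    )
    permuted = _permuted_label_accuracy(doc_graph, service_emb, seed)

    # (b) specialty cosine separation
    V = doctor_emb.vectors / np.linalg.norm(doctor_emb.vectors, axis=1, keepdims=True)
    spec = np.array([truth.doctor_specialty[d] for d in doctor_emb.ids])
    sims = V @ V.T
    same = spec[:, None] == spec[None, :]
    off_diag = ~np.eye(len(V), dtype=bool)
    within = float(sims[same & off_diag].mean())
    between = float(sims[~same].mean())

    # patient embeddings on the full graph for the outcome check
    hybrid_graph = duplicate_annotate(build_patient_multigraph(journeys))
    patient_emb, _ = train_patient_embeddings(
        hybrid_graph,
        service_emb,
        doctor_emb,
        PatientEmbedConfig(dim=128, negatives=10, epochs=20, seed=seed),
    )

    # (e) outcome signal vs shuffled-label controls
    labels = {p: int(v) for p, v in truth.patient_label.items()}
    _, roc = binary_outcome_eval(patient_emb, labels, folds=10, seed=seed)
    rng = np.random.default_rng(seed)
    ids = list(labels)
    vals = np.array([labels[i] for i in ids])
    shuffled_rocs = []
    for _ in range(10):
        perm = rng.permutation(len(vals))
        shuffled = {i: int(v) for i, v in zip(ids, vals[perm])}
        _, r = binary_outcome_eval(patient_emb, shuffled, folds=10, seed=seed)
        shuffled_rocs.append(r)

    # (d) link prediction on a planted-block bipartite graph
    link = planted_block_link_auc(seed)

    return {
        "specialty_holdout_accuracy": report["val_accuracy"],
        "specialty_permuted_accuracy": permuted,
        "doctor_cosine_within": within,
        "doctor_cosine_between": between,
        "spatial_isolation_spearman": spatial_rho,
        "outcome_roc_auc": roc,
        "outcome_roc_auc_shuffled": shuffled_rocs,
        "link_auc": link["auc"],
        "link_auc_random": link["auc_random"],
        "n_patients": sim.n_patients,
        "n_doctors": sim.n_doctors,
        "n_services": sim.n_services,
    }


def _permuted_label_accuracy(doc_graph, service_emb, seed: int) -> float:
    rng = np.random.default_rng(seed + 1)
    doctors = list(doc_graph.doctors)
    labels = [doc_graph.specialty[d] for d in doctors]
    permuted = dict(zip(doctors, rng.permutation(labels)))
    shuffled_graph = replace(doc_graph, specialty=permuted)
    _, _, report = train_gat(
        shuffled_graph,
        service_emb,
        GatConfig(seed=seed, epochs=60, val_fraction=0.4, patience=10),
    )
    return report["val_accuracy"]


def planted_block_link_auc(
    seed: int = 0,
    n_blocks: int = 4,
    patients_per_block: int = 25,
    doctors_per_block: int = 8,
    p_within: float = 0.3,
    p_between: float = 0.01,
) -> dict:
    """Link prediction on a block-structured patient-doctor graph.

    Journeys are materialized from the sampled edges (one row per edge with a
    block-specific service), patient/doctor embeddings are trained on the
    residual graph only, and the split is scored; random embeddings provide
    the chance-level reference.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_blocks):
        for i in range(patients_per_block):
            pid = f"p{b}_{i}"
            degree = 0
            while degree == 0:
                for b2 in range(n_blocks):
                    prob = p_within if b2 == b else p_between
                    for jd in range(doctors_per_block):
                        if rng.random() < prob:
                            did = f"d{b2}_{jd}"
                            svc = f"s{b2}_{rng.integers(3)}"
                            rows.append((pid, did, f"spec{b2}", svc, int(rng.integers(30))))
                            degree += 1
    journeys = JourneyTable(
        pd.DataFrame(
            rows, columns=["patient_id", "doctor_id", "specialty", "service_code", "date"]
        )
    )
    edges = sorted(set(zip(journeys.frame["patient_id"], journeys.frame["doctor_id"])))
    split = link_prediction_split(edges, 0.1, seed=seed)

    removed = set(split.positive_test_edges)
    keep = [
        (p, d) not in removed
        for p, d in zip(journeys.frame["patient_id"], journeys.frame["doctor_id"])
    ]
    residual = JourneyTable(journeys.frame[keep].reset_index(drop=True))

    graph = build_cooccurrence(residual, T=8)
    service_emb = train_skipgram(
        simulate_walks(graph, WalkConfig(num_walks=10, walk_length=20, seed=seed)),
        SkipgramConfig(dim=32, epochs=5, seed=seed),
        vocabulary=graph.services,
    )
    doc_graph = build_doctor_service_graph(residual)
    doctor_emb, _, _ = train_gat(
        doc_graph, service_emb, GatConfig(heads=4, epochs=120, seed=seed, val_fraction=0.0)
    )
    hybrid_graph = duplicate_annotate(build_patient_multigraph(residual))
    patient_emb, ann_params = train_patient_embeddings(
        hybrid_graph,
        service_emb,
        doctor_emb,
        PatientEmbedConfig(dim=32, negatives=10, epochs=40, seed=seed),
    )
    auc = link_prediction_eval(split, patient_emb, doctor_emb, seed=seed)

    rng2 = np.random.default_rng(seed + 99)
    rand_pat = EmbeddingTable(patient_emb.ids, rng2.normal(size=patient_emb.vectors.shape))
    rand_doc = EmbeddingTable(doctor_emb.ids, rng2.normal(size=doctor_emb.vectors.shape))
    auc_random = link_prediction_eval(split, rand_pat, rand_doc, seed=seed)

    # diagnostic: the model-native bilinear score p . h(s, d) expresses the
    # block-match interaction that concatenated features cannot (see ledger)
    auc_bilinear = _bilinear_auc(
        split, hybrid_graph, patient_emb, service_emb, doctor_emb, ann_params
    )
    return {
        "auc": auc,
        "auc_random": auc_random,
        "auc_bilinear": auc_bilinear,
        "n_test_pairs": 2 * len(removed),
    }


def _bilinear_auc(
    split, hybrid_graph, patient_emb, service_emb, doctor_emb, ann_params
) -> float:
    from sklearn.metrics import roc_auc_score

    from .patient_embedding import hybrid_vectors as make_hybrid_vectors

    hvecs = make_hybrid_vectors(
        hybrid_graph.hybrids, service_emb, doctor_emb, ann_params
    )
    by_doctor: dict[str, list[np.ndarray]] = {}
    for (s, d), hid in zip(hybrid_graph.hybrids, hvecs.ids):
        by_doctor.setdefault(d, []).append(hvecs.vector(hid))
    centroids = {d: np.mean(v, axis=0) for d, v in by_doctor.items()}
    pairs = split.positive_test_edges + split.negative_test_edges
    y = [1] * len(split.positive_test_edges) + [0] * len(split.negative_test_edges)
    scores = [float(patient_emb.vector(p) @ centroids[d]) for p, d in pairs]
    return float(roc_auc_score(y, scores))


# ---------------------------------------------------------------------------
# descent on the exact objective


def exact_descent_losses(seed: int = 0, steps: int = 25, lr: float = 0.05) -> list[float]:
    """Full-batch gradient descent on the exact objective for a 3-patient /
    4-hybrid toy; returns the loss trajectory."""
    rng = np.random.default_rng(seed)
    edges = pd.DataFrame(
        [
            ("p0", "s0", "d0", 2),
            ("p0", "s1", "d0", 1),
            ("p1", "s1", "d1", 3),
            ("p1", "s0", "d1", 1),
            ("p2", "s0", "d0", 1),
            ("p2", "s1", "d1", 1),
        ],
        columns=["patient_id", "service_code", "doctor_id", "weight"],
    )
    mg = PatientMultigraph(patients=["p0", "p1", "p2"], edges=edges)
    hg = duplicate_annotate(mg)
    assert len(hg.hybrids) == 4
    dim, feat_dim = 6, 8
    X = rng.normal(size=(len(hg.hybrids), feat_dim))
    P = rng.normal(scale=0.3, size=(len(hg.patients), dim))
    params = AnnotationParams(
        W_a=rng.normal(scale=0.3, size=(dim, feat_dim)), b_a=np.zeros(dim)
    )
    losses = []
    for _ in range(steps):
        loss, gP, gW, gb = exact_gradients(hg, P, X, params)
        losses.append(loss)
        P -= lr * gP
        params.W_a -= lr * gW
        params.b_a -= lr * gb
    losses.append(exact_gradients(hg, P, X, params)[0])
    return losses


# ---------------------------------------------------------------------------
# bitwise reproducibility


def reproducibility_check(base_dir, seed: int = 0) -> dict:
    """Run the full pipeline twice with one config; compare artifact hashes."""
    from .pipeline import RunConfig, run_pipeline

    small = dict(
        n_patients=80,
        n_doctors=12,
        n_services=30,
        n_specialties=3,
        services_per_patient_mean=15.0,
        dim=32,
        heads=4,
        num_walks=4,
        walk_length=20,
        sg_epochs=2,
        gat_epochs=40,
        patient_epochs=5,
        seed=seed,
    )
    m1 = run_pipeline(RunConfig(out_dir=str(base_dir / "run1"), **small))
    m2 = run_pipeline(RunConfig(out_dir=str(base_dir / "run2"), **small))
    h1 = {s["stage"]: s["output_hashes"] for s in m1["stages"]}
    h2 = {s["stage"]: s["output_hashes"] for s in m2["stages"]}
    return {"identical": h1 == h2, "stages": sorted(h1)}
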