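import math

import numpy as np
import pandas as pd
import pytest

from me2vec import (
    AnnotationParams,
    EmbeddingTable,
    PatientEmbedConfig,
    PatientMultigraph,
    build_patient_multigraph,
    duplicate_annotate,
    empirical_context,
    exact_patient_loss,
    hybrid_vectors,
    train_patient_embeddings,
)
from me2vec.errors import ContractError, Me2VecError, ParameterError
from me2vec.patient_embedding import exact_gradients, hybrid_features, negative_sampling_gradients

from conftest import make_journeys

EDGE_COLUMNS = ["patient_id", "service_code", "doctor_id", "weight"]


def mg_from(rows):
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return PatientMultigraph(patients=sorted({r[0] for r in rows}), edges=edges)


class TestMultigraph:
    def test_weights_count_rows(self):
        journeys = make_journeys(
            [
                ("p1", "d1", "x", "sA", 0),
                ("p1", "d1", "x", "sA", 1),
                ("p1", "d2", "x", "sA", 2),
            ]
        )
        mg = build_patient_multigraph(journeys)
        rows = {
            (r.service_code, r.doctor_id): r.weight for r in mg.edges.itertuples()
        }
        assert rows == {("sA", "d1"): 2, ("sA", "d2"): 1}

    def test_single_row_single_edge(self):
        mg = build_patient_multigraph(make_journeys([("p1", "d1", "x", "sA", 0)]))
        assert len(mg.edges) == 1 and mg.total_weight == 1

    def test_total_weight_equals_row_count(self, small_cohort):
        journeys, _ = small_cohort
        assert build_patient_multigraph(journeys).total_weight == len(journeys)

    def test_duplicate_edge_rejected(self):
        with pytest.raises(Me2VecError):
            mg_from([("p1", "sA", "d1", 1), ("p1", "sA", "d1", 2)])


class TestDuplicateAnnotate:
    def test_service_split_per_doctor_attribute(self):
        mg = mg_from(
            [
                ("p1", "ECG", "d1", 1),
                ("p2", "ECG", "d2", 1),
                ("p1", "gene", "d3", 1),
                ("p2", "gene", "d3", 1),
            ]
        )
        hg = duplicate_annotate(mg)
        assert sum(s == "ECG" for s, _ in hg.hybrids) == 2
        assert sum(s == "gene" for s, _ in hg.hybrids) == 1
        assert hg.total_weight == mg.total_weight

    def test_single_doctor_services_not_duplicated(self):
        mg = mg_from(
            [("p1", "sA", "d1", 2), ("p2", "sA", "d1", 1), ("p1", "sB", "d1", 1)]
        )
        hg = duplicate_annotate(mg)
        assert len(hg.hybrids) == 2  # one per distinct service

    @pytest.mark.parametrize("seed", range(5))
    def test_random_multigraph_against_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(int(rng.integers(1, 10))):
            for _ in range(int(rng.integers(1, 8))):
                rows.append(
                    (
                        f"p{k}",
                        f"s{rng.integers(8)}",
                        f"d{rng.integers(4)}",
                        int(rng.integers(1, 5)),
                    )
                )
        frame = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        frame = frame.groupby(EDGE_COLUMNS[:3], as_index=False)["weight"].sum()
        mg = PatientMultigraph(
            patients=sorted(frame["patient_id"].unique()), edges=frame
        )
        hg = duplicate_annotate(mg)
        assert set(hg.hybrids) == set(
            zip(frame["service_code"], frame["doctor_id"])
        )
        assert hg.total_weight == mg.total_weight


class TestHybridVectors:
    def test_projection_identity(self, rng):
        svc = EmbeddingTable(["sA"], rng.normal(size=(1, 3)))
        doc = EmbeddingTable(["d1"], rng.normal(size=(1, 3)))
        params = AnnotationParams(
            W_a=np.hstack([np.eye(3), np.zeros((3, 3))]), b_a=np.zeros(3)
        )
        out = hybrid_vectors([("sA", "d1")], svc, doc, params)
        np.testing.assert_allclose(out.vectors[0], svc.vector("sA"))

    def test_bias_only(self, rng):
        svc = EmbeddingTable(["sA", "sB"], rng.normal(size=(2, 2)))
        doc = EmbeddingTable(["d1"], rng.normal(size=(1, 2)))
        b = rng.normal(size=4)
        params = AnnotationParams(W_a=np.zeros((4, 4)), b_a=b)
        out = hybrid_vectors([("sA", "d1"), ("sB", "d1")], svc, doc, params)
        np.testing.assert_allclose(out.vectors, np.tile(b, (2, 1)))

    def test_matches_matrix_arithmetic(self, rng):
        svc = EmbeddingTable(["sA", "sB"], rng.normal(size=(2, 3)))
        doc = EmbeddingTable(["d1", "d2"], rng.normal(size=(2, 2)))
        params = AnnotationParams(W_a=rng.normal(size=(4, 5)), b_a=rng.normal(size=4))
        hybrids = [("sA", "d2"), ("sB", "d1")]
        out = hybrid_vectors(hybrids, svc, doc, params)
        for i, (s, d) in enumerate(hybrids):
            x = np.concatenate([svc.vector(s), doc.vector(d)])
            np.testing.assert_allclose(out.vectors[i], params.W_a @ x + params.b_a)

    def test_missing_entity_named(self, rng):
        svc = EmbeddingTable(["sA"], rng.normal(size=(1, 2)))
        doc = EmbeddingTable(["d1"], rng.normal(size=(1, 2)))
        params = AnnotationParams(W_a=np.zeros((2, 4)), b_a=np.zeros(2))
        with pytest.raises(Me2VecError, match="ghost"):
            hybrid_vectors([("ghost", "d1")], svc, doc, params)


class TestEmpiricalContext:
    def test_symmetric_weights(self):
        hg = duplicate_annotate(mg_from([("p1", "sA", "d1", 2), ("p1", "sB", "d1", 2)]))
        _, probs = empirical_context(hg, "p1")
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_single_neighbor(self):
        hg = duplicate_annotate(mg_from([("p1", "sA", "d1", 7)]))
        _, probs = empirical_context(hg, "p1")
        np.testing.assert_allclose(probs, [1.0])

    def test_one_two_three(self):
        hg = duplicate_annotate(
            mg_from(
                [("p1", "sA", "d1", 1), ("p1", "sB", "d1", 2), ("p1", "sC", "d1", 3)]
            )
        )
        idx, probs = empirical_context(hg, "p1")
        got = {hg.hybrids[i][0]: p for i, p in zip(idx, probs)}
        assert got == pytest.approx({"sA": 1 / 6, "sB": 1 / 3, "sC": 1 / 2})
        assert abs(probs.sum() - 1.0) <= 1e-12

    def test_unknown_patient_rejected(self):
        hg = duplicate_annotate(mg_from([("p1", "sA", "d1", 1)]))
        with pytest.raises(KeyError):
            empirical_context(hg, "p9")


class TestExactLoss:
    def test_zero_embeddings_closed_form(self):
        hg = duplicate_annotate(
            mg_from(
                [("p1", "sA", "d1", 1), ("p1", "sB", "d1", 2), ("p2", "sA", "d1", 3)]
            )
        )
        n_h = len(hg.hybrids)
        P = np.zeros((2, 4))
        H = np.zeros((n_h, 4))
        assert exact_patient_loss(hg, P, H) == pytest.approx(2 * math.log(n_h))

    def test_single_patient_single_hybrid_zero(self):
        hg = duplicate_annotate(mg_from([("p1", "sA", "d1", 5)]))
        assert exact_patient_loss(hg, np.ones((1, 3)), np.ones((1, 3))) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            (
                f"p{k}",
                f"s{rng.integers(3)}",
                f"d{rng.integers(2)}",
                int(rng.integers(1, 4)),
            )
            for k in range(3)
            for _ in range(int(rng.integers(1, 4)))
        ]
        frame = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        frame = frame.groupby(EDGE_COLUMNS[:3], as_index=False)["weight"].sum()
        mg = PatientMultigraph(sorted(frame["patient_id"].unique()), frame)
        hg = duplicate_annotate(mg)
        P = rng.normal(size=(len(hg.patients), 3))
        H = rng.normal(size=(len(hg.hybrids), 3))

        # naive reference: explicit loops, math.exp/log only
        ref = 0.0
        for k, patient in enumerate(hg.patients):
            idx, w = hg.patient_edges(patient)
            denom = sum(math.exp(float(P[k] @ H[l])) for l in range(len(hg.hybrids)))
            for pos, l in enumerate(idx):
                p2 = math.exp(float(P[k] @ H[l])) / denom
                ref -= (float(w[pos]) / float(w.sum())) * math.log(p2)
        assert exact_patient_loss(hg, P, H) == pytest.approx(ref, abs=1e-9)

    def test_entropy_lower_bound(self, rng):
        hg = duplicate_annotate(
            mg_from(
                [
                    ("p1", "sA", "d1", 1),
                    ("p1", "sB", "d2", 4),
                    ("p2", "sA", "d2", 2),
                    ("p2", "sB", "d1", 2),
                ]
            )
        )
        P = rng.normal(size=(2, 5))
        H = rng.normal(size=(len(hg.hybrids), 5))
        entropy = 0.0
        for patient in hg.patients:
            _, probs = empirical_context(hg, patient)
            entropy -= float((probs * np.log(probs)).sum())
        assert exact_patient_loss(hg, P, H) >= entropy - 1e-12

    def test_nonfinite_rejected(self):
        hg = duplicate_annotate(mg_from([("p1", "sA", "d1", 1)]))
        with pytest.raises(Me2VecError):
            exact_patient_loss(hg, np.array([[1e400 - 1e400]]), np.ones((1, 1)))


class TestTraining:
    @pytest.fixture
    def toy_setup(self, rng):
        rows = [
            ("p0", "s0", "d0", 2),
            ("p0", "s1", "d0", 1),
            ("p1", "s1", "d1", 3),
            ("p1", "s0", "d1", 1),
            ("p2", "s0", "d0", 1),
            ("p2", "s1", "d1", 1),
        ]
        hg = duplicate_annotate(mg_from(rows))
        svc = EmbeddingTable(["s0", "s1"], rng.normal(size=(2, 4)))
        doc = EmbeddingTable(["d0", "d1"], rng.normal(size=(2, 4)))
        return hg, svc, doc

    def test_exact_mode_descends(self, toy_setup):
        hg, svc, doc = toy_setup
        X = hybrid_features(hg.hybrids, svc, doc)
        rng = np.random.default_rng(1)
        P = rng.normal(scale=0.3, size=(len(hg.patients), 6))
        params = AnnotationParams(W_a=rng.normal(scale=0.3, size=(6, 8)), b_a=np.zeros(6))
        losses = []
        for _ in range(20):
            loss, gP, gW, gb = exact_gradients(hg, P, X, params)
            losses.append(loss)
            P -= 0.05 * gP
            params.W_a -= 0.05 * gW
            params.b_a -= 0.05 * gb
        assert all(b < a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_exact_gradient_matches_finite_differences(self, toy_setup):
        hg, svc, doc = toy_setup
        X = hybrid_features(hg.hybrids, svc, doc)
        rng = np.random.default_rng(2)
        P = rng.normal(scale=0.4, size=(len(hg.patients), 3))
        params = AnnotationParams(W_a=rng.normal(scale=0.4, size=(3, 8)), b_a=rng.normal(size=3))
        loss0, gP, gW, gb = exact_gradients(hg, P, X, params)
        eps = 1e-6
        for idx in [(0, 1), (2, 2)]:
            P2 = P.copy()
            P2[idx] += eps
            lp = exact_gradients(hg, P2, X, params)[0]
            assert (lp - loss0) / eps == pytest.approx(gP[idx], rel=1e-4, abs=1e-6)
        W2 = AnnotationParams(W_a=params.W_a.copy(), b_a=params.b_a.copy())
        W2.W_a[1, 3] += eps
        lw = exact_gradients(hg, P, X, W2)[0]
        assert (lw - loss0) / eps == pytest.approx(gW[1, 3], rel=1e-4, abs=1e-6)

    def test_sampled_gradient_consistent_with_exact_direction(self, rng):
        """Averaged noise-contrastive gradients stay within 15 degrees of the
        exact-objective gradient on a tiny graph in the regime where the two
        objectives agree: equal hybrid degrees (noise = softmax's uniform
        normalizer), one negative per edge, embeddings near zero."""
        # unequal per-patient weights (3:1) keep the leading gradient term
        # nonzero; equal hybrid degrees keep the noise distribution uniform
        rows = [
            ("p0", "s0", "d0", 3),
            ("p0", "s1", "d1", 1),
            ("p1", "s1", "d1", 3),
            ("p1", "s1", "d0", 1),
            ("p2", "s1", "d0", 3),
            ("p2", "s0", "d1", 1),
            ("p3", "s0", "d1", 3),
            ("p3", "s0", "d0", 1),
        ]
        hg = duplicate_annotate(mg_from(rows))
        svc = EmbeddingTable(["s0", "s1"], rng.normal(size=(2, 4)))
        doc = EmbeddingTable(["d0", "d1"], rng.normal(size=(2, 4)))
        X = hybrid_features(hg.hybrids, svc, doc)
        P = rng.normal(scale=0.02, size=(len(hg.patients), 4))
        params = AnnotationParams(
            W_a=rng.normal(scale=0.2, size=(4, 8)), b_a=np.zeros(4)
        )
        _, gP_exact, _, _ = exact_gradients(hg, P, X, params)

        coo = hg.weights.tocoo()
        edge_pat, edge_hyb = coo.coords
        edge_w = coo.data.astype(float)
        edge_probs = edge_w / edge_w.sum()
        degree = np.asarray(hg.weights.sum(axis=0)).reshape(-1).astype(float)
        noise = degree**0.75
        noise /= noise.sum()
        acc = np.zeros_like(P)
        n_draws = 8000
        for _ in range(n_draws):
            e = rng.choice(len(edge_w), p=edge_probs)
            neg = rng.choice(len(noise), size=(1, 1), p=noise)
            _, gP, _, _ = negative_sampling_gradients(
                P, X, params, edge_pat[[e]], edge_hyb[[e]], neg
            )
            acc += gP
        acc /= n_draws
        ge = gP_exact.ravel()
        gs = acc.ravel()
        cosine = float(ge @ gs / (np.linalg.norm(ge) * np.linalg.norm(gs)))
        assert cosine >= math.cos(math.radians(15.0))

    def test_two_block_recovery(self, rng):
        rows = []
        for k in range(6):
            block = "A" if k < 3 else "B"
            for s in range(3):
                rows.append((f"p{k}", f"s{block}{s}", f"d{block}", int(rng.integers(1, 4))))
        hg = duplicate_annotate(mg_from(rows))
        svc_ids = sorted({r[1] for r in rows})
        svc = EmbeddingTable(svc_ids, rng.normal(size=(len(svc_ids), 6)))
        doc = EmbeddingTable(["dA", "dB"], rng.normal(size=(2, 6)))
        emb, _ = train_patient_embeddings(
            hg, svc, doc, PatientEmbedConfig(dim=8, negatives=5, epochs=300, seed=4)
        )
        V = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
        sims = V @ V.T
        blocks = np.array([p < "p3" for p in emb.ids])
        same = blocks[:, None] == blocks[None, :]
        off = ~np.eye(len(V), dtype=bool)
        assert sims[same & off].mean() > sims[~same].mean()

    def test_zero_epochs_returns_seeded_init(self, toy_setup):
        hg, svc, doc = toy_setup
        cfg = PatientEmbedConfig(dim=5, epochs=0, seed=8)
        e1, _ = train_patient_embeddings(hg, svc, doc, cfg)
        e2, _ = train_patient_embeddings(hg, svc, doc, cfg)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_zero_negatives_rejected_in_sampled_mode(self):
        with pytest.raises(ParameterError):
            PatientEmbedConfig(negatives=0, exact=False)

    def test_patient_similarity_scenarios(self, rng):
        """Same (service, doctor) > same service/different doctor > nothing,
        averaged over three replicas of each patient role."""
        rows = []
        for r in range(3):
            rows += [
                (f"pa{r}", "sX", "d1", 3),  # reference
                (f"pb{r}", "sX", "d1", 3),  # shares service AND doctor
                (f"pc{r}", "sX", "d2", 3),  # shares only the service
                (f"pd{r}", "sZ", "d3", 3),  # shares nothing
                (f"pa{r}", "sY", "d1", 1),
                (f"pb{r}", "sY", "d1", 1),
                (f"pc{r}", "sY", "d2", 1),
                (f"pd{r}", "sW", "d3", 1),
            ]
        hg = duplicate_annotate(mg_from(rows))
        svc = EmbeddingTable(["sW", "sX", "sY", "sZ"], rng.normal(size=(4, 6)))
        # doctors sharing a service are near each other in the hierarchy:
        # d2 administers the same services as d1, d3 is unrelated
        base = rng.normal(size=6)
        doc = EmbeddingTable(
            ["d1", "d2", "d3"],
            np.stack([base, base + 0.3 * rng.normal(size=6), rng.normal(size=6)]),
        )
        emb, _ = train_patient_embeddings(
            hg, svc, doc, PatientEmbedConfig(dim=8, negatives=5, epochs=100, seed=1)
        )

        def cos(a, b):
            x, y = emb.vector(a), emb.vector(b)
            return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))

        ab = np.mean([cos(f"pa{i}", f"pb{j}") for i in range(3) for j in range(3)])
        ac = np.mean([cos(f"pa{i}", f"pc{j}") for i in range(3) for j in range(3)])
        ad = np.mean([cos(f"pa{i}", f"pd{j}") for i in range(3) for j in range(3)])
        assert ab > ac > ad
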