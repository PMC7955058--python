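import numpy as np
import pandas as pd
import pytest

from me2vec import (
    GatConfig,
    JourneyTable,
    SimConfig,
    SkipgramConfig,
    WalkConfig,
    build_cooccurrence,
    build_doctor_service_graph,
    generate_cohort,
    simulate_walks,
    train_gat,
    train_skipgram,
)

COLUMNS = ["patient_id", "doctor_id", "specialty", "service_code", "date"]


def make_journeys(rows):
    """rows: iterable of (patient, doctor, specialty, service, day)."""
    return JourneyTable(pd.DataFrame(list(rows), columns=COLUMNS))


@pytest.fixture
def tiny_journeys():
    return make_journeys(
        [
            ("p1", "d1", "cardio", "svcA", 0),
            ("p1", "d1", "cardio", "svcB", 3),
            ("p1", "d2", "onco", "svcC", 10),
            ("p2", "d2", "onco", "svcA", 1),
            ("p2", "d2", "onco", "svcC", 2),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(
        n_patients=150,
        n_doctors=20,
        n_services=40,
        n_specialties=4,
        n_conditions=4,
        services_per_patient_mean=20.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def mid_cohort():
    """Cohort sized for the statistical examples (Poisson mean, Zipf slope)."""
    cfg = SimConfig(n_patients=500, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_service_emb(small_cohort):
    journeys, _ = small_cohort
    graph = build_cooccurrence(journeys, T=8)
    walks = simulate_walks(graph, WalkConfig(num_walks=6, walk_length=25, seed=7))
    emb = train_skipgram(
        walks, SkipgramConfig(dim=32, epochs=4, seed=7), vocabulary=graph.services
    )
    return graph, emb


@pytest.fixture(scope="session")
def trained_gat(small_cohort, small_service_emb):
    journeys, truth = small_cohort
    _, service_emb = small_service_emb
    graph = build_doctor_service_graph(journeys)
    emb, params, report = train_gat(
        graph, service_emb, GatConfig(heads=4, epochs=120, seed=7, val_fraction=0.25)
    )
    return graph, emb, params, report


@pytest.fixture
def rng():
    return np.random.default_rng(0)
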