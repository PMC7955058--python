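"""End-to-end pipeline: simulate -> service graph -> service/doctor/patient
embeddings -> evaluations, with per-stage derived seeds and a run manifest.

Stages execute in the hierarchical order of the method (services first, then
doctors, finally patients).  In deterministic mode a rerun with the same
config and seed reproduces every embedding file bitwise.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .doctor_embedding import GatConfig, build_doctor_service_graph, train_gat
from .ehr_data import (
    read_embeddings,
    read_journeys,
    write_embeddings,
    write_journeys,
)
from .errors import DependencyError
from .evaluation import (
    binary_outcome_eval,
    link_prediction_eval,
    link_prediction_split,
    node_classification_eval,
)
from .patient_embedding import (
    PatientEmbedConfig,
    build_patient_multigraph,
    duplicate_annotate,
    train_patient_embeddings,
    write_hybrid_vocabulary,
)
from .service_embedding import SkipgramConfig, WalkConfig, embed_services
from .service_graph import build_cooccurrence, graph_density, write_cooccurrence
from .synthetic_ehr import SimConfig, generate_cohort, write_ground_truth

STAGES = (
    "simulate",
    "build-graph",
    "embed-service",
    "embed-doctor",
    "embed-patient",
    "eval-nodes",
    "eval-links",
)


@dataclass
class RunConfig:
    out_dir: str = "me2vec_run"
    seed: int = 0
    deterministic: bool = True
    # cohort
    n_patients: int = 500
    n_doctors: int = 50
    n_services: int = 100
    n_specialties: int = 5
    n_conditions: int = 5
    services_per_patient_mean: float = 30.0
    # model hyperparameters (defaults follow the experimental setup)
    window_T: int = 8
    dim: int = 128
    negatives: int = 10
    heads: int = 4
    p: float = 1.0
    q: float = 1.0
    num_walks: int = 10
    walk_length: int = 80
    sg_window: int = 5
    sg_epochs: int = 5
    gat_epochs: int = 150
    patient_epochs: int = 20
    link_fraction: float = 0.1
    stages: list[str] = field(default_factory=lambda: list(STAGES))


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed by stage-name hashing."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing upstream artifact for this stage: {what} ({path})")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "stages": []}
    requested = [s for s in STAGES if s in config.stages]

    paths = {
        "journeys": out / "journeys.csv",
        "truth": out / "ground_truth.csv",
        "svc_edges": out / "service_graph.tsv",
        "svc_vocab": out / "service_vocab.txt",
        "svc_emb": out / "service.vec",
        "doc_emb": out / "doctor.vec",
        "pat_emb": out / "patient.vec",
        "hybrids": out / "hybrid_vocab.tsv",
        "nodes_report": out / "node_classification.json",
        "links_report": out / "link_prediction.json",
    }

    for stage in requested:
        t0 = time.perf_counter()
        outputs: list[Path] = []
        if stage == "simulate":
            sim = SimConfig(
                n_patients=config.n_patients,
                n_doctors=config.n_doctors,
                n_services=config.n_services,
                n_specialties=config.n_specialties,
                n_conditions=config.n_conditions,
                services_per_patient_mean=config.services_per_patient_mean,
                seed=stage_seed(config.seed, "simulate"),
            )
            journeys, truth = generate_cohort(sim)
            write_journeys(journeys, paths["journeys"])
            write_ground_truth(truth, paths["truth"])
            outputs = [paths["journeys"], paths["truth"]]
        elif stage == "build-graph":
            journeys = read_journeys(_require(paths["journeys"], "journey table"))
            graph = build_cooccurrence(journeys, config.window_T)
            write_cooccurrence(graph, paths["svc_edges"], paths["svc_vocab"])
            outputs = [paths["svc_edges"], paths["svc_vocab"]]
        elif stage == "embed-service":
            from .service_graph import read_cooccurrence

            _require(paths["svc_edges"], "service co-occurrence graph")
            graph = read_cooccurrence(paths["svc_edges"], paths["svc_vocab"])
            emb = embed_services(
                graph,
                WalkConfig(
                    p=config.p,
                    q=config.q,
                    num_walks=config.num_walks,
                    walk_length=config.walk_length,
                    seed=stage_seed(config.seed, "embed-service"),
                ),
                SkipgramConfig(
                    dim=config.dim,
                    window=config.sg_window,
                    negatives=config.negatives,
                    epochs=config.sg_epochs,
                    seed=stage_seed(config.seed, "embed-service"),
                ),
            )
            write_embeddings(emb, paths["svc_emb"])
            outputs = [paths["svc_emb"]]
        elif stage == "embed-doctor":
            journeys = read_journeys(_require(paths["journeys"], "journey table"))
            service_emb = read_embeddings(_require(paths["svc_emb"], "service embeddings"))
            graph = build_doctor_service_graph(journeys)
            emb, _, report = train_gat(
                graph,
                service_emb,
                GatConfig(
                    heads=config.heads,
                    epochs=config.gat_epochs,
                    seed=stage_seed(config.seed, "embed-doctor"),
                ),
            )
            write_embeddings(emb, paths["doc_emb"])
            (out / "specialty_report.json").write_text(
                json.dumps({k: v for k, v in report.items() if k != "history"}, indent=2)
            )
            outputs = [paths["doc_emb"], out / "specialty_report.json"]
        elif stage == "embed-patient":
            journeys = read_journeys(_require(paths["journeys"], "journey table"))
            service_emb = read_embeddings(_require(paths["svc_emb"], "service embeddings"))
            doctor_emb = read_embeddings(_require(paths["doc_emb"], "doctor embeddings"))
            hybrid_graph = duplicate_annotate(build_patient_multigraph(journeys))
            emb, _ = train_patient_embeddings(
                hybrid_graph,
                service_emb,
                doctor_emb,
                PatientEmbedConfig(
                    dim=config.dim,
                    negatives=config.negatives,
                    epochs=config.patient_epochs,
                    seed=stage_seed(config.seed, "embed-patient"),
                ),
            )
            write_embeddings(emb, paths["pat_emb"])
            write_hybrid_vocabulary(hybrid_graph, paths["hybrids"])
            outputs = [paths["pat_emb"], paths["hybrids"]]
        elif stage == "eval-nodes":
            from .synthetic_ehr import read_ground_truth_labels

            emb = read_embeddings(_require(paths["pat_emb"], "patient embeddings"))
            labels = read_ground_truth_labels(_require(paths["truth"], "ground truth"), "label")
            report = node_classification_eval(
                emb, labels, repeats=10, seed=stage_seed(config.seed, "eval-nodes")
            )
            pr_auc, roc_auc = binary_outcome_eval(
                emb,
                {k: int(v) for k, v in labels.items()},
                folds=10,
                seed=stage_seed(config.seed, "eval-nodes"),
            )
            paths["nodes_report"].write_text(
                json.dumps(
                    {
                        "micro_f1": {str(k): v for k, v in report.micro_f1.items()},
                        "macro_f1": {str(k): v for k, v in report.macro_f1.items()},
                        "pr_auc": pr_auc,
                        "roc_auc": roc_auc,
                    },
                    indent=2,
                )
            )
            outputs = [paths["nodes_report"]]
        elif stage == "eval-links":
            journeys = read_journeys(_require(paths["journeys"], "journey table"))
            service_emb = read_embeddings(_require(paths["svc_emb"], "service embeddings"))
            seed = stage_seed(config.seed, "eval-links")
            edges = sorted(
                set(zip(journeys.frame["patient_id"], journeys.frame["doctor_id"]))
            )
            split = link_prediction_split(edges, config.link_fraction, seed=seed)
            # re-embed doctors and patients on the residual journeys only
            removed = set(split.positive_test_edges)
            keep = [
                (p, d) not in removed
                for p, d in zip(
                    journeys.frame["patient_id"], journeys.frame["doctor_id"]
                )
            ]
            from .ehr_data import JourneyTable

            residual = JourneyTable(journeys.frame[keep].reset_index(drop=True))
            doc_graph = build_doctor_service_graph(residual)
            doctor_emb, _, _ = train_gat(
                doc_graph,
                service_emb,
                GatConfig(heads=config.heads, epochs=config.gat_epochs, seed=seed),
            )
            hybrid_graph = duplicate_annotate(build_patient_multigraph(residual))
            patient_emb, _ = train_patient_embeddings(
                hybrid_graph,
                service_emb,
                doctor_emb,
                PatientEmbedConfig(
                    dim=config.dim,
                    negatives=config.negatives,
                    epochs=config.patient_epochs,
                    seed=seed,
                ),
            )
            auc = link_prediction_eval(split, patient_emb, doctor_emb, seed=seed)
            paths["links_report"].write_text(
                json.dumps(
                    {
                        "auc": auc,
                        "n_positive": len(split.positive_test_edges),
                        "n_negative": len(split.negative_test_edges),
                    },
                    indent=2,
                )
            )
            outputs = [paths["links_report"]]
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": [str(p) for p in outputs],
                "output_hashes": {p.name: _sha256(p) for p in outputs},
                "seed": stage_seed(config.seed, stage),
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def cooccurrence_density_report(journeys_path, T: int) -> float:
    journeys = read_journeys(journeys_path)
    return graph_density(build_cooccurrence(journeys, T))
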