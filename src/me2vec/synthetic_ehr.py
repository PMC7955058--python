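"""Synthetic patient-journey generator with planted, recoverable structure.

The generator emits journey tables shaped like claims extracts: doctors have
specialty-specific service-usage profiles, patients carry latent conditions
that drive both which specialties they visit and a binary outcome label,
service frequencies follow a Zipf-like skew with a rare tail, and successive
services are separated by irregular (geometric) day gaps.

Every quantity is reproducible from the config seed.  The RNG is split
hierarchically (profiles -> one stream per patient) so that growing the
cohort does not perturb the journeys of earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ehr_data import JOURNEY_COLUMNS, JourneyTable
from .errors import ConfigError, GenerationError

# Profile mass allocation per specialty.  The own-block share stays >= 0.7
# so pairwise total-variation distance between profiles is >= 0.3 by
# construction.  The routine tier is shared by every specialty, making its
# services globally frequent regardless of the patient mix, while the rare
# tail is reachable only through low-probability mass.
_OWN_BLOCK_MASS = 0.70
_ROUTINE_MASS = 0.20
_RARE_MASS = 0.08
_ROUTINE_FRACTION = 0.10
_SAME_DAY_PROB = 0.2
_AFFINITY_CONCENTRATION = 0.75


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 500
    n_doctors: int = 50
    n_services: int = 100
    n_specialties: int = 5
    n_conditions: int = 5
    services_per_patient_mean: float = 30.0
    gap_p: float = 0.5
    rare_service_fraction: float = 0.2
    zipf_exponent: float = 1.0
    label_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name in ("n_doctors", "n_services", "n_specialties", "n_conditions"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.services_per_patient_mean <= 0:
            raise ConfigError("services_per_patient_mean must be positive")
        if not (0 < self.gap_p <= 1):
            raise ConfigError("gap_p must lie in (0, 1]")
        for name in ("rare_service_fraction", "label_noise"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.zipf_exponent <= 0:
            raise ConfigError("zipf_exponent must be positive")
        if self.n_services < self.n_specialties:
            raise ConfigError(
                "n_services must be >= n_specialties to allocate disjoint service blocks"
            )


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a synthetic cohort."""

    doctor_specialty: dict[str, str]
    patient_condition: dict[str, int]
    patient_label: dict[str, int]
    specialty_service_profile: dict[str, np.ndarray]
    condition_specialty_affinity: dict[int, np.ndarray]
    services: list[str] = field(default_factory=list)
    specialties: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("doctor", d, "specialty", s) for d, s in self.doctor_specialty.items()]
        rows += [("patient", p, "condition", str(c)) for p, c in self.patient_condition.items()]
        rows += [("patient", p, "label", str(v)) for p, v in self.patient_label.items()]
        return pd.DataFrame(rows, columns=["entity_type", "entity_id", "attribute", "value"])


def _service_id(i: int) -> str:
    return f"svc{i:04d}"


def _doctor_id(i: int) -> str:
    return f"doc{i:04d}"


def _patient_id(i: int) -> str:
    return f"pat{i:05d}"


def _specialty_name(i: int) -> str:
    return f"spec{i:02d}"


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=np.float64)
    w = ranks ** (-exponent)
    return w / w.sum()


def generate_profiles(config: SimConfig) -> GroundTruth:
    """Build the planted profiles, affinities and entity assignments.

    Specialty profiles concentrate >= 70% of their mass on pairwise-disjoint
    blocks of "common" services, with a shared low-probability rare tail that
    yields a Zipf-like global rank-frequency curve.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    services = [_service_id(i) for i in range(config.n_services)]
    specialties = [_specialty_name(i) for i in range(config.n_specialties)]

    # tiers: [routine | specialty blocks | rare tail], in index order so the
    # global rank-frequency curve is Zipf-like with routine codes at the head
    n_rare = int(round(config.rare_service_fraction * config.n_services))
    n_rare = min(n_rare, max(config.n_services - config.n_specialties, 0))
    n_routine = min(
        int(round(_ROUTINE_FRACTION * config.n_services)),
        max(config.n_services - n_rare - config.n_specialties, 0),
    )
    n_block_total = config.n_services - n_rare - n_routine
    bounds = n_routine + np.linspace(0, n_block_total, config.n_specialties + 1).astype(int)
    rare_lo = n_routine + n_block_total

    profiles: dict[str, np.ndarray] = {}
    for k, spec in enumerate(specialties):
        p = np.zeros(config.n_services)
        lo, hi = bounds[k], bounds[k + 1]
        routine_mass = _ROUTINE_MASS if n_routine else 0.0
        rare_mass = _RARE_MASS if n_rare else 0.0
        p[lo:hi] = (
            _OWN_BLOCK_MASS + (1.0 - _OWN_BLOCK_MASS - routine_mass - rare_mass)
        ) * _zipf_weights(hi - lo, config.zipf_exponent)
        if n_routine:
            p[:n_routine] = routine_mass * _zipf_weights(n_routine, config.zipf_exponent)
        if n_rare:
            p[rare_lo:] = rare_mass * _zipf_weights(n_rare, config.zipf_exponent + 1.0)
        profiles[spec] = p / p.sum()

    doctor_specialty = {
        _doctor_id(i): specialties[i % config.n_specialties]
        for i in range(config.n_doctors)
    }

    affinity: dict[int, np.ndarray] = {}
    for c in range(config.n_conditions):
        a = np.full(
            config.n_specialties,
            (1.0 - _AFFINITY_CONCENTRATION) / max(config.n_specialties - 1, 1),
        )
        a[c % config.n_specialties] = (
            _AFFINITY_CONCENTRATION if config.n_specialties > 1 else 1.0
        )
        affinity[c] = a / a.sum()

    # patient-level maps are filled in by generate_cohort
    del rng
    return GroundTruth(
        doctor_specialty=doctor_specialty,
        patient_condition={},
        patient_label={},
        specialty_service_profile=profiles,
        condition_specialty_affinity=affinity,
        services=services,
        specialties=specialties,
    )


def generate_cohort(config: SimConfig) -> tuple[JourneyTable, GroundTruth]:
    """Draw a full cohort of patient journeys from the planted profiles.

    Each patient draws a latent condition, a Poisson journey length, and a
    sequence of (specialty -> doctor -> service) choices separated by
    geometric day gaps (with same-day bursts).  The binary outcome marks the
    designated case condition (condition 0), flipped with ``label_noise``.
    """
    truth = generate_profiles(config)
    specialties = truth.specialties
    services = np.array(truth.services)
    doctors_by_spec: dict[str, np.ndarray] = {
        s: np.array([d for d, ds in truth.doctor_specialty.items() if ds == s])
        for s in specialties
    }
    profile_matrix = {s: truth.specialty_service_profile[s] for s in specialties}

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients + 1)
    rows: list[tuple[str, str, str, str, int]] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(seeds[i + 1])
        pid = _patient_id(i)
        condition = int(rng.integers(config.n_conditions))
        truth.patient_condition[pid] = condition
        base_label = 1 if condition == 0 else 0
        flip = rng.random() < config.label_noise
        truth.patient_label[pid] = base_label ^ int(flip)

        n_steps = int(rng.poisson(config.services_per_patient_mean))
        day = 0
        affinity = truth.condition_specialty_affinity[condition]
        for _ in range(n_steps):
            spec = specialties[rng.choice(config.n_specialties, p=affinity)]
            pool = doctors_by_spec[spec]
            if len(pool) == 0:
                raise GenerationError(f"specialty {spec} has no doctors")
            doctor = str(pool[rng.integers(len(pool))])
            service = str(services[rng.choice(config.n_services, p=profile_matrix[spec])])
            rows.append((pid, doctor, spec, service, day))
            if rng.random() < _SAME_DAY_PROB:
                gap = 0
            else:
                gap = int(rng.geometric(config.gap_p))
            day += gap

    frame = pd.DataFrame(rows, columns=list(JOURNEY_COLUMNS))
    if len(frame) == 0:
        frame = frame.astype({"date": np.int64}, errors="ignore")
    return JourneyTable(frame), truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, index=False)


def read_ground_truth_labels(path, attribute: str = "label") -> dict[str, str]:
    frame = pd.read_csv(path, dtype=str)
    sel = frame[frame["attribute"] == attribute]
    return dict(zip(sel["entity_id"], sel["value"]))
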