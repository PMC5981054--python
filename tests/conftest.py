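import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clinalign.embeddings import EmbeddingModel, TrainingConfig, train_embeddings
from clinalign.pathways import EventType, MedicalEvent
from clinalign.synthdata import SyntheticConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_events():
    """Six events, two patients, shuffled timestamps, two admissions each."""
    return [
        MedicalEvent("p1", "a2", 10, EventType.DIAGNOSIS, "250.13"),
        MedicalEvent("p1", "a1", 2, EventType.LAB, "50912"),
        MedicalEvent("p1", "a1", 1, EventType.PRESCRIPTION, "ASA"),
        MedicalEvent("p1", "a2", 9, EventType.LAB, "50931"),
        MedicalEvent("p2", "b1", 5, EventType.CONDITION, "401"),
        MedicalEvent("p2", "b2", 7, EventType.DIAGNOSIS, "V45.81"),
    ]


@pytest.fixture(scope="session")
def toy_model():
    """Deterministic 5-code model with hand-chosen geometry."""
    return EmbeddingModel(
        vocabulary=["d_250", "d_401", "l_A", "l_B", "p_C"],
        matrix=np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],
                [0.9, 0.1, 0.0],
                [0.0, 0.9, 0.4],
                [-1.0, 0.0, 0.1],
            ]
        ),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but learnable synthetic cohort shared across tests."""
    cfg = SyntheticConfig(n_patients=300, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def trained_pair(small_cohort):
    """Two same-corpus models trained with different seeds (plus corpus)."""
    cohort, gt = small_cohort
    sentences = [cohort.pathways[p].events for p in cohort.patient_ids]
    tc = TrainingConfig(dim=25, window=5, epochs=5, seed=1)
    m1 = train_embeddings(sentences, tc)
    m2 = train_embeddings(
        sentences, TrainingConfig(dim=25, window=5, epochs=5, seed=2)
    )
    return m1, m2, sentences
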