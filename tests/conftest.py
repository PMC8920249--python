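import numpy as np
import pytest

from preysel import (
    FeedingRecord,
    SimulationConfig,
    TreatmentSpec,
    simulate_experiment,
    study_treatments,
)


@pytest.fixture(scope="session")
def treatments():
    return study_treatments()


@pytest.fixture(scope="session")
def equal_spec(treatments) -> TreatmentSpec:
    return treatments["2:2:2:2"]


@pytest.fixture(scope="session")
def skewed_spec(treatments) -> TreatmentSpec:
    return treatments["1:2:1:4"]


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated trial reused across I/O and summary tests."""
    cfg = SimulationConfig(n_predators=10, n_days=14, seed=42)
    records, truth = simulate_experiment(cfg)
    return cfg, records, truth


def make_record(counts, predator="P1", day=1, treatment="2:2:2:2") -> FeedingRecord:
    return FeedingRecord(
        predator_id=predator,
        tank="T1",
        compartment="C1",
        treatment_id=treatment,
        day=day,
        counts=tuple(counts),
    )
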