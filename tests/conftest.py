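import sys
from pathlib import Path
from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

import pvsignal as pv
from pvsignal.config import DemographicModel, DrugSpec, EventSpec, ScenarioConfig

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "pvsignal",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.filter_too_much],
)
settings.load_profile("pvsignal")


def make_small_scenario(n_cases=4000, seed=0, **overrides) -> ScenarioConfig:
    """A compact, fully observed scenario for fast unit tests."""
    base = dict(
        n_cases=n_cases,
        drugs=(
            DrugSpec("drug A", "A01", 0.05),
            DrugSpec("drug B", "B01", 0.10),
            DrugSpec("drug C", "C01", 0.20),
        ),
        events=(
            EventSpec("Fracture", True, 0.05),
            EventSpec("Femur fracture", True, 0.02),
            EventSpec("Nausea", False, 0.30),
            EventSpec("Rash", False, 0.20),
        ),
        planted_effects={},
        demographics=DemographicModel(),
        confounding={},
        missingness={},
        duplicate_rate=0.0,
        outlier_rate=0.0,
        involvement_mix=(1.0, 0.0, 0.0),
        seed=seed,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized realistic cohort shared across read-only tests."""
    config = pv.default_scenario(n_cases=20_000, seed=42)
    demo, drug, reac, truth = pv.generate_cohort(config)
    rows, report = pv.build_analysis_table(demo, drug, reac)
    return SimpleNamespace(config=config, demo=demo, drug=drug, reac=reac,
                           truth=truth, rows=rows, report=report)


@pytest.fixture()
def tiny_tables():
    """Hand-built three-table fixture: 2 cases, mixed involvement, 3 events."""
    import numpy as np
    import pandas as pd
    demo = pd.DataFrame({
        "case_id": ["C1", "C2"],
        "sex": ["female", "male"],
        "age_band": ["60s", "30s"],
        "height_cm": [154.0, 170.0],
        "weight_kg": [52.1, 80.0],
    })
    drug = pd.DataFrame({
        "case_id": ["C1", "C1", "C2"],
        "drug_name": ["drug A", "drug B", "drug A"],
        "involvement": ["suspected", "concomitant", "suspected"],
        "atc_code": ["A01", "B01", "A01"],
    })
    reac = pd.DataFrame({
        "case_id": ["C1", "C1", "C2"],
        "preferred_term": ["Femur fracture", "Nausea", "Rash"],
        "outcome": ["recovered", "unknown", np.nan],
    })
    return demo, drug, reac
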