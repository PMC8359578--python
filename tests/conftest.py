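import numpy as np
import pandas as pd
import pytest

from bioage import CohortTable, GeneratorConfig, ParameterMatrix, generate_cohort


def make_cohort(
    ca,
    sex=None,
    status=None,
    death_cause=None,
    followup=None,
    flags=None,
):
    """Hand-rolled cohort frame for small fixtures."""
    n = len(ca)
    ids = [f"P{i}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "sex": sex if sex is not None else ["male"] * n,
            "ca_years": ca,
            "followup_days": followup if followup is not None else [365.0] * n,
            "status": status if status is not None else ["alive"] * n,
            "death_cause": death_cause if death_cause is not None else ["none"] * n,
            "structural_heart_disease": False,
            "pacing": False,
            "tachyarrhythmia": False,
            "indeterminate_axis": False,
        },
        index=pd.Index(ids, name="patient_id"),
    )
    if flags:
        for flag, values in flags.items():
            frame[flag] = values
    return CohortTable(frame)


def make_params(data: dict, index=None) -> ParameterMatrix:
    n = len(next(iter(data.values())))
    ids = index if index is not None else pd.Index([f"P{i}" for i in range(n)], name="patient_id")
    return ParameterMatrix(pd.DataFrame(data, index=ids))


@pytest.fixture(scope="session")
def small_synthetic():
    """One shared n=2000 synthetic cohort for cheap downstream checks."""
    cfg = GeneratorConfig(n_patients=2000, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_synthetic():
    """The n=5000 strong-signal cohort used for parameter-recovery checks."""
    cfg = GeneratorConfig(n_patients=5000, seed=11)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
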