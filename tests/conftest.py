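import numpy as np
import pandas as pd
import pytest

from ckdtriage import (
    SystemConfig,
    default_cohort_spec,
    generate_cohort,
    run_training,
)
from ckdtriage.cohort import CohortTable


@pytest.fixture(scope="session")
def separable_cohort():
    """Well-separated study-condition cohort (separation 3, n = 500)."""
    return generate_cohort(default_cohort_spec(n_patients=500, separation=3.0, seed=7))


@pytest.fixture(scope="session")
def moderate_cohort():
    """Overlapping-classes cohort for pattern/cutpoint behaviour."""
    return generate_cohort(default_cohort_spec(n_patients=400, separation=1.0, seed=3))


@pytest.fixture(scope="session")
def trained_bundle(separable_cohort):
    """One fully trained system reused across system/explain tests."""
    return run_training(separable_cohort, SystemConfig(seed=7))


def make_table(values: dict, labels=None, mask=None) -> CohortTable:
    """Small hand-built cohort table; None entries become missing."""
    frame = pd.DataFrame(values, dtype=float)
    frame.index = pd.Index([f"P{i}" for i in range(len(frame))], name="patient_id")
    observed = frame.notna() if mask is None else pd.DataFrame(
        mask, index=frame.index, columns=frame.columns
    )
    lab = None
    if labels is not None:
        lab = pd.Series(labels, index=frame.index, name="ckd_stage").astype(int)
    return CohortTable(features=frame, labels=lab, observed_mask=observed)
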