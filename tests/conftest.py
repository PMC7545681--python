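import numpy as np
import pandas as pd
import pytest

from morphome import SimulationConfig, simulate_cohort


def make_cells(rows):
    """rows: (patient, field, cluster, cell, pattern) tuples."""
    return pd.DataFrame(
        rows,
        columns=["patient_id", "field_id", "cluster_id", "cell_id", "ecad_pattern"],
    )


@pytest.fixture
def cells_two_clusters():
    """Two clusters (sizes 3 and 4) for one patient, mixed patterns."""
    rows = []
    for i, pat in enumerate(["membranous", "mixed", "cytoplasmic"]):
        rows.append(("P1", "F1", "c1", f"a{i}", pat))
    for i, pat in enumerate(["mixed", "mixed", "membranous", "cytoplasmic"]):
        rows.append(("P1", "F1", "c2", f"b{i}", pat))
    return make_cells(rows)


@pytest.fixture
def surv_simple():
    """8 subjects, one covariate, no ties; enough events for a stable fit."""
    time = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0])
    event = np.array([1, 1, 0, 1, 1, 0, 1, 1], dtype=bool)
    x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
    return x, time, event


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=40), seed=202, expand_cells=True)


@pytest.fixture(scope="session")
def medium_cohort():
    """A 171-patient cohort-scale dataset (matrix-level, no cell table)."""
    return simulate_cohort(SimulationConfig(), seed=7, expand_cells=False)
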