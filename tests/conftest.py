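import numpy as np
import pandas as pd
import pytest

from mirsense import (
    CombinationSpec,
    DrugResponsePanel,
    ExpressionMatrix,
    ResponseSignature,
)
from mirsense.simulate import (
    CohortSimParams,
    PanelSimParams,
    simulate_cell_line_panel,
    simulate_patient_cohort,
)


@pytest.fixture(scope="session")
def default_panel_sim():
    """One simulated cell-line screen at generator defaults."""
    return simulate_cell_line_panel(PanelSimParams())


@pytest.fixture(scope="session")
def default_cohort_sim():
    """One simulated patient cohort at generator defaults."""
    return simulate_patient_cohort(CohortSimParams())


@pytest.fixture(scope="session")
def truth_signature(default_cohort_sim):
    """Signature made of the cohort's planted features (nominal r)."""
    _, _, truth = default_cohort_sim
    return ResponseSignature(
        treatment_name="CHOP",
        entries=tuple((f, 0.5) for f in truth.planted_features),
    )


@pytest.fixture
def tiny_panel():
    """3-drug, 4-cell-line panel with one missing value."""
    values = pd.DataFrame(
        {
            "CL1": [6.0, 4.0, 2.0],
            "CL2": [5.0, 4.0, 3.0],
            "CL3": [1.0, 1.0, 1.0],
            "CL4": [np.nan, 2.0, 2.0],
        },
        index=["vincristine", "doxorubicin", "cyclophosphamide"],
    )
    return DrugResponsePanel(values)


@pytest.fixture
def chop_spec():
    return CombinationSpec(
        treatment_name="CHOP",
        component_drugs=("vincristine", "doxorubicin", "cyclophosphamide"),
    )


@pytest.fixture
def small_expression():
    """5 features x 5 samples, including a constant feature."""
    rng = np.random.default_rng(42)
    values = rng.normal(7, 1, size=(5, 5))
    values[3] = 7.0  # zero variance
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"miR-{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(5)],
        )
    )
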