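import numpy as np
import pandas as pd
import pytest

from curvemr import preset, simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20231117)


@pytest.fixture()
def tiny_cohort():
    """Six hand-written individuals covering the derivation edge cases."""
    return pd.DataFrame({
        "individual_id": [f"p{i}" for i in range(6)],
        "sex": [0, 1, 0, 1, 0, 1],
        "age": [50.0, 61.0, 55.0, 47.0, 70.0, 58.0],
        "bmi": [24.0, 28.5, 22.1, 31.0, 26.0, 25.5],
        "ldl_c": [3.1, 2.5, 4.0, 3.6, 2.9, 3.3],
        "fbg": [5.5, 7.0, 6.9, np.nan, 5.2, 6.0],
        "ogtt_2h": [7.0, 8.0, 11.0, 9.0, np.nan, 11.1],
        "sbp": [128.0, 141.0, 139.9, 135.0, 150.0, np.nan],
        "dbp": [80.0, 85.0, 89.9, 90.0, 95.0, np.nan],
        "self_report_diabetes": [0, 0, 0, 1, 0, 0],
        "hypoglycemic_drug_use": [0, 0, 0, 0, 0, 0],
        "lipid_lowering_drug_use": [0, 1, 0, 0, 1, 0],
        "self_report_hypertension": [0, 0, 0, 0, 1, 0],
        "antihypertensive_use": [0, 0, 0, 0, 1, 1],
        "diabetes_family_history": [0, 1, 0, 0, 1, 0],
        "chd": [0, 0, 1, 0, 0, 0],
        "dyslipidemia": [0, 1, 0, 0, 1, 1],
        "ever_smoker": [0, 1, 0, 1, 0, 0],
    })


@pytest.fixture(scope="session")
def spurious_u_cohort():
    """One mid-size spurious-U realization shared across read-only tests."""
    return simulate_cohort(preset("SPURIOUS_U", n_individuals=4000, seed=11))


@pytest.fixture(scope="session")
def linear_protective_cohort():
    return simulate_cohort(preset("LINEAR_PROTECTIVE", n_individuals=4000, seed=7))
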