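import numpy as np
import pytest

from neovanc.foce_engine import compile_dataset
from neovanc.pk_structural import final_model
from neovanc.synthetic_cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def final_structure():
    return final_model()


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject cohort used by fast unit tests."""
    return simulate_cohort(CohortConfig(n_subjects=20, seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    """Full 80-subject, 2-sample design at the published parameters."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def study_fit(study_cohort, final_structure):
    from neovanc.foce_engine import fit

    dataset, _ = study_cohort
    return fit(dataset, final_structure)


@pytest.fixture(scope="session")
def study_compiled(study_cohort, final_structure):
    dataset, _ = study_cohort
    return compile_dataset(dataset, final_structure.covariate_names())


TRUE_THETA = np.array([0.309, 1.55, -0.337, 2.63, 1.05])
TRUE_OMEGA2 = 0.379**2
TRUE_SIGMA2 = 0.375**2


@pytest.fixture(scope="session")
def truth_values():
    return TRUE_THETA, TRUE_OMEGA2, TRUE_SIGMA2
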