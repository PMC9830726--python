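import numpy as np
import pandas as pd
import pytest

from metabshape import CohortConfig, IntensityMatrix, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> CohortConfig:
    """Small cohort for fast pipeline-level tests."""
    return CohortConfig(
        group_sizes=(8, 10, 9),
        n_metabolites_per_class={
            "U_up": 4, "U_down": 4, "line_up": 4, "line_down": 4, "null": 20,
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the study's group sizes and default effects."""
    return generate_cohort(CohortConfig(seed=3))


@pytest.fixture
def random_matrix() -> IntensityMatrix:
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.lognormal(mean=5.0, sigma=1.0, size=(100, 20)),
        index=[f"S{i}" for i in range(100)],
        columns=[f"m{j}" for j in range(20)],
    )
    return IntensityMatrix(df, "maternal", "pos")
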