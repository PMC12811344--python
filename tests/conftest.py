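import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import intervalcure as ic
from intervalcure.types import Dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(rows, p=1, q=1):
    """Build a Dataset from (u_left, u_right, delta1, delta2) tuples with
    placeholder covariates."""
    rows = np.asarray(rows, dtype=float)
    n = len(rows)
    rng = np.random.default_rng(12345)
    return Dataset(
        rows[:, 0], rows[:, 1], rows[:, 2], rows[:, 3],
        rng.standard_normal((n, p)), rng.standard_normal((n, q)),
    )


@pytest.fixture
def toy_dataset():
    """Six subjects covering all three censoring types."""
    return make_dataset(
        [
            (0.0, 0.3, 1, 0),
            (0.2, 0.5, 0, 1),
            (0.4, 0.9, 0, 1),
            (0.6, np.inf, 0, 0),
            (1.0, np.inf, 0, 0),
            (0.5, 1.4, 0, 1),
        ]
    )


@pytest.fixture(scope="session")
def sc1_data():
    """One moderate scenario-1 draw with ground truth."""
    rng = np.random.default_rng(20240901)
    return ic.generate_dataset(ic.scenario_spec(1), 150, rng)


@pytest.fixture(scope="session")
def sc1_fit(sc1_data):
    dataset, _ = sc1_data
    rng = np.random.default_rng(77)
    return ic.fit_mcm_svm(dataset, ic.EMConfig(max_iter=5, seed=77), rng)
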