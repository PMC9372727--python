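import numpy as np
import pandas as pd
import pytest

import stimscreen as ss


@pytest.fixture(scope="session")
def tiny_design():
    return ss.ScreenDesign(n_samples=8)


@pytest.fixture(scope="session")
def tiny_truth(tiny_design):
    return ss.default_truth(tiny_design)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_design, tiny_truth):
    return ss.generate_cohort(tiny_design, tiny_truth, seed=7)


@pytest.fixture(scope="session")
def tiny_wells(tiny_design, tiny_cohort, tiny_truth):
    return ss.generate_plates(tiny_design, tiny_cohort, tiny_truth, seed=8)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_wells):
    return ss.response_matrix(ss.log_relative_viability(tiny_wells))


def binary_features(rng, n, names, prevalence=0.3):
    return pd.DataFrame(
        {name: (rng.random(n) < prevalence).astype(float) for name in names},
        index=[f"S{i:03d}" for i in range(n)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
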