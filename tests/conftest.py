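import numpy as np
import pandas as pd
import pytest

from thyrosig import SyntheticScenario, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The paper-like default scenario: 11 ATC + 48 PTC, 5000 probes, seed 42."""
    scenario = SyntheticScenario()
    ratios, sheet, truth = generate_cohort(scenario)
    return scenario, ratios, sheet, truth


@pytest.fixture(scope="session")
def zero_noise_cohort():
    scenario = SyntheticScenario(noise_sd=0.0)
    ratios, sheet, truth = generate_cohort(scenario)
    return scenario, ratios, sheet, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ratio_matrix(rng, n_probes, n_samples, scale=1.5):
    """Dense random log2-ratio matrix for oracle-equivalence tests."""
    values = rng.normal(0.0, scale, size=(n_probes, n_samples))
    probes = [f"p{i}" for i in range(n_probes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return pd.DataFrame(values, index=probes, columns=samples)
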