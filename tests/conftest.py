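import matplotlib

matplotlib.use("Agg")

import pytest

from zwdistort import preset_cross, simulate_cross, simulate_population


@pytest.fixture(scope="session")
def s5_spec():
    return preset_cross("S5")


@pytest.fixture(scope="session")
def s3_spec():
    return preset_cross("S3")


@pytest.fixture(scope="session")
def s5_clean(s5_spec):
    """Noise-free S5 population (table, truth)."""
    return simulate_population(s5_spec, seed=11)


@pytest.fixture(scope="session")
def s5_noisy(s5_spec):
    """S5 population with the default missingness and error rates."""
    return simulate_cross(s5_spec, seed=11)


@pytest.fixture(scope="session")
def s3_clean(s3_spec):
    return simulate_population(s3_spec, seed=7)
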