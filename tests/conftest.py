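import numpy as np
import pandas as pd
import pytest

from neogrowth import GrowthChart, SyntheticConfig, generate_chart, generate_cohort


@pytest.fixture(scope="session")
def toy_chart() -> GrowthChart:
    """Hand-built geometric chart: M doubles every ~7.3 weeks, L=1, S=0.1."""
    rows = []
    for sex, m0 in (("male", 500.0), ("female", 480.0)):
        for wk in range(22, 45):
            rows.append(
                {"sex": sex, "pma_days": wk * 7, "L": 1.0, "M": m0 * 1.1 ** (wk - 22), "S": 0.1}
            )
    return GrowthChart("toy", pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=20240, n=800)


@pytest.fixture(scope="session")
def synthetic_chart(default_config):
    return generate_chart(default_config)


@pytest.fixture(scope="session")
def synthetic_cohort(default_config, synthetic_chart) -> pd.DataFrame:
    return generate_cohort(default_config, synthetic_chart)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
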