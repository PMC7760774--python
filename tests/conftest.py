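import numpy as np
import pytest

from critspeed import GeneratorConfig, calibrate_sex_cs_distributions
from critspeed.pipeline import run_full


@pytest.fixture(scope="session")
def calibrated_config() -> GeneratorConfig:
    """Default configuration with calibrated sex-specific CS distributions."""
    return calibrate_sex_cs_distributions(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def demo_run():
    """The canonical demo cohort: 37 athletes, 9 pacing + 3 VP violators."""
    config = GeneratorConfig(
        n_athletes=37, n_pacing_violators=9, n_vp_violators=3, seed=1
    )
    report, cohort = run_full(config)
    return report, cohort


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
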