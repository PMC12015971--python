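import math

import numpy as np
import pytest

from pt2nerve import AcquisitionSpec, GeometryConfig, RunConfig
from pt2nerve.simulate import simulate_subject


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    cfg = RunConfig(master_seed=123, n_attrv=3, n_hc=3)
    cfg.geometry = GeometryConfig(shape=(64, 64, 5))
    return cfg


@pytest.fixture(scope="session")
def noiseless_subject():
    """One ATTRv subject rendered without noise (deterministic)."""
    cfg = RunConfig(master_seed=99)
    cfg.geometry = GeometryConfig(shape=(64, 64, 5))
    cfg.acquisition = AcquisitionSpec(snr=math.inf)
    rng = np.random.default_rng(42)
    truth, vol, mask = simulate_subject("ATTRv", cfg, rng, "NOISELESS-1")
    return truth, vol, mask
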