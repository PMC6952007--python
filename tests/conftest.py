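import numpy as np
import pytest

from eggsim import (
    breeder_flock_config,
    generate_flock,
    layer_flock_config,
    make_fixture,
    simulate_flock,
)


@pytest.fixture(scope="session")
def det_cfg():
    """One hen, all SDs zero, constant lag 1 h, threshold 8.5 h, noise-free times."""
    return make_fixture("deterministic_hen")


@pytest.fixture(scope="session")
def det_result(det_cfg):
    fl = det_cfg.flock
    return simulate_flock(generate_flock(fl), det_cfg.horizon_d, fl)


@pytest.fixture(scope="session")
def layer_result():
    cfg = layer_flock_config(n_hens=120, seed=1)
    return simulate_flock(generate_flock(cfg), 300, cfg)


@pytest.fixture(scope="session")
def breeder_result():
    cfg = breeder_flock_config(n_hens=120, seed=1)
    return simulate_flock(generate_flock(cfg), 300, cfg)
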