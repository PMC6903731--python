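import numpy as np
import pandas as pd
import pytest

from pengwinter.synthetic import Deployment, SimulationConfig, generate_env_grids


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def env(config):
    return generate_env_grids(config)


@pytest.fixture()
def shirreff():
    return Deployment(
        deployment_id="cs-test", colony="Cape Shirreff",
        colony_lon=-60.789, colony_lat=-62.46, stage="adult",
        release_time=pd.Timestamp("2017-02-19T12:00:00"))


def exact_obs_config(seed=7, **overrides) -> SimulationConfig:
    """Config whose Argos process is error-free class 3 (no Z, no missing
    ellipses), handy wherever observed == true is needed."""
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.argos_class_probs = {"3": 1.0, "2": 0.0, "1": 0.0, "0": 0.0,
                             "A": 0.0, "B": 0.0, "Z": 0.0}
    cfg.argos_class_sd = {**cfg.argos_class_sd, "3": 0.0}
    cfg.missing_ellipse_frac = 0.0
    return cfg
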