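import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from foodcast.indicators import (
    fcs_insufficient,
    interpolate_gaps,
    rcsi_crisis,
    rolling_prevalence,
)
from foodcast.synth import ScenarioConfig, daily_driver_features, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """5 areas x 400 days, modest survey volume; shared across tests."""
    cfg = ScenarioConfig(n_areas=5, n_days=400, households_per_day=15, seed=42)
    drivers, latent, surveys = generate_scenario(cfg)
    return cfg, drivers, latent, surveys


@pytest.fixture(scope="session")
def small_forecast_inputs(small_scenario):
    """Target/rCSI prevalence and daily driver features for the small scenario."""
    cfg, drivers, latent, surveys = small_scenario
    d = cfg.rolling_window_d
    target = interpolate_gaps(
        rolling_prevalence(surveys, d, fcs_insufficient(), index=cfg.index)
    )
    rcsi = interpolate_gaps(
        rolling_prevalence(surveys, d, rcsi_crisis(), index=cfg.index)
    )
    daily = daily_driver_features(drivers, cfg, cfg.index)
    return cfg, target, rcsi, daily, drivers.statics
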