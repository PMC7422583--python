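"""Shared fixtures: the heavy seasonal-landscape runs are session-scoped so
the scenario-comparison assertions can share them."""

import numpy as np
import pytest

from drivesuppress.landscape import SeasonProfile, generate_landscape, generate_rainfall
from drivesuppress.metrics import annual_release_schedule
from drivesuppress.scenarios import SCENARIOS
from drivesuppress.spatial import SimConfig, run_simulation

SEASONAL_YEARS = 4


@pytest.fixture(scope="session")
def seasonal_landscape():
    """500 clustered settlements over 100x100 km with a north-south
    seasonality gradient, mirroring the structure of the study region at
    reduced scale."""
    ls = generate_landscape(500, (100.0, 100.0), clustering=1.0, seed=42)
    rain = generate_rainfall(
        ls, SeasonProfile(latitudinal_gradient=0.5), years=SEASONAL_YEARS + 2, seed=7
    )
    return ls, rain


@pytest.fixture(scope="session")
def seasonal_runs(seasonal_landscape):
    """Reference plus strong/medium/weak drive release runs (paired on the
    same landscape and rainfall, independent demographic seeds)."""
    ls, rain = seasonal_landscape
    schedule = annual_release_schedule(
        ls, SEASONAL_YEARS, fraction=0.01, n_males=5000, strategy="random", seed=5
    )
    runs = {"reference": run_simulation(SimConfig(seed=100), ls, rain, None, SEASONAL_YEARS)}
    for i, name in enumerate(["ideal", "medium", "high"]):
        cfg = SimConfig(drive=SCENARIOS[name], seed=201 + i)
        runs[name] = run_simulation(cfg, ls, rain, schedule, SEASONAL_YEARS)
    return runs
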