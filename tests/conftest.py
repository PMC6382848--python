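"""Shared fixtures: tiny handcrafted rainfall series and one full synthetic
study reused across pipeline-level tests."""

import numpy as np
import pytest

from tgbcover import DailyRainfallSeries, RunConfig, Scenario, run
from tgbcover._calendar import MONTH_LENGTHS, MONTH_STARTS


def series_from_monthly(monthly, n_years=1):
    """A daily series spreading each month's total evenly over its days."""
    monthly = np.asarray(monthly, dtype=float)
    depths = np.zeros((n_years, 365))
    for m in range(12):
        start, stop = MONTH_STARTS[m], MONTH_STARTS[m + 1]
        depths[:, start:stop] = monthly[m] / MONTH_LENGTHS[m]
    return DailyRainfallSeries(depths)


@pytest.fixture
def uniform_series():
    """1 mm on every day of one year."""
    return DailyRainfallSeries(np.ones((1, 365)))


@pytest.fixture(scope="session")
def small_scenario():
    return Scenario(
        n_cells={"R1": 40, "R2": 40, "R3": 20}, n_masked_cells=10, seed=11
    )


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full end-to-end run of the default synthetic scenario."""
    outdir = tmp_path_factory.mktemp("default_run")
    return run(RunConfig(scenario=Scenario(), outdir=outdir, seed=5))
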