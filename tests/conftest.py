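"""Shared fixtures: synthetic study-condition data, reused across modules."""

import numpy as np
import pytest

import pulsepop as pp
from pulsepop.fitting import FitConfig

#: truth used by the recovery / bootstrap tests (Ivlev, observed-seedfall fit)
TRUTH = pp.IVLEV_OBSERVED_FIT


@pytest.fixture(scope="session")
def noise_free_fixture():
    """43-year seedfall record + noise-free quarterly output (last 25 years)."""
    cfg = pp.FixtureConfig(seed=3, obs_noise_cv=0.0)
    temps, seedfall, quarterly = pp.make_fixture(cfg)
    sub = pp.AnnualSeries(seedfall.years[-25:], seedfall.values[-25:])
    return temps, sub, quarterly


@pytest.fixture(scope="session")
def recovery_fit(noise_free_fixture):
    """Simplified Ivlev fit to the noise-free fixture (shared: it is slow)."""
    _, seedfall, quarterly = noise_free_fixture
    cfg = FitConfig(n_starts=6, seed=0)
    return pp.fit_consumer_model(quarterly, seedfall, "ivlev", "simplified", cfg)


def ramp_temperatures(dts, start_year=1968, t0=16.0):
    """Temperature series whose successive dT values are exactly ``dts``.

    Built by cumulative summation, so the two-summer differential for the
    year indexed ``start_year + 2 + i`` equals ``dts[i]`` exactly.  Used
    by the regression inverse tests, which need dT controlled so the
    zero-floor of the back-transform never triggers.
    """
    dts = np.asarray(dts, dtype=float)
    temps = t0 + np.concatenate([[0.0], np.cumsum(dts), [np.sum(dts)]])
    # order: T_{y-2}, then each T_{y-1} = previous + dT; final padding year
    years = np.arange(start_year, start_year + temps.size)
    return pp.AnnualSeries(years, temps, name="temperature")
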