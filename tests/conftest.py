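"""Shared fixtures: small hand-built climate series and a cached default
synthetic study (generation is cheap; the heavier mixed-model analyses on
it are cached per session by the tests that need them)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cambiomatch.climate import DailyClimateSeries


def climate_from_fn(fn, start_year=2000, end_year=2001, site_id="test",
                    latitude=45.0, prcp=None):
    """Build a series whose tmean is fn(dates) (vectorized or scalar)."""
    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    try:
        tmean = np.asarray(fn(dates), dtype=float)
        if tmean.shape != (len(dates),):
            raise TypeError
    except TypeError:
        tmean = np.array([float(fn(d)) for d in dates])
    return DailyClimateSeries(site_id=site_id, dates=dates, tmean=tmean,
                              prcp=prcp, latitude=latitude)


def constant_climate(value, start_year=2000, end_year=2001, **kw):
    return climate_from_fn(lambda d: np.full(len(d), float(value)),
                           start_year, end_year, **kw)


@pytest.fixture(scope="session")
def default_study():
    from cambiomatch.synthetic_data import make_study

    return make_study(seed=1)


@pytest.fixture(scope="session")
def structural_result():
    """Full chilling/forcing + response chain on the default study (seed 1)."""
    import warnings

    from cambiomatch.experiments import structural_recovery

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return structural_recovery(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
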