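"""Shared fixtures: small synthetic series and supervised sets."""

import numpy as np
import pandas as pd
import pytest

from elmbloom.data import SiteSeries, SupervisedSet
from elmbloom.synth import SynthConfig, generate_pair


def make_series(n_weeks: int = 10, site_id: str = "site", seed: int = 0,
                start: str = "2013-01-07") -> SiteSeries:
    """A small, fully populated weekly series with deterministic values."""
    rng = np.random.default_rng(seed)
    weeks = pd.date_range(start, periods=n_weeks, freq="7D")
    tn = 2.0 + rng.uniform(0, 2, n_weeks)
    tp = 0.03 + rng.uniform(0, 0.05, n_weeks)
    frame = pd.DataFrame(
        {
            "week_start": weeks,
            "AT": 10 + 10 * np.sin(np.arange(n_weeks) / 3.0),
            "RF": rng.gamma(1.0, 10.0, n_weeks),
            "SR": 12 + rng.uniform(-3, 3, n_weeks),
            "TN": tn,
            "TP": tp,
            "NP": tn / tp,
            "Chla": 5 + rng.uniform(0, 30, n_weeks),
        }
    )
    return SiteSeries(site_id, frame)


def make_supervised(n: int = 30, d: int = 3, seed: int = 0,
                    fn=None, noise_sd: float = 0.0) -> SupervisedSet:
    """A generic supervised set (variant 'custom') with optional target map."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-2, 2, size=(n, d))
    if fn is None:
        y = X.sum(axis=1)
    else:
        y = fn(X)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, n)
    return SupervisedSet(
        X=X, T=y, feature_names=[f"x{i}" for i in range(d)],
        week_index=pd.date_range("2013-01-07", periods=n, freq="7D"),
        variant="custom",
    )


@pytest.fixture(scope="session")
def default_pair():
    """One default-configuration synthetic weir pair (upstream, downstream)."""
    up, down, truth = generate_pair(SynthConfig(seed=1))
    return up, down, truth


@pytest.fixture()
def small_series():
    return make_series(10)


@pytest.fixture()
def upstream_series():
    return make_series(10, site_id="up", seed=1)
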