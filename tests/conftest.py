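import numpy as np
import pandas as pd
import pytest

from aircrossover.datamodel import DailySeries
from aircrossover.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def default_series() -> DailySeries:
    """Three-year scenario at registry scale with an injected PM2.5 effect."""
    return generate_scenario(ScenarioConfig(rng_seed=42))


@pytest.fixture(scope="session")
def null_series() -> DailySeries:
    """Three-year scenario with no pollutant effect at all."""
    return generate_scenario(ScenarioConfig(rng_seed=43, true_log_rr_per_ug={}))


@pytest.fixture()
def toy_series() -> DailySeries:
    """Four informative days in two (month, weekday) strata, binary exposure.

    Within each stratum the exposed day has roughly double the deaths of the
    unexposed one, so the Poisson MLE for the exposure log-RR has the closed
    form ln((20+22)/(10+12)) = ln(21/11).
    """
    dates = pd.date_range("2014-01-01", "2014-01-09", freq="D")
    f = pd.DataFrame(index=dates)
    f.index.name = "date"
    f["pm25"] = 0.0
    f["deaths_all_cause"] = 0
    for day, x, y in [
        ("2014-01-01", 0.0, 10),
        ("2014-01-08", 1.0, 20),
        ("2014-01-02", 0.0, 12),
        ("2014-01-09", 1.0, 22),
    ]:
        f.loc[day, "pm25"] = x
        f.loc[day, "deaths_all_cause"] = y
    return DailySeries(f)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
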