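import numpy as np
import pandas as pd
import pytest

from urbanwild import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20140101)


@pytest.fixture
def two_species_config():
    """Small two-species scenario with mild covariate effects."""
    return simulate.ScenarioConfig(
        species=[
            simulate.SpeciesParams(
                name="coyote",
                occ_intercept=0.4,
                occ_coefs={"core_forest_5km": 0.5},
                det_intercept=-0.4,
                event_rate=0.12,
            ),
            simulate.SpeciesParams(
                name="red_fox",
                occ_intercept=-0.5,
                det_intercept=-1.0,
                event_rate=0.05,
            ),
        ],
        n_sites_per_cell=3,
        seed=42,
    )


@pytest.fixture
def small_survey(two_species_config):
    sites = simulate.simulate_sites(two_species_config)
    history, truth = simulate.simulate_occupancy_survey(two_species_config, sites)
    return sites, history, truth


def make_sites(n, n_days=21, density=0.2, level="wild", plot="large_forest", start="2014-06-01"):
    """Minimal hand-built site table for unit tests."""
    start = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(n)],
            "city": "DC",
            "housing_density": density,
            "development_level": level,
            "plot_type": plot,
            "deploy_start": start,
            "deploy_end": start + pd.Timedelta(days=n_days - 1),
        }
    )
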