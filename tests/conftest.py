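import warnings

import numpy as np
import pandas as pd
import pytest

import bymgamma as bg

warnings.filterwarnings("ignore", message="ArviZ")


@pytest.fixture(scope="session")
def path_graph():
    """Three regions in a path: A - B - C."""
    return bg.SpatialGraph.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator: 20-region lattice, 6 years."""
    return bg.GeneratorConfig(grid_shape=(4, 5), seed=42)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return bg.sample_truth(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config, small_truth):
    return bg.generate_panel(small_truth, small_config)


@pytest.fixture(scope="session")
def small_fit(small_config, small_panel):
    """One modest MCMC fit shared by summary-level tests."""
    model = bg.SpatialGammaModel(
        small_panel, small_config.resolve_graph(), small_config.model_spec()
    )
    return model.fit(bg.SamplerConfig(n_iter=1200, n_burnin=600, thin=2, n_chains=2, seed=9))


def make_records(rows):
    """Survey records from (region, year, sex, age_group, flags...) dicts."""
    base = {
        "hypertension": np.nan, "stroke": np.nan, "myocardial_infarction": np.nan,
        "angina": np.nan, "current_smoker": np.nan, "passive_home": np.nan,
        "passive_work": np.nan, "bmi": 23.0, "drinks_monthly": np.nan,
    }
    return pd.DataFrame([{**base, **r} for r in rows])
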