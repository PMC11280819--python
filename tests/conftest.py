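import numpy as np
import pandas as pd
import pytest

from aquarisk import configio, synthetic_data


@pytest.fixture(scope="session")
def small_dataset():
    """59-site, 3-season synthetic campaign shared across tests."""
    sites = synthetic_data.generate_sites(59, seed=11)
    covariates = synthetic_data.generate_covariates(sites, seed=12)
    measurements = synthetic_data.generate_measurements(sites, covariates, seed=13)
    return sites, covariates, measurements


@pytest.fixture(scope="session")
def wqi_config():
    return configio.load_wqi_config()


@pytest.fixture(scope="session")
def class3_limits():
    return configio.load_class3_limits()


@pytest.fixture(scope="session")
def trophic_config():
    return configio.load_trophic_config()


@pytest.fixture(scope="session")
def exposure_model():
    return configio.load_exposure_model()


@pytest.fixture(scope="session")
def toxicity():
    return configio.load_toxicity()


def brute_force_q(y, labels):
    """Independent oracle: q as the between-strata share of the total sum
    of squares, accumulated group by group."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    ssb = 0.0
    for lab in pd.unique(labels):
        grp = y[labels == lab]
        ssb += grp.size * (grp.mean() - grand) ** 2
    return ssb / sst
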