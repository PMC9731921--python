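import numpy as np
import pandas as pd
import pytest

from camtrap_community import (
    CommunityHyperparams,
    StudyDesign,
    simulate_community,
)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared by fast model tests."""
    hyper = CommunityHyperparams(
        n_species_true=12, mu_lpsi=-1.0, sigma_lpsi=1.2, mu_lp=-2.0, sigma_lp=0.4
    )
    design = StudyDesign(
        n_stations=15, n_occasions=10, malfunction_rate=0.05, seed=7
    )
    truth, detection = simulate_community(hyper, design)
    return truth, detection


@pytest.fixture()
def events_table():
    """Hand-built raw capture records covering the filter edge cases."""
    rows = [
        # same station/species: 10:00 kept, 10:15 suppressed, 10:31 kept
        ("ST01", "leopard", "2020-04-01T10:00"),
        ("ST01", "leopard", "2020-04-01T10:15"),
        ("ST01", "leopard", "2020-04-01T10:31"),
        # different species at the same station never suppressed
        ("ST01", "jackal", "2020-04-01T10:05"),
        # same species at another station never suppressed
        ("ST02", "leopard", "2020-04-01T10:05"),
    ]
    return pd.DataFrame(rows, columns=["station_id", "species", "timestamp"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
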