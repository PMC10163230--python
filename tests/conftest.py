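import numpy as np
import pandas as pd
import pytest

import befcausal as bc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_raw():
    """Three plots with 6, 5 and 4 observed years; one of the 6 has bad biomass."""
    rows = []
    for plot, n_years in (("A1", 6), ("A2", 5), ("B1", 4)):
        site = plot[0]
        for t in range(n_years):
            rows.append(
                dict(site_id=site, plot_id=plot, year=2007 + t,
                     live_mass=100.0 + 10 * t, richness=3 + (t % 2))
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def confounded_panel():
    """One realization of the default confounded scenario, shared per module."""
    panel, truth = bc.simulate_panel(bc.scenario("confounded", seed=101))
    return panel, truth


def random_small_panel(seed, n_sites=3, plots_per_site=2, n_years=3):
    """Small random panel for dummy-regression oracle checks."""
    panel, _ = bc.simulate_panel(
        bc.scenario("confounded", seed=seed, n_sites=n_sites,
                    plots_per_site=plots_per_site, n_years=n_years)
    )
    return panel
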