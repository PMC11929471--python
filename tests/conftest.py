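import numpy as np
import pandas as pd
import pytest

from cotspred import simulate


@pytest.fixture(scope="session")
def survey_default():
    """One survey table at the default (study-shaped) design."""
    return simulate.generate_survey(simulate.SurveyConfig(seed=42))


@pytest.fixture(scope="session")
def trials_fixture():
    """Deterministic feeding-trial table (expected-count mode)."""
    return simulate.generate_feeding_trials(seed=7, exact=True)


@pytest.fixture(scope="session")
def screen_fixture():
    """Deterministic wild-screen table: 2/12 south, 7/63 north positive."""
    return simulate.generate_specimen_screen(seed=7, exact_counts=True)


def simulate_zinb_counts(
    seed,
    logmeans=(1.0, 0.2, 0.8),
    pi=0.3,
    theta=1.5,
    site_sd=0.25,
    sites_per_region=6,
    n_per_region=300,
):
    """Transect-shaped table with zero-inflated NB counts from known truth."""
    rng = np.random.default_rng(seed)
    rows = []
    for region, lm in zip(("south", "central", "north"), logmeans):
        site_eff = rng.normal(scale=site_sd, size=sites_per_region)
        for i in range(n_per_region):
            s = i % sites_per_region
            mu = np.exp(lm + site_eff[s])
            y = 0 if rng.uniform() < pi else rng.negative_binomial(theta, theta / (theta + mu))
            rows.append(
                {
                    "region": region,
                    "reef": f"{region}_reef",
                    "site": f"{region}_s{s}",
                    "area_m2": 100.0,
                    "count_s_aspera": int(y),
                }
            )
    return pd.DataFrame(rows)
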