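import numpy as np
import pandas as pd
import pytest

from nutripanel.synth import TrueParams, WorldConfig, generate_bookmarks, generate_world


@pytest.fixture(scope="session")
def small_config() -> WorldConfig:
    return WorldConfig(
        n_states=3,
        counties_per_state=4,
        users_per_county_mean=12.0,
        n_recipes=300,
        bookmark_rate=5.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_bookmarks(small_world, small_config):
    return generate_bookmarks(small_world, small_config)


@pytest.fixture(scope="session")
def intercepts_params() -> TrueParams:
    """Random-intercepts-only truth (no slopes, no covariates)."""
    return TrueParams(
        nutrition_coefficients={},
        state_slope_var=0.0,
        state_cov=0.0,
        county_slope_var=0.0,
        county_cov=0.0,
    )


@pytest.fixture
def hand_panel() -> pd.DataFrame:
    """Tiny hand-built county-year panel: 2 states x 2 counties x 3 years."""
    rows = []
    rng = np.random.default_rng(7)
    for sid in (1, 2):
        for cid in (sid * 1000 + 1, sid * 1000 + 2):
            for year in (2004, 2005, 2006):
                rows.append(
                    {
                        "state_id": sid,
                        "county_id": cid,
                        "year": year,
                        "year_centered": year - 2004,
                        "obesity": 20 + sid + 0.5 * (year - 2004) + rng.normal(0, 0.3),
                        "mean_fat": 10 + rng.normal(0, 1),
                        "mean_sugar": 12 + rng.normal(0, 1),
                        "fsa_score_of_means": int(rng.integers(6, 11)),
                    }
                )
    return pd.DataFrame(rows)
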