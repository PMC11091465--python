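"""Shared fixtures: small simulated cohorts and raw-data builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oxbalance import categorize_quartiles, score_cohort
from oxbalance.components import default_components
from oxbalance.simulate import SimulationConfig, generate_cohort

#: raw columns required by the default 22-component roster
RAW_SOURCE_COLUMNS = tuple(
    dict.fromkeys(
        c for spec in default_components() for c in spec.source_columns
    )
)
#: raw columns with a point mass at zero (abstention-rule sources)
ZERO_INFLATED = ("beef", "lamb", "pork", "smoking", "alcohol")


def random_raw_cohort(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Minimal random cohort carrying every scoring source column."""
    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "sex": rng.choice(["female", "male"], size=n),
        }
    )
    for col in RAW_SOURCE_COLUMNS:
        vals = rng.lognormal(mean=1.0, sigma=0.6, size=n)
        if col in ZERO_INFLATED:
            vals = np.where(rng.random(n) < 0.3, 0.0, vals)
        df[col] = vals
    return df


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition cohort at desk scale (n=4000, seed 123)."""
    return generate_cohort(SimulationConfig(n_participants=4000, seed=123))


@pytest.fixture(scope="session")
def scored_default(default_sim):
    return categorize_quartiles(score_cohort(default_sim.cohort))


@pytest.fixture(scope="session")
def strong_effect_scored():
    """Cohort with a strong OBS effect and high event rate, for power tests."""
    cfg = SimulationConfig(
        n_participants=8000,
        seed=77,
        beta_obs={"crc": -0.08},
        covariate_effects={},
        mediator_paths={},
        baseline_hazard_scale=0.01,
        missing_rates={},
    )
    sim = generate_cohort(cfg)
    return categorize_quartiles(score_cohort(sim.cohort))
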