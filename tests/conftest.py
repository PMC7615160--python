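"""Shared fixtures: tariffs and small synthetic cohorts.

All fixtures are generated programmatically; expensive cohorts are
session-scoped so several tests can share one generation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cvburden import default_config, generate_cohort

# property tests run derandomized so the suite is reproducible
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from cvburden.eq5d import DIMENSIONS, LEVELS, Tariff, toy_tariff
from cvburden.pipeline import cost_analysis_frame, qol_analysis_frame


@pytest.fixture(scope="session")
def tariff() -> Tariff:
    return toy_tariff()


@pytest.fixture(scope="session")
def uniform_tariff() -> Tariff:
    """Synthetic tariff with a flat 0.05 decrement per level above 1."""
    dec = {(d, lev): 0.05 * (lev - 1) for d in DIMENSIONS for lev in LEVELS}
    return Tariff(name="uniform-toy", decrements=dec)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter cohort at n=4000 (seed 20314)."""
    return generate_cohort(default_config(n_participants=4000, seed=20314))


@pytest.fixture(scope="session")
def small_qol_frame(small_cohort):
    return qol_analysis_frame(small_cohort.participants, small_cohort.events)


@pytest.fixture(scope="session")
def small_cost_frame(small_cohort):
    return cost_analysis_frame(small_cohort.participants, small_cohort.person_years)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(8675309)


def random_profiles(rng: np.random.Generator, n: int) -> pd.DataFrame:
    levels = rng.integers(1, 6, size=(n, 5))
    return pd.DataFrame(levels, columns=list(DIMENSIONS))
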