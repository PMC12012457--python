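"""Shared fixtures: small synthetic worlds and cohorts."""

import numpy as np
import pandas as pd
import pytest

from scholarmigrate import CohortConfig, build_world, simulate_cohort


@pytest.fixture(scope="session")
def world():
    """2 continents x 3 countries x 4 regions = 24 regions."""
    return build_world(2, 3, 4, seed=11)


@pytest.fixture(scope="session")
def clean_cohort(world):
    """Fully observed cohort: everyone publishes every year, one affiliation.

    Careers span the whole 1998-2017 window, so inference should recover
    the ground truth exactly.
    """
    config = CohortConfig(
        n_authors=500,
        year_start=1998,
        year_end=2017,
        career_start_low=1998,
        career_start_high=1998,
        career_length_mean=1e9,
        publish_prob=1.0,
        multi_affil_prob=0.0,
        internal_move_rate=0.02,
        international_move_rate=0.01,
        seed=42,
    )
    records, truth = simulate_cohort(world, config)
    return records, truth, config


@pytest.fixture(scope="session")
def noisy_cohort(world):
    """Realistic cohort: publication gaps, multiple affiliations, short careers."""
    config = CohortConfig(
        n_authors=400,
        year_start=1996,
        year_end=2020,
        publish_prob=0.75,
        multi_affil_prob=0.1,
        internal_move_rate=0.02,
        international_move_rate=0.01,
        seed=7,
    )
    records, truth = simulate_cohort(world, config)
    return records, truth, config


def timeline_frame(author, entries):
    """Build a residence-timeline frame from (year, region, country[, source])."""
    rows = []
    for e in entries:
        year, region, country = e[:3]
        source = e[3] if len(e) > 3 else "observed"
        rows.append((author, year, region, country, source))
    return pd.DataFrame(
        rows, columns=["author_id", "year", "region_id", "country_id", "source"]
    )


def records_frame(author, entries):
    """Build an affiliation-record frame from (year, region, country)."""
    return pd.DataFrame(
        [(author, y, r, c) for y, r, c in entries],
        columns=["author_id", "year", "region_id", "country_id"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
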