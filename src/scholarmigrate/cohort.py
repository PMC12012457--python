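"""Synthetic author cohorts with known ground-truth migration histories.

The generator emulates the structure of longitudinal bibliometric
author-affiliation data: each author has a career span inside the
observation window, publishes intermittently (so residence must sometimes
be inferred across gaps), occasionally lists a second affiliation in the
same year (so the modal rule is exercised), and relocates between regions
with configurable internal and international hazards that may drift over
time region by region.

Because every residence and move is recorded as ground truth, every
downstream inference stage can be validated exactly, without access to any
proprietary bibliometric database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from scholarmigrate.world import RegionRegistry

AFFILIATION_COLUMNS = ["author_id", "year", "region_id", "country_id"]
EVENT_COLUMNS = [
    "author_id",
    "year",
    "origin_region",
    "origin_country",
    "dest_region",
    "dest_country",
    "scope",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Hazards are per-author-year probabilities of a move; an author moves at
    most once per year, at the year boundary, so true residence is
    single-valued per calendar year.  ``region_trend`` maps region ids to a
    multiplicative annual change applied to both move hazards of authors
    resident there (1.0 = stationary).
    """

    n_authors: int = 1000
    year_start: int = 1996
    year_end: int = 2020
    career_start_low: int | None = None  # default: year_start
    career_start_high: int | None = None  # default: year_end
    career_length_mean: float = 12.0  # geometric mean length, clipped to span
    publish_prob: float = 0.7
    multi_affil_prob: float = 0.1
    multi_affil_international_split: float = 0.5
    internal_move_rate: float = 0.015
    international_move_rate: float = 0.008
    region_trend: Mapping[str, float] | None = None
    mix_move_year: bool = False  # if True, pre-move records may appear in move year
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_authors < 1:
            raise ValueError("n_authors must be >= 1")
        if self.year_end < self.year_start:
            raise ValueError("empty year span")
        for name in ("publish_prob", "multi_affil_prob", "multi_affil_international_split"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("internal_move_rate", "international_move_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.career_length_mean < 1:
            raise ValueError("career_length_mean must be >= 1")


@dataclass
class GroundTruth:
    """True residences, migration events and per-region-year flow tallies."""

    residence: pd.DataFrame = field(repr=False)  # author_id, year, region_id, country_id
    events: pd.DataFrame = field(repr=False)  # EVENT_COLUMNS
    flows: pd.DataFrame = field(repr=False)  # region_id, year, I_*, E_* tallies

    def to_csv(self, residence_path, events_path) -> None:
        self.residence.to_csv(residence_path, index=False)
        self.events.to_csv(events_path, index=False)


def _tally_flows(events: pd.DataFrame) -> pd.DataFrame:
    """Tally per-region-year inflow/outflow counts by scope from an event list."""
    empty = pd.DataFrame(
        columns=["region_id", "year", "I_internal", "E_internal",
                 "I_international", "E_international"]
    )
    if events.empty:
        return empty
    cells = []
    for scope in ("internal", "international"):
        sub = events.loc[events["scope"] == scope]
        inn = (
            sub.groupby(["dest_region", "year"]).size().rename(f"I_{scope}")
        ).rename_axis(["region_id", "year"])
        out = (
            sub.groupby(["origin_region", "year"]).size().rename(f"E_{scope}")
        ).rename_axis(["region_id", "year"])
        cells.extend([inn, out])
    flows = pd.concat(cells, axis=1).fillna(0).astype(int).reset_index()
    return flows.sort_values(["region_id", "year"]).reset_index(drop=True)


def simulate_cohort(
    registry: RegionRegistry, config: CohortConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate author careers and return (affiliation records, ground truth).

    Mechanics, per author:

    - career start uniform on ``[career_start_low, career_start_high]``,
      length Geometric with mean ``career_length_mean``, clipped to the
      year span;
    - initial residence uniform over regions;
    - each year after the first, an internal move with hazard
      ``internal_move_rate * m_r(t)`` or an international move with hazard
      ``international_move_rate * m_r(t)`` (competing risks, at most one
      move), where ``m_r(t)`` is the region trend multiplier compounded
      from ``year_start``; destinations are uniform over eligible regions;
    - each active year publishes with probability ``publish_prob`` (one
      record at the true residence); if no year published, the first active
      year is forced so every author leaves at least one record;
    - a published year gains a second, non-residence affiliation with
      probability ``multi_affil_prob``: a different country with probability
      ``multi_affil_international_split``, else a different region of the
      same country when one exists.

    A move in year *t* means the author's residence is the new region from
    *t* onward; by default all of the move year's records carry the new
    region (``mix_move_year=True`` instead emits pre-move records at the
    old region with probability 1/2, mimicking mid-year transitions).
    """
    if len(registry) == 0:
        raise ValueError("registry must contain at least one region")

    rng = np.random.default_rng(config.seed)
    regions = np.array(registry.regions)
    r2c = registry.region_to_country()
    by_country: dict[str, np.ndarray] = {
        c: np.array(registry.regions_in_country(c)) for c in registry.countries
    }
    countries = np.array(registry.countries)
    trend = dict(config.region_trend or {})

    start_low = config.career_start_low if config.career_start_low is not None else config.year_start
    start_high = config.career_start_high if config.career_start_high is not None else config.year_end
    if not (config.year_start <= start_low <= start_high <= config.year_end):
        raise ValueError("career start bounds must lie inside the year span")

    records: list[tuple] = []
    residences: list[tuple] = []
    events: list[tuple] = []

    for a in range(config.n_authors):
        author = f"A{a:06d}"
        start = int(rng.integers(start_low, start_high + 1))
        length = int(rng.geometric(1.0 / config.career_length_mean))
        end = min(start + length - 1, config.year_end)
        region = str(rng.choice(regions))

        publish_years = []
        for year in range(start, end + 1):
            moved_this_year = False
            if year > start:
                mult = trend.get(region, 1.0) ** (year - config.year_start)
                p_int = min(config.internal_move_rate * mult, 1.0)
                p_intl = min(config.international_move_rate * mult, 1.0)
                total = p_int + p_intl
                if total > 1.0:  # competing risks need a proper split
                    p_int, p_intl = p_int / total, p_intl / total
                u = rng.random()
                origin = region
                country = r2c[origin]
                if u < p_int:
                    others = by_country[country][by_country[country] != origin]
                    if len(others):
                        region = str(rng.choice(others))
                        events.append(
                            (author, year, origin, country, region, country, "internal")
                        )
                        moved_this_year = True
                elif u < p_int + p_intl:
                    other_countries = countries[countries != country]
                    if len(other_countries):
                        dest_country = str(rng.choice(other_countries))
                        region = str(rng.choice(by_country[dest_country]))
                        events.append(
                            (author, year, origin, country, region, dest_country,
                             "international")
                        )
                        moved_this_year = True

            residences.append((author, year, region, r2c[region]))

            if rng.random() < config.publish_prob:
                publish_years.append((year, region, moved_this_year))
        if not publish_years:
            # force one record so every author appears in the data
            first_res = next(r for r in residences if r[0] == author)
            publish_years.append((first_res[1], first_res[2], False))

        for year, region_y, moved in publish_years:
            rec_region = region_y
            if config.mix_move_year and moved and rng.random() < 0.5:
                # pre-move publication still carries the origin affiliation
                prev = [r for r in residences if r[0] == author and r[1] == year - 1]
                if prev:
                    rec_region = prev[0][2]
            records.append((author, year, rec_region, r2c[rec_region]))
            if rng.random() < config.multi_affil_prob:
                country = r2c[rec_region]
                if rng.random() < config.multi_affil_international_split:
                    other_countries = countries[countries != country]
                    if len(other_countries):
                        oc = str(rng.choice(other_countries))
                        extra = str(rng.choice(by_country[oc]))
                        records.append((author, year, extra, oc))
                else:
                    others = by_country[country][by_country[country] != rec_region]
                    if len(others):
                        extra = str(rng.choice(others))
                        records.append((author, year, extra, country))

    records_df = pd.DataFrame(records, columns=AFFILIATION_COLUMNS)
    records_df = records_df.sort_values(["author_id", "year"]).reset_index(drop=True)
    residence_df = pd.DataFrame(
        residences, columns=["author_id", "year", "region_id", "country_id"]
    )
    events_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    truth = GroundTruth(
        residence=residence_df, events=events_df, flows=_tally_flows(events_df)
    )
    return records_df, truth
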