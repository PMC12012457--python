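"""Modal-residence inference and migration-event detection.

An author's residence in a calendar year is defined as the *modal*
affiliation country of that year's publications, and, within the modal
country, the modal region.  Ties are broken in favour of the tied option
held in the closest previous residence year; a tie among entirely new
options is resolved uniformly at random from a seeded stream so the whole
pipeline is reproducible.

Publication gaps are bridged with a two-year backward fill: a publication
observed after a gap is taken as evidence that the author already resided
at the new location up to two years earlier (publication preparation
delay), so the last ``min(gap, 2)`` years of the gap inherit the later
residence.  A migration event is dated to the first year carrying the new
residence, and classified internal (same country, different region) or
international (different country).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from scholarmigrate.world import RegionRegistry

RESIDENCE_COLUMNS = ["author_id", "year", "region_id", "country_id", "source"]
EVENT_COLUMNS = [
    "author_id",
    "year",
    "origin_region",
    "origin_country",
    "dest_region",
    "dest_country",
    "scope",
]

#: maximum number of years of a publication gap inherited from the later
#: observation (publication preparation delay)
BACKFILL_YEARS = 2


def _break_tie(
    tied: list[str],
    year: int,
    prior: Mapping[int, str],
    rng: np.random.Generator,
) -> str:
    """Resolve a modal tie: closest previous residence wins, else random.

    Scans year-1, year-2, ... down to the earliest prior residence year;
    the first prior residence found among the tied options is returned.
    If none of the tied options ever was a residence, one is drawn
    uniformly at random (sorted first, so the draw is label-order
    independent of input ordering).
    """
    tied_set = set(tied)
    if prior:
        for y in range(year - 1, min(prior) - 1, -1):
            r = prior.get(y)
            if r in tied_set:
                return r
    return str(rng.choice(sorted(tied_set)))


def modal_country(
    year_affiliations: Iterable[str],
    prior_residences: Mapping[int, str],
    year: int,
    rng: np.random.Generator,
) -> str:
    """Modal affiliation country of one author-year.

    Parameters
    ----------
    year_affiliations
        Multiset of country ids attached to the author's publications in
        ``year`` (one entry per affiliation, repeats meaningful).
    prior_residences
        Mapping of earlier years to the already-inferred residence country,
        used for tie-breaking.
    year
        The calendar year being resolved.
    rng
        Seeded generator for ties among entirely new countries.
    """
    counts = Counter(year_affiliations)
    if not counts:
        raise ValueError("year_affiliations must be non-empty")
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    return _break_tie(tied, year, prior_residences, rng)


def modal_region(
    year_affiliations: Iterable[tuple[str, str]],
    modal_country_id: str,
    prior_residences: Mapping[int, str],
    year: int,
    rng: np.random.Generator,
) -> str:
    """Modal region among the year's affiliations *within* the modal country.

    Restricting to the modal country guarantees the inferred region is
    consistent with the inferred country.  ``prior_residences`` maps earlier
    years to residence *regions*.
    """
    counts = Counter(
        region for region, country in year_affiliations if country == modal_country_id
    )
    if not counts:
        raise RuntimeError(
            f"no affiliation in modal country {modal_country_id!r}: "
            "modal_country and modal_region saw different data"
        )
    top = max(counts.values())
    tied = [r for r, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    return _break_tie(tied, year, prior_residences, rng)


def build_residence_timeline(
    records: pd.DataFrame, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Infer one author's annual residence timeline from affiliation records.

    ``records`` holds all of one author's rows (columns ``author_id, year,
    region_id, country_id``).  Observed years get modal residences; for each
    observed year *y* preceded by a gap, years *y-1* and *y-2* (as far as the
    gap extends) are backfilled with *y*'s residence.  Years deeper than two
    into a gap stay unassigned, and nothing before the first observed year
    is ever filled.

    Returns a frame with columns ``author_id, year, region_id, country_id,
    source`` (``observed`` or ``backfilled``), sorted by year, one row per
    year.
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    authors = records["author_id"].unique()
    if len(authors) != 1:
        raise ValueError("build_residence_timeline expects a single author")
    author = authors[0]
    if rng is None:
        rng = np.random.default_rng(0)

    prior_country: dict[int, str] = {}
    prior_region: dict[int, str] = {}
    observed: list[tuple[int, str, str]] = []
    for year, grp in records.sort_values("year").groupby("year", sort=True):
        year = int(year)
        country = modal_country(grp["country_id"], prior_country, year, rng)
        region = modal_region(
            list(zip(grp["region_id"], grp["country_id"])),
            country,
            prior_region,
            year,
            rng,
        )
        prior_country[year] = country
        prior_region[year] = region
        observed.append((year, region, country))

    rows = [(author, y, r, c, "observed") for y, r, c in observed]
    for (prev_year, _, _), (year, region, country) in zip(observed, observed[1:]):
        for fy in range(max(prev_year + 1, year - BACKFILL_YEARS), year):
            rows.append((author, fy, region, country, "backfilled"))
    out = pd.DataFrame(rows, columns=RESIDENCE_COLUMNS)
    return out.sort_values("year").reset_index(drop=True)


def detect_migration_events(
    timeline: pd.DataFrame, registry: RegionRegistry | None = None
) -> pd.DataFrame:
    """Detect dated migration events in one author's residence timeline.

    One event is emitted for each consecutive pair of residence years whose
    region differs; the migration year is the first year carrying the new
    residence.  Scope is ``internal`` when the countries match and
    ``international`` otherwise.  When a registry is supplied, every
    timeline row is validated against it.
    """
    if timeline.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    if timeline["year"].duplicated().any():
        raise ValueError("timeline has duplicate years")
    t = timeline.sort_values("year").reset_index(drop=True)
    if registry is not None:
        r2c = registry.region_to_country()
        for region, country in zip(t["region_id"], t["country_id"]):
            if r2c.get(region) != country:
                raise ValueError(
                    f"timeline row ({region}, {country}) inconsistent with registry"
                )
    events = []
    for i in range(1, len(t)):
        prev, cur = t.iloc[i - 1], t.iloc[i]
        if cur["region_id"] == prev["region_id"]:
            continue
        scope = (
            "internal" if cur["country_id"] == prev["country_id"] else "international"
        )
        events.append(
            (
                cur["author_id"],
                int(cur["year"]),
                prev["region_id"],
                prev["country_id"],
                cur["region_id"],
                cur["country_id"],
                scope,
            )
        )
    out = pd.DataFrame(events, columns=EVENT_COLUMNS)
    out["year"] = out["year"].astype(int)
    return out


def censor_window(
    table: pd.DataFrame, first_year: int = 1998, last_year: int = 2017
) -> pd.DataFrame:
    """Keep rows with ``first_year <= year <= last_year`` (inclusive bounds).

    The default window trims the edges of a 1996–2020 observation span to
    limit left- and right-censoring artifacts: events near the span edges
    are systematically under-detected because the modal rule needs
    observations on both sides of a move.
    """
    if first_year > last_year:
        raise ValueError(f"inverted window: {first_year} > {last_year}")
    return table.loc[
        (table["year"] >= first_year) & (table["year"] <= last_year)
    ].reset_index(drop=True)


def infer_residences(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Infer residence timelines for every author in an affiliation table.

    A single named random stream (derived from ``seed``) serves all
    tie-breaks, processed in sorted author order, so runs are reproducible.
    """
    required = {"author_id", "year", "region_id", "country_id"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"affiliation table missing columns: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E51DE]))
    parts = [
        build_residence_timeline(grp, rng)
        for _, grp in records.sort_values(["author_id", "year"]).groupby(
            "author_id", sort=True
        )
    ]
    return pd.concat(parts, ignore_index=True)


def infer_events(
    residences: pd.DataFrame, registry: RegionRegistry | None = None
) -> pd.DataFrame:
    """Detect migration events for every author in a residence table."""
    parts = [
        detect_migration_events(grp, registry)
        for _, grp in residences.groupby("author_id", sort=True)
    ]
    if not parts:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(parts, ignore_index=True)
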