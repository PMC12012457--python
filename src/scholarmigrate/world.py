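"""Synthetic world geography: a region → country → continent hierarchy.

Regions play the role of first-level subnational administrative units
(states/provinces); each region belongs to exactly one country and each
country to exactly one continent.  Countries may additionally carry an
alternative grouping label (e.g. an income class) so that downstream
inequality analyses can group by something other than continent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGISTRY_COLUMNS = ["region_id", "country_id", "continent_id", "group_label"]

#: default alternative grouping labels, assigned per country
DEFAULT_GROUP_LABELS = ("low-income", "middle-income", "high-income")


@dataclass(frozen=True)
class RegionRegistry:
    """Lookup table mapping every region to its country and continent.

    Invariants (validated on construction): region ids are globally unique,
    each region maps to exactly one country and each country to exactly one
    continent.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REGISTRY_COLUMNS[:3] if c not in t.columns]
        if missing:
            raise ValueError(f"registry missing columns: {missing}")
        if t["region_id"].duplicated().any():
            dupes = t.loc[t["region_id"].duplicated(), "region_id"].tolist()
            raise ValueError(f"duplicate region ids: {dupes}")
        cc = t[["country_id", "continent_id"]].drop_duplicates()
        if cc["country_id"].duplicated().any():
            raise ValueError("a country maps to more than one continent")
        if "group_label" not in t.columns:
            object.__setattr__(
                self, "table", t.assign(group_label=pd.NA).loc[:, REGISTRY_COLUMNS]
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def regions(self) -> list[str]:
        return self.table["region_id"].tolist()

    @property
    def countries(self) -> list[str]:
        return self.table["country_id"].unique().tolist()

    @property
    def continents(self) -> list[str]:
        return self.table["continent_id"].unique().tolist()

    def country_of(self, region_id: str) -> str:
        row = self.table.loc[self.table["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region: {region_id}")
        return row["country_id"].iloc[0]

    def regions_in_country(self, country_id: str) -> list[str]:
        return self.table.loc[
            self.table["country_id"] == country_id, "region_id"
        ].tolist()

    def region_to_country(self) -> dict[str, str]:
        return dict(zip(self.table["region_id"], self.table["country_id"]))

    def region_to_continent(self) -> dict[str, str]:
        return dict(zip(self.table["region_id"], self.table["continent_id"]))

    def region_to_group(self) -> dict[str, str]:
        return dict(zip(self.table["region_id"], self.table["group_label"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionRegistry":
        return cls(pd.read_csv(path, dtype=str))


def build_world(
    n_continents: int,
    countries_per_continent: int,
    regions_per_country: int,
    seed: int = 0,
    group_labels: tuple[str, ...] | None = DEFAULT_GROUP_LABELS,
) -> RegionRegistry:
    """Build a balanced synthetic geography.

    Produces ``n_continents * countries_per_continent * regions_per_country``
    regions with deterministic hierarchical ids (``CT1.CN2.R3`` lives in
    country ``CT1.CN2`` on continent ``CT1``).  If ``group_labels`` is given,
    each country is assigned one label uniformly at random from it using
    ``seed`` — the only stochastic element, so two calls with equal arguments
    produce identical registries.
    """
    for name, n in (
        ("n_continents", n_continents),
        ("countries_per_continent", countries_per_continent),
        ("regions_per_country", regions_per_country),
    ):
        if n < 1:
            raise ValueError(f"{name} must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_continents + 1):
        continent = f"CT{c}"
        for k in range(1, countries_per_continent + 1):
            country = f"{continent}.CN{k}"
            label = rng.choice(group_labels) if group_labels else pd.NA
            for r in range(1, regions_per_country + 1):
                rows.append((f"{country}.R{r}", country, continent, label))
    return RegionRegistry(pd.DataFrame(rows, columns=REGISTRY_COLUMNS))
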