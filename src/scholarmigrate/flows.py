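"""Region-year populations, directed migration flows, rates and NMR.

The scholar population ``N`` of a region-year is the number of distinct
authors resident there (observed or backfilled).  Each migration event
contributes one outflow at its origin and one inflow at its destination in
its scope (internal/international), in its migration year.  The net
migration rate over a period is

    NMR = 1000 * (sum of inflows - sum of outflows) / (sum of N),

a per-1,000-scholars-per-year rate: person-years accumulate in the
denominator, so a multi-year period automatically yields an annual rate.

Region-years with ``N = 0`` but nonzero flows can occur (e.g. a move into a
region whose population is otherwise unobserved); rates there are undefined
and flagged rather than set to zero — 0/0 is not evidence of zero
migration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scholarmigrate.world import RegionRegistry

FLOW_COLUMNS = [
    "region_id",
    "year",
    "N",
    "I_internal",
    "I_international",
    "E_internal",
    "E_international",
    "I_total",
    "E_total",
]

SCOPES = ("internal", "international", "total")
MIGRATION_TYPES = [f"{scope}-{d}" for scope in SCOPES for d in ("in", "out")]


def _scope_cols(scope: str, direction: str | None = None) -> tuple[str, str] | str:
    if scope not in SCOPES:
        raise ValueError(f"unknown scope: {scope!r}")
    if direction is None:
        return f"I_{scope}", f"E_{scope}"
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    return (f"I_{scope}" if direction == "in" else f"E_{scope}")


def tabulate_flows(
    residences: pd.DataFrame,
    events: pd.DataFrame,
    registry: RegionRegistry,
) -> pd.DataFrame:
    """Aggregate residences and events into a region-year flow table.

    ``N`` counts distinct authors per region-year; each event increments
    exactly one inflow cell (destination, year) and one outflow cell
    (origin, year) in its scope.  The output covers the union of region-years
    seen in either input; events referencing regions absent from the
    registry raise.
    """
    known = set(registry.regions)
    for col in ("origin_region", "dest_region"):
        if len(events):
            bad = set(events[col]) - known
            if bad:
                raise ValueError(f"events reference unknown regions: {sorted(bad)}")
    unknown_res = set(residences["region_id"]) - known
    if unknown_res:
        raise ValueError(f"residences reference unknown regions: {sorted(unknown_res)}")

    n = (
        residences.groupby(["region_id", "year"])["author_id"]
        .nunique()
        .rename("N")
    )
    parts = [n]
    for scope in ("internal", "international"):
        sub = events.loc[events["scope"] == scope] if len(events) else events
        if len(sub):
            parts.append(
                sub.groupby(["dest_region", "year"])
                .size()
                .rename(f"I_{scope}")
                .rename_axis(["region_id", "year"])
            )
            parts.append(
                sub.groupby(["origin_region", "year"])
                .size()
                .rename(f"E_{scope}")
                .rename_axis(["region_id", "year"])
            )
    flows = pd.concat(parts, axis=1)
    for col in ("I_internal", "I_international", "E_internal", "E_international"):
        if col not in flows.columns:
            flows[col] = 0
    flows = flows.fillna(0).astype(int).reset_index()
    flows["I_total"] = flows["I_internal"] + flows["I_international"]
    flows["E_total"] = flows["E_internal"] + flows["E_international"]
    return (
        flows.loc[:, FLOW_COLUMNS]
        .sort_values(["region_id", "year"])
        .reset_index(drop=True)
    )


def annual_nmr(flows: pd.DataFrame, scope: str = "total") -> pd.DataFrame:
    """Annual net migration rate per 1,000 scholars, one row per region-year.

    Rows with ``N = 0`` get ``nmr = NaN`` and ``undefined = True``.
    """
    i_col, e_col = _scope_cols(scope)
    out = flows.loc[:, ["region_id", "year"]].copy()
    out["period_start"] = flows["year"]
    out["period_end"] = flows["year"]
    out["scope"] = scope
    with np.errstate(divide="ignore", invalid="ignore"):
        out["nmr_per_1000"] = np.where(
            flows["N"] > 0,
            1000.0 * (flows[i_col] - flows[e_col]) / flows["N"],
            np.nan,
        )
    out["undefined"] = flows["N"] == 0
    return out.drop(columns="year")


def period_nmr(
    flows: pd.DataFrame, period: tuple[int, int], scope: str = "total"
) -> pd.DataFrame:
    """Period-averaged net migration rate per 1,000 scholars per year.

    Flows and person-years are summed over ``period`` (inclusive); a region
    "exists" in the period if it has any scholars in any of its years.
    Regions with zero person-years over the whole period are flagged
    undefined.
    """
    start, end = period
    if start > end:
        raise ValueError(f"inverted period: {period}")
    i_col, e_col = _scope_cols(scope)
    sub = flows.loc[(flows["year"] >= start) & (flows["year"] <= end)]
    agg = sub.groupby("region_id")[[i_col, e_col, "N"]].sum().reset_index()
    out = agg.loc[:, ["region_id"]].copy()
    out["period_start"] = start
    out["period_end"] = end
    out["scope"] = scope
    with np.errstate(divide="ignore", invalid="ignore"):
        out["nmr_per_1000"] = np.where(
            agg["N"] > 0, 1000.0 * (agg[i_col] - agg[e_col]) / agg["N"], np.nan
        )
    out["undefined"] = agg["N"] == 0
    return out


def annual_rates(
    flows: pd.DataFrame, direction: str, scope: str
) -> pd.DataFrame:
    """Annual migration rate (events per scholar) per region-year.

    ``rate = count / N`` for the requested direction ('in' uses inflows,
    'out' outflows) and scope; undefined (NaN, flagged) where ``N = 0``.
    The population column is carried along because it doubles as the
    weight in the inequality analyses.
    """
    col = _scope_cols(scope, direction)
    out = flows.loc[:, ["region_id", "year", "N"]].copy()
    out["direction"] = direction
    out["scope"] = scope
    out["count"] = flows[col]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rate"] = np.where(flows["N"] > 0, flows[col] / flows["N"], np.nan)
    out["undefined"] = flows["N"] == 0
    return out


def rates_long(flows: pd.DataFrame) -> pd.DataFrame:
    """All six migration-rate series (3 scopes x in/out) in long form.

    Adds a ``migration_type`` label like ``internal-in`` used by the Gini
    and interrelation analyses.
    """
    parts = []
    for scope in SCOPES:
        for direction in ("in", "out"):
            r = annual_rates(flows, direction, scope)
            r["migration_type"] = f"{scope}-{direction}"
            parts.append(r)
    return pd.concat(parts, ignore_index=True)
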