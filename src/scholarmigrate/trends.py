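"""Per-region quasi-Poisson time trends of migration rates.

Each eligible region-series (in/out x internal/international) is modelled
as a log-linear rate trend

.. math::

    E[y_t] = N_t \\exp(\\alpha + \\beta t),

i.e. a Poisson log-link GLM of the event counts with the log scholar
population as exposure offset.  Standard errors are inflated by the
Pearson-based quasi-Poisson dispersion
:math:`\\hat\\varphi = \\chi^2_{Pearson} / (n - 2)` to accommodate the
overdispersion typical of migration counts.  The fitted slope lives on the
linear-predictor (log) scale; ``transform_slope`` maps it to the percent
change per year, :math:`T(x) = 100(e^x - 1)`.

Eligibility follows three conjunctive filters: a region must exceed 25
scholars in at least one observation year, have at least 10 observation
years, and at least 5 years with a nonzero migration count.  A stricter
alternative parsing (at least 10 years each with counts >= the threshold)
is exposed via :class:`EligibilityRule.parsing`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from scholarmigrate.flows import _scope_cols

TREND_COLUMNS = [
    "region_id",
    "direction",
    "scope",
    "slope",
    "se",
    "dispersion",
    "n_years",
    "slope_pct_per_year",
]


def transform_slope(x) -> np.ndarray | float:
    """Percent change per year implied by a log-scale slope: 100*(exp(x)-1).

    T(0) = 0 (no change); T(ln 1.2) = 20 (a 20% annual increase);
    T(-0.2231) = -20 (a 20% annual decrease).  Strictly increasing.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("slope must be finite")
    out = 100.0 * np.expm1(x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EligibilityRule:
    """Region filters applied before trend fitting.

    ``parsing="conjunctive"`` (default) reads the three thresholds as
    independent conditions: peak population strictly above
    ``min_peak_scholars``, at least ``min_obs_years`` observation years,
    and at least ``min_nonzero_years`` years with a nonzero count.
    ``parsing="joint"`` is the stricter alternative: at least
    ``min_obs_years`` years each with a count of at least
    ``min_nonzero_years`` events.
    """

    min_peak_scholars: int = 25
    min_obs_years: int = 10
    min_nonzero_years: int = 5
    parsing: str = "conjunctive"

    def __post_init__(self) -> None:
        for name in ("min_peak_scholars", "min_obs_years", "min_nonzero_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.parsing not in ("conjunctive", "joint"):
            raise ValueError(f"parsing must be 'conjunctive' or 'joint', got {self.parsing!r}")


def eligible_regions(
    flows: pd.DataFrame,
    rule: EligibilityRule = EligibilityRule(),
    direction: str = "in",
    scope: str = "internal",
) -> set[str]:
    """Regions passing the eligibility filters for one count series.

    Observation years are region-years with a positive scholar population;
    the nonzero-count condition is evaluated on the requested series
    (direction x scope), so eligibility can differ between series.
    """
    col = _scope_cols(scope, direction)
    obs = flows.loc[flows["N"] > 0]
    keep = set()
    for region, grp in obs.groupby("region_id"):
        if grp["N"].max() <= rule.min_peak_scholars:  # strict "more than"
            continue
        if len(grp) < rule.min_obs_years:
            continue
        if rule.parsing == "conjunctive":
            if (grp[col] > 0).sum() < rule.min_nonzero_years:
                continue
        else:
            if (grp[col] >= rule.min_nonzero_years).sum() < rule.min_obs_years:
                continue
        keep.add(region)
    return keep


class TrendResults:
    """Fitted quasi-Poisson trend for one region-series.

    Attributes
    ----------
    slope, se : float
        Annual change of the log rate and its dispersion-inflated SE.
    dispersion : float
        Pearson quasi-Poisson dispersion estimate, chi2/(n-2).
    intercept : float
        Log rate at the (centered) time origin.
    n_years : int
        Years used in the fit.
    """

    def __init__(self, model, glm_results, phi: float):
        self.model = model
        self._res = glm_results
        self.intercept = float(glm_results.params[0])
        self.slope = float(glm_results.params[1])
        # quasi-Poisson: Poisson-ML SE inflated by the Pearson dispersion
        self.se = float(np.sqrt(phi) * glm_results.bse[1])
        self.dispersion = phi
        self.n_years = int(glm_results.nobs)

    @property
    def slope_pct_per_year(self) -> float:
        return transform_slope(self.slope)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Wald interval for the slope on the log scale."""
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        return (self.slope - z * self.se, self.slope + z * self.se)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Quasi-Poisson log-linear trend",
            "==============================",
            f"observations (years): {self.n_years}",
            f"dispersion phi:       {self.dispersion:.4f}",
            f"slope (log scale):    {self.slope:.5f}  (SE {self.se:.5f})",
            f"  95% CI:             [{lo:.5f}, {hi:.5f}]",
            f"percent change/year:  {self.slope_pct_per_year:.2f}%",
        ]
        return "\n".join(lines)


class QuasiPoissonTrend:
    """Log-linear time-trend model for one region's annual event counts.

    Parameters
    ----------
    counts
        Annual migration event counts.
    exposures
        Matching scholar populations N_t (the exposure); years with N = 0
        are dropped rather than given an infinite offset.
    years
        Calendar years; centered at their midpoint before fitting for
        numerical stability (the slope is unaffected).
    """

    def __init__(self, counts, exposures, years, center: bool = True):
        counts = np.asarray(counts, dtype=float)
        exposures = np.asarray(exposures, dtype=float)
        years = np.asarray(years, dtype=float)
        if not (len(counts) == len(exposures) == len(years)):
            raise ValueError("counts, exposures and years must be equally long")
        usable = exposures > 0
        counts, exposures, years = counts[usable], exposures[usable], years[usable]
        if len(counts) < 3:
            raise ValueError("need at least 3 usable years")
        if np.all(counts == 0):
            raise ValueError("all counts zero: no information about a trend")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        self.counts = counts
        self.exposures = exposures
        self.years = years
        self._t = years - (years.min() + years.max()) / 2.0 if center else years

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> TrendResults:
        """Fit by IRLS; SEs scaled by the Pearson dispersion."""
        X = sm.add_constant(self._t)
        glm = sm.GLM(
            self.counts,
            X,
            family=sm.families.Poisson(),
            offset=np.log(self.exposures),
        )
        res = glm.fit(maxiter=maxiter, tol=tol)
        if not res.converged:
            raise RuntimeError(
                f"IRLS did not converge in {maxiter} iterations "
                f"(deviance {res.deviance:.3g})"
            )
        n = len(self.counts)
        phi = float(res.pearson_chi2 / (n - 2))
        return TrendResults(self, res, phi)


def fit_quasipoisson_trend(counts, exposures, years, **fit_kwargs) -> TrendResults:
    """Convenience wrapper: build a :class:`QuasiPoissonTrend` and fit it."""
    return QuasiPoissonTrend(counts, exposures, years).fit(**fit_kwargs)


def fit_region_trends(
    flows: pd.DataFrame,
    rule: EligibilityRule = EligibilityRule(),
    window: tuple[int, int] = (1998, 2017),
) -> pd.DataFrame:
    """Fit all four trend series for every eligible region.

    Returns one row per (region, direction, scope) that passed eligibility
    and produced a converged fit, with the slope, its SE, the dispersion,
    and the percent-per-year transform of the slope.
    """
    start, end = window
    sub = flows.loc[(flows["year"] >= start) & (flows["year"] <= end)]
    rows = []
    for direction in ("in", "out"):
        for scope in ("internal", "international"):
            col = _scope_cols(scope, direction)
            keep = eligible_regions(sub, rule, direction, scope)
            for region in sorted(keep):
                grp = sub.loc[(sub["region_id"] == region) & (sub["N"] > 0)]
                try:
                    res = fit_quasipoisson_trend(
                        grp[col].to_numpy(),
                        grp["N"].to_numpy(),
                        grp["year"].to_numpy(),
                    )
                except (ValueError, RuntimeError):
                    continue
                rows.append(
                    (
                        region,
                        direction,
                        scope,
                        res.slope,
                        res.se,
                        res.dispersion,
                        res.n_years,
                        res.slope_pct_per_year,
                    )
                )
    return pd.DataFrame(rows, columns=TREND_COLUMNS)
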