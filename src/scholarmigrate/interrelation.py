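"""Interrelation of internal and international migration.

Three complementary views:

- **Kendall tau-b** rank correlations between a region's internal and
  international annual migration rates (tie-corrected, because small
  regions produce many zero-rate ties);
- **quadrant fractions** of regions by the signs of paired statistics
  (e.g. internal vs. international trend slopes), with exact zeros
  reported in a separate bucket;
- a **Bayesian errors-in-variables (EIV) regression** of internal trend
  slopes on international trend slopes that propagates the known standard
  errors of both.

The EIV model treats the observed slopes as noisy measurements of latent
values: ``x_i ~ N(xi_i, x_se_i^2)`` and ``y_i ~ N(alpha + beta*xi_i,
y_se_i^2 + sigma^2)``, with a hierarchical Normal prior
``xi_i ~ N(mu, tau^2)`` on the latent predictor.  The latents are
marginalised analytically — each pair (x_i, y_i) is bivariate Gaussian
given ``(alpha, beta, mu, tau, sigma)`` — so the MCMC (an affine-invariant
ensemble sampler) explores only five parameters.  The slope is declared
significant when its central 95% credible interval excludes zero.  Unlike
ordinary least squares on the observed slopes, which attenuates the slope
toward zero when the predictor is noisy, the EIV posterior targets the
relation between the latent quantities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy import stats

KENDALL_COLUMNS = ["region_id", "tau_in", "tau_out", "n_years", "undefined"]


def kendall_tau(x, y) -> float:
    """Kendall tau-b rank correlation (tie-corrected) between two series.

    Returns NaN (the undefined-tau signal) when either series is constant,
    which happens e.g. for regions with zero international migration
    throughout the window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def region_tau_pairs(
    rates: pd.DataFrame, window: tuple[int, int] = (1998, 2017)
) -> pd.DataFrame:
    """Per-region tau between internal and international annual rates.

    ``rates`` is the long table from :func:`scholarmigrate.flows.rates_long`.
    ``tau_in`` correlates the internal-in with the international-in series,
    ``tau_out`` the out-migration counterparts, over years in ``window``
    where both rates are defined.  Regions where either tau is undefined
    (constant series, or fewer than 3 usable years) are flagged.
    """
    start, end = window
    sub = rates.loc[
        (rates["year"] >= start) & (rates["year"] <= end) & rates["rate"].notna()
    ]
    wide = sub.pivot_table(
        index=["region_id", "year"], columns="migration_type", values="rate"
    )
    rows = []
    for region, grp in wide.groupby(level="region_id"):
        taus = {}
        n_years = 0
        for d in ("in", "out"):
            cols = [f"internal-{d}", f"international-{d}"]
            if not all(c in grp.columns for c in cols):
                taus[d] = float("nan")
                continue
            pair = grp[cols].dropna()
            if d == "in":
                n_years = len(pair)
            if len(pair) < 3:
                taus[d] = float("nan")
                continue
            taus[d] = kendall_tau(pair[cols[0]].to_numpy(), pair[cols[1]].to_numpy())
        undefined = bool(np.isnan(taus["in"]) or np.isnan(taus["out"]))
        rows.append((region, taus["in"], taus["out"], n_years, undefined))
    return pd.DataFrame(rows, columns=KENDALL_COLUMNS)


def quadrant_fractions(x, y) -> dict[str, float]:
    """Percentage of points per sign quadrant, zeros bucketed separately.

    Keys: ``pos_pos`` (x>0, y>0), ``neg_pos`` (x<0, y>0), ``neg_neg``,
    ``pos_neg``, and ``zero`` for points with either coordinate exactly 0.
    The five percentages sum to 100 exactly, so the four quadrants alone
    may sum to less than 100 when zeros are present.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("x and y must be equally long, non-empty 1-D arrays")
    n = len(x)
    onzero = (x == 0) | (y == 0)
    return {
        "pos_pos": 100.0 * np.sum((x > 0) & (y > 0)) / n,
        "neg_pos": 100.0 * np.sum((x < 0) & (y > 0)) / n,
        "neg_neg": 100.0 * np.sum((x < 0) & (y < 0)) / n,
        "pos_neg": 100.0 * np.sum((x > 0) & (y < 0)) / n,
        "zero": 100.0 * np.sum(onzero) / n,
    }


@dataclass
class EIVResults:
    """Posterior summary of the errors-in-variables regression."""

    intercept: float
    slope: float
    slope_ci: tuple[float, float]
    sigma: float
    significant: bool
    n_regions: int
    acceptance_fraction: float
    ess: float
    chain: np.ndarray = field(repr=False)  # flattened posterior draws, (m, 5)

    def summary(self) -> str:
        lo, hi = self.slope_ci
        lines = [
            "Bayesian errors-in-variables regression",
            "=======================================",
            f"regions:              {self.n_regions}",
            f"intercept (mean):     {self.intercept:.4f}",
            f"slope (mean):         {self.slope:.4f}",
            f"  95% credible int.:  [{lo:.4f}, {hi:.4f}]",
            f"residual scale sigma: {self.sigma:.4f}",
            f"significant (CI excludes 0): {self.significant}",
            f"mean acceptance fraction:    {self.acceptance_fraction:.3f}",
            f"effective sample size (slope): {self.ess:.0f}",
        ]
        return "\n".join(lines)


def _eiv_log_prob(theta, x, y, x_var, y_var):
    alpha, beta, mu, tau, sigma = theta
    if tau <= 0 or sigma < 0:
        return -np.inf
    # weakly informative priors: N(0,10^2) on alpha, beta, mu;
    # half-Normal(0,10) on tau (wide latent scale); half-Normal(0,5) on sigma
    lp = (
        -0.5 * (alpha**2 + beta**2 + mu**2) / 100.0
        - 0.5 * tau**2 / 100.0
        - 0.5 * sigma**2 / 25.0
    )
    t2 = tau * tau
    vx = t2 + x_var
    vy = beta * beta * t2 + sigma * sigma + y_var
    cov = beta * t2
    det = vx * vy - cov * cov
    dx = x - mu
    dy = y - (alpha + beta * mu)
    quad = (dx * dx * vy - 2.0 * dx * dy * cov + dy * dy * vx) / det
    return lp - 0.5 * float(np.sum(np.log(det) + quad)) - len(x) * np.log(2.0 * np.pi)


class ErrorsInVariablesModel:
    """Linear regression with known measurement SEs on both variables.

    Parameters
    ----------
    y, y_se
        Response measurements (internal-trend slopes) and their SEs.
    x, x_se
        Predictor measurements (international-trend slopes) and their SEs.
    """

    def __init__(self, y, y_se, x, x_se):
        arrs = [np.asarray(a, dtype=float) for a in (y, y_se, x, x_se)]
        if len({a.shape for a in arrs}) != 1 or arrs[0].ndim != 1:
            raise ValueError("y, y_se, x, x_se must be 1-D and equally long")
        if any(np.any(~np.isfinite(a)) for a in arrs):
            raise ValueError("inputs must be finite")
        if len(arrs[0]) < 5:
            raise ValueError("need at least 5 regions")
        if np.any(arrs[1] <= 0) or np.any(arrs[3] <= 0):
            raise ValueError("all SEs must be positive")
        self.y, self.y_se, self.x, self.x_se = arrs

    def fit(
        self,
        seed: int = 0,
        nwalkers: int = 32,
        nsteps: int = 2000,
        burn: int = 500,
        min_ess: float = 400.0,
    ) -> EIVResults:
        """Sample the marginal posterior with an affine-invariant ensemble.

        ``nsteps`` post-burn steps are kept from each of ``nwalkers``
        walkers.  A warning (not an error) is emitted when the slope's
        effective sample size falls below ``min_ess``.
        """
        x, y = self.x, self.y
        x_var, y_var = self.x_se**2, self.y_se**2

        # moment-based starting point: OLS slope, sample spreads
        b0 = float(np.polyfit(x, y, 1)[0])
        a0 = float(np.mean(y) - b0 * np.mean(x))
        mu0 = float(np.mean(x))
        tau0 = max(float(np.std(x)), 1e-3)
        sig0 = max(float(np.std(y - (a0 + b0 * x))), 1e-3)
        center = np.array([a0, b0, mu0, tau0, sig0])

        rng = np.random.default_rng(seed)
        p0 = center + 1e-3 * np.abs(center).clip(min=0.1) * rng.standard_normal(
            (nwalkers, 5)
        )
        p0[:, 3] = np.abs(p0[:, 3]) + 1e-6
        p0[:, 4] = np.abs(p0[:, 4])

        sampler = emcee.EnsembleSampler(
            nwalkers, 5, _eiv_log_prob, args=(x, y, x_var, y_var)
        )
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2**31))
        ).get_state()
        sampler.run_mcmc(p0, burn + nsteps, progress=False)
        chain = sampler.get_chain(discard=burn, flat=True)

        slope_draws = chain[:, 1]
        lo, hi = np.percentile(slope_draws, [2.5, 97.5])
        autocorr_logger = logging.getLogger("emcee.autocorr")
        previous_level = autocorr_logger.level
        autocorr_logger.setLevel(logging.ERROR)
        try:
            tau_int = float(
                emcee.autocorr.integrated_time(
                    sampler.get_chain(discard=burn)[:, :, 1], quiet=True
                )[0]
            )
        except Exception:
            tau_int = float("nan")
        finally:
            autocorr_logger.setLevel(previous_level)
        ess = len(slope_draws) / tau_int if np.isfinite(tau_int) and tau_int > 0 else float("nan")
        if not np.isfinite(ess) or ess < min_ess:
            warnings.warn(
                f"low effective sample size for the slope: {ess:.0f} < {min_ess:.0f}",
                RuntimeWarning,
            )
        return EIVResults(
            intercept=float(np.mean(chain[:, 0])),
            slope=float(np.mean(slope_draws)),
            slope_ci=(float(lo), float(hi)),
            sigma=float(np.mean(chain[:, 4])),
            significant=bool(lo > 0 or hi < 0),
            n_regions=len(x),
            acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
            ess=float(ess),
            chain=chain,
        )


def fit_eiv_regression(y, y_se, x, x_se, seed: int = 0, **mcmc) -> EIVResults:
    """Convenience wrapper: build an :class:`ErrorsInVariablesModel` and fit."""
    return ErrorsInVariablesModel(y, y_se, x, x_se).fit(seed=seed, **mcmc)
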