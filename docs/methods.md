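# Methods

This note documents the models and procedures implemented in
`scholarmigrate`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real
bibliometric data.

## Residence inference

The unit of observation is an author-year-affiliation record. Residence in
a year is the **modal affiliation country**, then the modal region *within*
that country. Nesting the region mode inside the country mode is a design
choice: it guarantees the region residence is always consistent with the
country residence, at the cost of occasionally overruling a raw region
mode that lies outside the modal country.

Tie-breaking proceeds in two stages. A tie between modal options is first
resolved in favour of the option held in the closest *previous* residence
year, scanning year−1, year−2, … back to the author's first year (future
years never participate). A tie among options never previously held is
resolved uniformly at random. All random tie-breaks for a run draw from one
named stream derived from the run seed, so the pipeline is bit-reproducible.

**Backward fill.** Publications take time to prepare, so a publication
observed after a gap is evidence the author already resided at the new
location earlier. A gap of length *g* before an observed year *y* is filled
with *y*'s residence for min(*g*, 2) years; deeper gap years remain
unassigned rather than being interpolated — we prefer missingness over
inventing residences with no observational support. Nothing before the
first observed year is ever filled. A consequence is that a move observed
only after a long silence is dated at most two years before the
reappearance, which may still be later than the true move year; the
censoring window (inclusive 1998–2017 by default, configurable) trims the
span edges where such artifacts concentrate.

A migration event is recorded whenever consecutive residence years differ
in region, dated to the first year carrying the new residence, and
classified internal (same country) or international (different countries).
Authors observed in a single year contribute to populations but can never
generate events.

## Flow accounting

`N_{i,t}` counts distinct authors resident in region *i* in year *t*,
including backfilled residence-years (they are residences by construction;
`tabulate_flows` operates on whatever residence table it is given, so a
caller can drop backfilled rows to measure the alternative). Each event
increments one outflow cell at its origin and one inflow cell at its
destination. Net migration rates are per 1,000 scholars per year; period
rates divide summed net flows by summed person-years, so they are
automatically annualised. Region-years with `N = 0` yield flagged,
undefined rates rather than zeros: 0/0 is not evidence of zero migration.

## Weighted Gini

The inequality measure is the mean-normalised (relative) Gini

G = Σᵢ Σⱼ wᵢ wⱼ |xᵢ − xⱼ| / (2 (Σ w)² x̄_w),

computed annually per continent (or alternative grouping) and migration
type, with that year's region populations as weights. Year-specific weights
(rather than a fixed base year) follow from computing the coefficient
annually. The implementation uses the O(n log n) sorted cumulative-sum
identity and is tested against an O(n²) pairwise double sum to 1e-12.
Weighting is the only small-region mitigation applied; no winsorising or
population floor is imposed. Group-years with fewer than two usable regions
are skipped with a warning.

## Quasi-Poisson trends

For each region and series, counts follow a log-linear rate trend
`E[y_t] = N_t exp(α + β t)`, fitted by IRLS (statsmodels GLM, Poisson
log-link, offset `log N_t`; convergence at relative tolerance 1e-8 within
100 iterations). The time covariate is centered at the window midpoint —
this changes only the intercept. Dispersion is the conventional Pearson
estimator φ̂ = χ²/(n − 2), and the slope SE is the Poisson-ML SE times
√φ̂. Years with zero exposure are dropped rather than given an infinite
offset; series that are all-zero carry no trend information and raise. The
axis transform `T(x) = 100(eˣ − 1)` converts log-scale slopes to percent
change per year.

Eligibility is parsed as three conjunctive conditions — peak population
strictly above 25, at least 10 observation years, at least 5 years with a
nonzero count — the most natural reading of the filter; the stricter
alternative (≥ 10 years each with ≥ 5 events) is available via
`EligibilityRule(parsing="joint")`. The nonzero-count condition is
evaluated per series, so a region can qualify for internal but not
international trends.

## Errors-in-variables regression

The relation between internal (y) and international (x) trend slopes is
estimated accounting for the measurement SEs of both:

- x_i ~ Normal(ξ_i, x_se_i²), y_i ~ Normal(α + β ξ_i, y_se_i² + σ²),
- latent ξ_i ~ Normal(μ, τ²) hierarchically.

Priors are weakly informative and scale-free for slopes of magnitude ≲ 1:
Normal(0, 10²) on α, β and μ; half-Normal(0, 10) on τ; half-Normal(0, 5)
on σ. The latents are marginalised analytically — each (x_i, y_i) pair is
bivariate Gaussian given (α, β, μ, τ, σ) — so the sampler explores only
five dimensions. Sampling uses an affine-invariant ensemble (emcee; default
32 walkers, 2,000 kept steps after 500 burn-in, seeded), with the mean
acceptance fraction and the autocorrelation-based effective sample size
reported as diagnostics (a warning fires below 400 effective draws). The
slope is "significant" when the central 95% credible interval excludes
zero. In the x_se, y_se → 0 limit the posterior mean reproduces ordinary
least squares; with noisy predictors it avoids the attenuation bias OLS
suffers. Both behaviours are verified by simulation in the test suite.

## Kendall correlations and quadrants

Per-region associations between internal and international annual rates use
Kendall **tau-b** (tie-corrected), because zero-rate ties are common in
small regions; tau is undefined (flagged, not zeroed) when a series is
constant, e.g. zero international migration throughout. Quadrant summaries
report the percentage of regions per sign quadrant of paired statistics,
with points on an axis counted in a separate zero bucket so the five
percentages always total 100 exactly.

## Synthetic cohorts

The generator emulates the structure of author-affiliation panels: careers
with uniform start years and geometric lengths (mean 12 years) inside the
observation span; i.i.d. Bernoulli publishing per active year (default
probability 0.7) — the simplest mechanism that exercises backward fill; a
second same-year affiliation with probability 0.1, split evenly between
same-country and different-country choices, to exercise mode tie-breaking;
and competing-risk internal/international moves with per-author-year
hazards (defaults 0.015 and 0.008, the order of magnitude of annual
scholarly mobility), at most one move per year at year boundaries so true
residence is single-valued per year. Per-region multiplicative annual
trend factors compound from the span start and scale both hazards of
authors resident there. Authors who never publish by chance are forced to
emit one record in their first active year so every simulated author is
observable.

Ground truth (residence timelines, events, flow tallies) is returned
alongside the records. By construction, with full observation
(publish probability 1, no second affiliations) inference recovers the
truth exactly; tests verify this identity and the conservation laws
(inflows = outflows = event count per year and scope; internal flows
balance within each country).

What the generator does **not** emulate: author-name disambiguation noise,
affiliation geocoding errors, coauthorship structure, discipline-specific
publication delays, or serially correlated publishing behaviour. Passing
tests therefore validate the *estimator logic* — not the robustness of the
modal rule to identity or geocoding errors in real bibliometric data.

## Problem sizes and numerical choices

Test cohorts use 250–500 authors over 20–25 years and worlds of 12–24
regions — large enough that every downstream stage has signal, small
enough to iterate quickly; the demonstration configuration scales to 4,000
authors. Calibration checks use 300–1,000 simulated trend series and 100
errors-in-variables replicates with a reduced (16-walker) sampler budget.
Monte-Carlo assertions use 3-SD tolerances on the corresponding binomial or
empirical errors. Exact-arithmetic oracles (pairwise Gini, Kendall pair
enumeration) are checked to 1e-12.

## Known limitations

- Sub-annual timing is invisible: an author who leaves and returns within
  a year, or moves twice in a year, registers no or one event.
- Multiple simultaneous residences are resolved to a single mode; authors
  with genuinely split appointments are assigned one residence per year.
- A move followed by a long publication silence is dated up to two years
  before the reappearance, which can lag the true move; recall of true
  events falls as publishing becomes sparser (tested to degrade gracefully).
- The errors-in-variables model assumes Gaussian measurement errors with
  known SEs and a unimodal latent slope distribution; heavy-tailed slope
  populations would call for a robust likelihood.
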