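# scholarmigrate

Estimation of **internal and international migration of scholars** from
longitudinal author–affiliation records, at the subnational-region level.

Bibliometric databases record, for each author and publication year, the
region and country of their institutional affiliations. Treating the modal
affiliation as the author's annual residence turns those records into a
longitudinal migration panel: moves between regions of the same country are
*internal* migration, moves between countries are *international* migration.
`scholarmigrate` implements the full analysis pipeline on top of that idea —
residence inference, migration-event detection, flow accounting, inequality
and trend statistics — together with a synthetic-cohort generator with known
ground truth, so every stage is testable without access to any proprietary
bibliometric database.

The package is aimed at demographers and science-of-science researchers who
want reproducible migration indicators from author-level affiliation panels
(or who want to validate such indicators against simulated cohorts).

## The method

1. **Residence inference.** An author's residence in year *t* is the modal
   affiliation country of that year's publications, and the modal region
   within that country. Ties go to the option held in the closest previous
   residence year; ties among entirely new options are broken uniformly at
   random from a seeded stream. Publication gaps are bridged by a two-year
   backward fill: a publication observed after a gap assigns its residence
   to up to two preceding years, reflecting publication preparation delay.
2. **Migration events.** A move is recorded when the residence region
   changes between consecutive residence years; the migration year is the
   first year with the new residence. Events are censored to an analysis
   window (default 1998–2017) to limit edge artifacts.
3. **Net migration rate.** For region *i*, period *P* and scope
   *k* ∈ {internal, international, total}:

   `NMR_{i,P,k} = 1000 · (Σ_{t∈P} I_{i,t,k} − Σ_{t∈P} E_{i,t,k}) / Σ_{t∈P} N_{i,t}`

   with *I* inflows, *E* outflows and *N* the scholar population — a
   per-1,000-scholars-per-year rate.
4. **Inequality.** Annual population-weighted relative Gini coefficients of
   regional migration rates within each continent (or any grouping label),
   for six migration types (internal/international/total × in/out):
   `G = Σ_i Σ_j w_i w_j |x_i − x_j| / (2 (Σ w)² x̄_w)`.
5. **Trends.** Per region and series, a quasi-Poisson log-link regression of
   annual event counts on calendar year with offset `log N_{i,t}`; SEs are
   inflated by the Pearson dispersion. Slopes are reported as percent change
   per year via `T(x) = 100·(e^x − 1)`. Regions qualify with more than 25
   scholars in some year, ≥ 10 observation years and ≥ 5 nonzero-count years.
6. **Interrelation.** Internal-trend slopes are regressed on
   international-trend slopes with a Bayesian errors-in-variables model that
   propagates the SEs of both (slope "significant" when the 95% credible
   interval excludes zero); per-region Kendall tau-b correlations relate
   internal and international annual rates; quadrant fractions summarise the
   signs, with exact zeros bucketed separately.

## Worked example

The repository ships a demonstration configuration that simulates a
4,000-author cohort on a 2-continent × 6-country × 18-region world
(1996–2020), with region-level multipliers that make some regions' move
rates rise and others' fall:

```bash
scholarmigrate all --config examples/demo_config.yaml
# pipeline complete; 14 outputs written
```

The run takes well under a minute and writes all products to `output/demo/`.
The three regions with the highest total net migration rate in 2012–2017:

```
 region_id  period_start  period_end scope  nmr_per_1000
CT2.CN3.R1          2012        2017 total     41.958042
CT1.CN1.R1          2012        2017 total     31.185031
CT1.CN2.R1          2012        2017 total     26.915114
```

`CT2.CN3.R1` gained about 42 scholars per 1,000 resident scholars per year
over the period — it is one of the regions whose move-rate multiplier makes
it an increasingly active destination. The inequality series (`gini.csv`)
gives, e.g. for continent CT1 in 2010, a weighted Gini of 0.38 for internal
in-migration versus 0.61 for international out-migration: international
flows are concentrated in fewer regions than internal ones. The trend stage
fits all 72 eligible region-series (18 regions × in/out ×
internal/international), and the errors-in-variables stage finds a
significantly positive relation between internal and international
out-migration trends on continent CT2:

```
group_id direction  slope  slope_ci_low  slope_ci_high  significant
     CT2       out 0.8018        0.2109         1.6739         True
```

i.e. regions whose international out-migration trends upward tend to show
rising internal out-migration too — the association the generator's shared
region multipliers build in.

Because every stage seed derives from the config seed, re-running the same
configuration byte-reproduces every output; `output/demo/manifest.json`
records the configuration, per-stage seeds, versions, row counts and SHA-256
digests.

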