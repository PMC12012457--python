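# Demonstration pipeline: a synthetic world of 2 continents x 3 countries
# x 3 regions and a 4,000-author cohort observed 1996-2020, analysed over
# the default 1998-2017 window.  Region-level trend multipliers make some
# regions' move rates rise and others' fall over time, so the trend and
# interrelation stages have real signal to find: both hazards of a region
# share its multiplier, which induces a positive association between
# internal and international slope trends.
out_dir: output/demo
seed: 17
window: [1998, 2017]
nmr_periods: [[2000, 2005], [2006, 2011], [2012, 2017]]
grouping: continent
eligibility:
  min_peak_scholars: 25
  min_obs_years: 10
  min_nonzero_years: 5
simulate:
  world:
    n_continents: 2
    countries_per_continent: 3
    regions_per_country: 3
  cohort:
    n_authors: 4000
    year_start: 1996
    year_end: 2020
    publish_prob: 0.75
    multi_affil_prob: 0.1
    internal_move_rate: 0.025
    international_move_rate: 0.012
    region_trend:
      CT1.CN1.R1: 0.94
      CT1.CN1.R2: 0.97
      CT1.CN1.R3: 1.00
      CT1.CN2.R1: 1.02
      CT1.CN2.R2: 1.04
      CT1.CN2.R3: 1.06
      CT1.CN3.R1: 0.94
      CT1.CN3.R2: 0.97
      CT1.CN3.R3: 1.00
      CT2.CN1.R1: 1.02
      CT2.CN1.R2: 1.04
      CT2.CN1.R3: 1.06
      CT2.CN2.R1: 0.94
      CT2.CN2.R2: 0.97
      CT2.CN2.R3: 1.00
      CT2.CN3.R1: 1.02
      CT2.CN3.R2: 1.04
      CT2.CN3.R3: 1.06
eiv_mcmc:
  nwalkers: 16
  nsteps: 1200
  burn: 400
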