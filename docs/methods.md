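# Methods

This note documents the statistical model behind `marshpace`, the defaults
and numerical choices, what the synthetic generator does and does not
emulate, and the limitations a user should keep in mind.

## Data model and units

All elevations are stored in metres on a common geodetic datum; all rates
are reported in mm/yr, with conversion only at reporting boundaries.
Series are `LevelSeries` objects (site id, cadence, pandas Series indexed
by time, optional per-period completeness). Time enters every regression
as decimal years; monthly values sit at mid-month, `year + (m − 0.5)/12`,
finer cadences at the exact timestamp position within the calendar year.
Regressions centre time on its mean for conditioning; slopes are invariant
to the shift.

## Preprocessing

Hourly → daily → monthly aggregation is the arithmetic mean with
completeness = records present / records expected (24 h per day, true day
counts per month, leap years honoured). Two boundary conventions are
deliberate and tested: a month is kept only when completeness strictly
*exceeds* 0.70 (22/31 days keeps a month, exactly 0.70 drops it), while a
site is kept when its monthly completeness is *at least* 0.70 (110/156
months passes, 108/156 fails). A daily mean requires at least one hourly
record; the daily completeness is carried forward so the monthly filter
sees it. Biannual SEC series pass a site-level screen of the same form
(observed occasions / expected biannual slots ≥ 0.70).

Deseasonalization subtracts a 12-value monthly climatology computed on
OLS-detrended data from the *raw* series, so the trend survives. The
climatology is exactly mean-centred (offsets sum to zero), which keeps the
series mean. One pass removes an exact annual sinusoid — and its
finite-window slope leakage, about −0.9 mm/yr for an 80 mm amplitude over
156 months — to second order; the residual is a repeating pattern below
1 mm at 13 years, which is why the idempotence and removal tests use
millimetre-scale tolerances rather than machine precision. A calendar
month observed fewer than twice is an error naming the month.

## Trend inference

Trends are OLS; significance and trend uncertainty both come from
surrogate residual series rather than parametric t statistics, because
monthly water levels are strongly serially correlated.

Residuals are modelled as stationary AR(1). The lag-1 coefficient is
estimated as the mean lagged product per consecutive pair divided by the
mean square per element (so regular gaps do not deflate it), then
corrected for the small-sample bias incurred by estimating it on OLS
residuals: the fitted intercept and slope absorb serial dependence,
biasing the raw estimate by about −(2 + 5φ)/n, and absorb low-frequency
noise power, deflating the residual variance by about
1 − 2(1 + φ)/((1 − φ)n). Without these corrections the surrogate trend
test on pure red noise (φ = 0.5, n = 156) rejects at ~8.5% instead of the
nominal 5%; with them the measured type-I error is 5.9% over 4,000
repetitions — the remaining sliver is irreducible parameter-estimation
uncertainty that a plug-in surrogate test cannot remove. The uncorrected
estimator remains available (`fit_ar1(..., detrended=False)`).

Surrogates are initialised from the stationary marginal distribution (no
burn-in); paths are evaluated as a linear filter over the innovations.
p-values use the add-one estimator (k + 1)/(n + 1), so the smallest
attainable value is 1/(n_draws + 1) and zero never occurs. Missing months
of the observed series are masked identically in every surrogate before
refitting, preserving the sampling pattern. SEC ensembles use white-noise
surrogates (φ = 0): a ~25-point biannual record cannot constrain φ.

The 10,000-member trend ensemble is a parametric residual bootstrap: each
surrogate path is added to the fitted line and the synthetic series refit.
Because the OLS slope is linear in the data this is evaluated exactly as
`point rate + slope(surrogate)`, one matrix product per site. How the
per-site trend distributions are constructed is an interpretive choice —
the alternatives (analytic AR(1) slope variance, block bootstrap) would be
defensible too — and the residual bootstrap was chosen because it reuses
the AR(1) surrogate machinery already required for significance testing.

Cross-series correlation (site vs reference sea level, both detrended) is
Pearson r over common months (≥ 24 required); its null distribution pairs
*independent* AR(1) surrogates of each series. Whether one or both series
should be surrogated is genuinely open; independent pairs are the
conservative standard choice. Cross-*site* correlation of rates (the
ecogeomorphic-feedback check) instead uses a seeded permutation test:
cross-sectional pairs carry no serial structure, so red-noise machinery
would be the wrong null.

## VLM correction

A site is exempt only when both the gauge and the RSET rod reach the
Pleistocene basement (`depth ≥ HP-interface depth` for both); unknown
interface depths are filled from the nearest station with a known one.
The correction rate is normal with 5th/95th percentiles pinned at 1 and
4 mm/yr, hence mean 2.5 and sd (4 − 1)/(2 z₀.₉₅) ≈ 0.912 mm/yr, constant
in time, not truncated (negative draws are kept). One distribution serves
all applicable sites: the per-site severity is not identifiable from the
instrument metadata alone. Correction draws are paired with trend draws by
index under independent sub-seeds.

Trend ensembles are corrected per draw. Monthly elevations are corrected
with the central rate by default — `corrected(t) = raw(t) −
rate · (t − 2014)`, raising pre-survey and lowering post-survey values;
the 2014.0 epoch is the fixed point — and `flood_mode="mc"` instead
propagates the per-draw rates into the flooding probability, for users who
want elevation uncertainty inside `P(flood)`. The default keeps flooding a
pure function of measurement occasions.

## Classification

`P(rate)` is the fraction of index-paired draws with cRWL strictly above
SEC; identical degenerate ensembles therefore return the tie fraction (0),
not 0.5 by fiat — ties essentially never occur with continuous ensembles.
`P(flood)` compares the surveyed wetland surface elevation at each SEC
occasion with the tide level of the same calendar month; the tide triplet
is the corrected monthly mean water level ∓/+ half the annual tidal
amplitude, so `P(flood|low) ≤ P(flood|mean) ≤ P(flood|high)` always.

The seven rules partition the unit square exactly with the boundary
conventions ≥ 0.66 / ≥ 0.33 / ≥ 0.90 / ≤ 0.10 / > 0.50 (the printed
probability intervals of the original scheme overlap at their endpoints;
these choices make the map total and are exercised by a grid sweep).
"Safe" is the complement of the three give-up categories. Cross-site
deficit summaries use the per-site median of the deficit draws; the
rate-correlation step trims sites with cRWL rates outside the
[2.5th, 97.5th] cross-site percentile interval and repeats the estimate on
the organic-rich subset (organic fraction > 0.30).

## Projections

Scenario curves are decadal rise rates 2025–2150 with a 1σ band, averaged
unweighted over coastal locations sharing the grid. Thresholds are
`observed GSL rate − deficit percentile`; the observed rate is a config
input (default: the OLS rate of the reference series). Crossing years are
reported at the native decadal resolution — "first grid year whose rate
meets the threshold" — matching how such statements are usually phrased;
linear interpolation exists behind `crossing_year_interpolated` but is off
in reports. The low-confidence projection tier is an alternative input
table, not a different algorithm; the upper-1σ band is selectable per
report row.

## Synthetic network

Each site's daily water level is
`w₂₀₁₄ + (trend + vlm)·(t − 2014) + A sin(2π(t − φ₀)) + weight · ocean(month) + ar1(month)`,
with uniform daily missingness and occasional whole-month outages; the
monthly AR(1) noise and shared ocean signal are held constant within a
month. SEC series are lines plus white measurement noise at biannual
occasions (the 15th of every sixth month). Differential VLM is injected
into water levels only — gauges float, rods are anchored — at sites where
the generated instrument depths demand a correction, with the true rate
drawn from the same 1–4 mm/yr band the correction model uses.

Defaults (chosen once to emulate a rapidly subsiding microtidal deltaic
coast over a 13-year window, 2009–2021): water-level trends U(5, 28) mm/yr
(mean ≈ 16.5, spread ≈ ±7); SEC trends U(0, 14) mm/yr (median ≈ 7);
seasonal amplitude 80 mm; monthly AR(1) with φ ∈ U(0.2, 0.7) and 30 mm
innovations; ocean signal 55 mm marginal sd at weight 0.7, which puts the
deseasonalized site-to-reference correlation near 0.74; reference trend
10.7 mm/yr; tidal amplitudes 0.1–0.6 m; gauge depths 4–5 m, rod depth
20 m, Holocene–Pleistocene interface U(0.5, 25) m (≈ 16% of sites exempt);
10% daily missingness plus 3% month outages. Seasonality is a single
annual harmonic — the monthly-climatology removal also handles higher
harmonics, but one keeps the ground truth analytic. Default scenario
curves are piecewise-linear anchor sets shaped like published
Louisiana-coast projections, with the middle pathway passing ~7 mm/yr
around 2070; per-location variants carry exactly zero-sum offsets so their
average reproduces the base curve.

Ground truth records every generating parameter and the category the
classification rules assign to the deterministic skeleton (trend lines +
seasonal cycle, stochastic terms off, true VLM removed exactly). The exact
noise-free recovery check runs the pipeline on `noise_free(config)` —
which zeroes every noise amplitude and collapses the true-VLM band to its
2.5 mm/yr centre — in central-rate correction mode, so the pipeline's
correction coincides with the injected motion and recovery is exact
(200/200 sites, all three tide conditions). With random per-site VLM and
draw-mode corrections, recovery is statistical.

One deliberate design point in the validation experiments: the
trend-ensemble *coverage* check (true trend inside the central 95%
interval for ~95% of sites) switches the shared ocean signal off. A signal
common to all sites gives the whole network a common trend-error
component, so the covered fraction of one realised network is not a
binomial proportion — with the default coupling it swung between 86% and
98% across seeds, while independent sites give a stable 93.5–94.5%. The
slight over- and under-shoots around 95% reflect the AR(1) plug-in
approximation, not a defect of the generator.

What the generator does **not** emulate: spatially correlated subsidence
fields, storm surge and hurricanes, vegetation dynamics, marsh-edge
erosion, non-linear VLM, and datum realisation differences. Passing tests
therefore demonstrate that the statistical machinery is calibrated and
self-consistent under the stated noise model — not that any real network
satisfies that model.

## Orchestration and reproducibility

`RunConfig` drives simulate → prep → trends → VLM → classify → project;
every stochastic step draws from a Generator seeded by
`SeedSequence([master, crc32(stage), crc32(site_id)])`, so runs are
bit-reproducible, sites do not perturb each other's streams, and stages
are independent. The CLI exposes `simulate`, `run-all` and `report`; the
individual stage functions (`pipeline.stage_*`) are the library-level
entry points for prep/trends/classify/project, since re-entering mid-pipeline
from disk would require persisting 10,000-member ensembles in a sidecar
format. Default problem sizes in the test-suite and acceptance script
(200-site networks, 1,000–10,000-member ensembles, 1,000 calibration
repetitions) were chosen so each experiment has sampling error well inside
its assertion band while a full validation run completes in well under a
minute.

## Known limitations

- The AR(1) plug-in surrogate test retains ~1 percentage point of type-I
  inflation from parameter uncertainty; a double bootstrap would remove it
  at ~100× the cost.
- One correction distribution for all applicable sites ignores any
  depth-dependence of differential VLM severity.
- Flooding probabilities are step functions of at most ~26 measurement
  occasions, so they move in coarse increments and category boundaries at
  0.10/0.50/0.90 can be sensitive to a single occasion.
- The classification of sites whose `P(rate)` lies within Monte Carlo
  error of a boundary (≈ ±0.01 at 10,000 draws) is ensemble-size
  dependent; the partition itself is exact, the probabilities are not.
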