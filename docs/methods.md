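# Methods

This note documents the models, the synthetic-study design, the numerical
choices, and the known limitations of `cambiomatch`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Forcing, chilling and the heat-requirement model

Daily forcing follows a saturating sigmoid of daily mean temperature,
`D_HU(T) = 28.4 / (1 + e^{-0.185 (T - 18.4)})` (dimensionless heat units):
near-zero contributions on frosty days, ≈ 1 heat unit near 0 °C, half the
asymptote at 18.4 °C. Accumulation starts on 1 January, counts only days
above a base threshold `T_th` (default 0 °C, the usual base for cold-limit
conifers), and *includes* the onset day itself — inclusivity at the end
point is a convention we fix explicitly because the sum is used as a
continuous requirement scale.

Chilling is a day count over the fixed 122-day window 1 September –
31 December of the year before onset. The temperature band is half-open
(`lower ≤ T < upper`) so that a day can never be counted by two adjacent
candidate bands (e.g. −5…0 and 0…5). Candidate bands are screened by
fitting the mixed model below once per band and ranking by AIC; exact ties
(identical counts) resolve toward the narrower band, then input order.

The heat requirement `HU` at onset is modelled as
`HU ~ chilling * life_form` with crossed random intercepts for site and
species, fitted by maximum likelihood (statsmodels `MixedLM` with variance
components; ML rather than REML so AICs are comparable across fixed-effect
structures). The AIC penalty counts fixed effects, variance components and
the residual variance. Degenerate grouping factors (a single site or a
single species) are dropped from the random structure, and with both
dropped the fit reduces exactly to OLS — a property the test suite checks
against a statsmodels OLS oracle. Life-form coding is explicit: the default
reference level is `tree` (the Chilling row is the tree slope); passing
`reference="shrub"` reproduces the sign pattern of the published-style
coefficient table (negative chilling main effect, positive interaction).
Both codings give the same shrub:tree slope ratio, which `slope_ratio`
computes from the coded coefficients without forcing any particular value.
t statistics are reported without denominator degrees of freedom by
default (LMM df are contested); a normal-approximation p column is
available behind a flag.

## Onset-response regressions

Spring (March–May) temperature `x` is linearized as `x' = log10(1 − x)`
before OLS of onset day on `x'`. The transform is undefined for `x ≥ 1 °C`;
the library raises a domain error naming the offending records rather than
silently dropping them. The pipeline, by contrast, excludes such records
*explicitly* and surfaces the count in the run manifest — the domain
restriction is a property of the transform, and at desk scale the right
behaviour differs between a low-level fit (fail loudly) and an end-to-end
run (proceed with an audit trail).

"Days per °C" is the derivative of the back-transformed curve at the
sample-mean spring temperature, `dy/dx = -b / ((1 - x̄) ln 10)`; the
evaluation point matters because the curve is non-linear, and the sample
mean is the only point that does not require an arbitrary choice. Slopes of
two life forms are contrasted with the pooled two-slope t test
(`df = n1 + n2 − 4`), which equals the interaction t of a pooled regression
with group-specific intercepts and slopes; the test suite asserts that
equivalence to 1e-8 against statsmodels. Partial correlations are Pearson
correlations of OLS residuals with `df = n − k − 2` (cross-checked against
pingouin in the tests). The projected mismatch under warming ΔT is the
difference of the two local days-per-°C slopes times ΔT, positive when
shrubs delay relative to trees.

## Growth simulator

The simulator follows the VS-Lite tradition: trapezoidal ramp responses
`g_T(T; t1, t2, t3, t4)` and `g_M(m; m1..m4)` (zero outside the outer
thresholds, one on the optimal plateau, linear between), combined by the
Liebig minimum (a product mode exists behind a flag), and modulated by
astronomical day length normalized to its annual maximum (supported for
|latitude| < 66.6°). Soil moisture is a daily leaky bucket — infiltration
net of a runoff fraction, temperature-index evapotranspiration that stops
at or below 0 °C, linear drainage, clipped to [0, capacity] — initialized
half-full each 1 January. For the humid treeline sites this package
targets, moisture limitation is off by default and the simulator is a
deterministic pure function of climate and parameters (asserted
bit-identical across runs).

Cambial onset is read off the simulation as the first day with `g_T > 0`
sustained for `onset_persistence` consecutive days (default 5). The
persistence rule is our definition — a single warm day does not reactivate
the cambium — and it is exposed in the parameter set. Annual increments are
within-year sums of the daily rate, standardized to mean one over the
simulated span before any comparison. Leap days are ordinary days, so a
366-day year accumulates marginally more than an identical 365-day one;
tests that require exact invariance use non-leap spans.

## Genetic-algorithm calibration

The GA is a plain real-coded algorithm: tournament selection (k = 3),
BLX-α blend crossover (α = 0.5), per-gene Gaussian mutation with scale 10%
of each bound range, clipping to bounds, elitism of one. The threshold
ordering (`t1 < t2 ≤ t3 < t4`) is enforced by rejection-resampling of
offspring so the fitness stays a pure Pearson correlation. All operators
and rates live in `GAConfig`; runs are deterministic per seed and the
best-so-far history is monotone under elitism (both asserted). Defaults
(population 60, 100 generations) are desk-scale; the pipeline stage uses a
smaller budget (24 × 15) because its purpose there is demonstration, not
exhaustive search.

Significance of the calibrated correlation uses the t transform with
`n − 2` df, without autocorrelation correction by default; a lag-1
effective-sample-size adjustment is available. RMSE between simulated and
observed onset days is a *validation* metric only, never part of the
objective — calibrating on ring widths and validating on phenology keeps
the two information sources independent.

### Identifiability of the minimum growth temperature

A correlation-only objective is nearly blind to `t1` in mild climates:
raising `t1` shortens every growing season roughly proportionally, which
rescales the increment series but barely changes its standardized pattern,
and Pearson correlation is invariant to affine rescaling. Profiling the
noise-free objective confirms r ≥ 0.98 across the whole `t1` box for
warm-summer climates. The packaged recovery experiment
(`experiments.t1_recovery_experiment`) therefore uses a climate where the
question is meaningful: a very short, marginal growing season (annual mean
−3 °C, amplitude 5.5 °C) in which moving `t1` changes *which years barely
grow at all* — a non-affine change the correlation does see. Under those
conditions, with the other thresholds held at truth, 50-year chronologies
and index noise σ = 0.3, the GA re-finds `t1 = 2 °C` with a median absolute
error well inside ±1.5 °C across seeds, and every calibration is retained
as significant. The experiment recovers one parameter because that is what
the data can identify; recovering all four thresholds from a single
correlation is not an honest claim for this objective.

## Dendro processing

Tucson/RWL decadal files are read and written natively, including both
stop-marker dialects (999 → 0.01 mm, −9999 → 0.001 mm). Only the *final*
value of a series is interpreted as a stop marker: a data value of 999
(0.999 mm in the 0.001 dialect) mid-series must not truncate the record.

The "spline" detrending curve is a second-difference penalized smoother
(discrete smoothing spline / Whittaker filter) whose penalty is set from
the standard 50%-amplitude frequency-response criterion:
`λ = (2 − 2 cos(2π/p))⁻²` for a cutoff wavelength `p`, defaulting to ⅔ of
the series length — the de-facto dendro standard cutoff. The modified
negative exponential `a·e^{−bt} + k` (a, b > 0, k ≥ 0) falls back to a
non-increasing straight line, then to the horizontal mean, each fallback
logged. Indices are width/curve, renormalized to mean exactly one (the
ratio alone has mean ≈ 1, not 1). Chronologies are per-year arithmetic
means, or Tukey biweight (c = 9, median/MAD, one step) when robustness is
requested; sample depth is recorded per year. Moving correlations use
21-year windows labelled by their central year (chosen for symmetry; the
labelling convention is a parameter in all outputs), with two-sided p at
each window and a 0.05 reference level; cross-site aggregation is the mean
± SE per central year.

## Synthetic-study design

The generator's job is to produce data with the statistical structure the
analysis assumes, with known truth, so the estimators can be tested as
recovery. Three design points deserve explanation.

**Asymmetric seasonal cycle.** The daily temperature expectation is
`μ + A·cos(2π(d − peak)/365) + B·sin(4π(d − peak)/365)` with `B < 0`
(default −1.9 °C): a steep spring warming and a long, mild autumn
cooling, with the annual peak in early August (`peak_doy` 225). This is
the characteristic shape of monsoon-influenced mountain climates, and it
is load-bearing: a symmetric cosine ties the spring and autumn crossing
rates together, which makes the direct forcing effect of a warm spring
overwhelm the chilling-mediated delay for *both* life forms. The
asymmetric shape keeps autumn temperatures hovering near the top of the
chilling band (so warm years genuinely lose chilling days) while spring
warms through the forcing threshold quickly (so the direct advance is
moderate) — the regime in which chilling-sensitive taxa can show a net
delay under warming.

**Shared interannual anomalies.** Besides daily AR(1) weather noise
(σ = 1.4 °C, ρ = 0.5), each calendar year carries one temperature anomaly
shared by all its days, itself AR(1) across years (σ = 1.1 °C, ρ = 0.8).
The year-to-year persistence couples the autumn that sets chilling to the
following spring that supplies forcing — without some such coupling (which
real climates have through decadal variability and trends) the
chilling-mediated pathway would be invisible in an onset-versus-spring
regression. Month-specific linear trends (+0.35 °C/decade in March–May,
+0.7 °C/decade in September–February) add the asymmetric seasonal warming
reported for high elevations, reinforcing that coupling.

**Phenology rule at published magnitudes.** Requirements follow
`HU* = a_f + b_f · chill + site offset + species offset` with defaults
`a_tree = 94`, `a_shrub = 186.5` heat units and `b_tree = −0.6125`,
`b_shrub = −1.96` (ratio exactly 3.2), plus Gaussian site/species offsets
(σ = 6) and observation noise on the onset day (σ = 2.5 d). Onset is the
first day the cumulative heat sum reaches `HU*`; years that never reach it
are censored and counted, never imputed. Ring-width indices are
`2.2 − 0.008 · onset + noise(σ = 0.12)`, floored at 0.05. Default study:
8 sites on a −0.8 °C elevation ladder, 2 species per life form, 40 years.
Mean spring temperatures sit near −2 °C so the log-transform domain
(`x < 1 °C`) is respected with margin; the pipeline's explicit-exclusion
path covers rare anomalous years.

One master seed drives everything through a spawned seed sequence, and
generated files are byte-identical across runs. The generating truth is
written to a separate `truth/` directory that no analysis stage reads
(asserted by a test).

What the generator does *not* emulate: microclimate decoupling between
life forms, snowpack insulation, photoperiod limits, spatial correlation
between sites, or realistic ring-width autocorrelation. Passing the
recovery tests therefore shows the estimators are correct and the
mechanism is detectable when present — not that real treeline data will be
as clean.

## Numerical choices and degenerate inputs

- Seasonal means are day-weighted means of daily values; winter of year Y
  is Dec (Y−1) – Feb (Y). Missing-day tolerance defaults to zero; short
  gaps can be linearly interpolated when explicitly allowed.
- Correlation of two identical constant onset vectors is reported as 1
  (RMSE 0); a constant versus non-constant pair is NaN.
- Zero simulated variance in the calibration objective returns a −1
  sentinel rather than NaN, keeping the GA ordering total.
- Chronology standardization with all-zero increments returns a zero
  index rather than dividing by zero.
- The LMM records convergence warnings in its result instead of raising;
  a singular random-effects fit is a reportable outcome, not a crash.

## Pipeline runtimes and sizes

Default problem sizes are chosen for interactive desk use: the full
pipeline (8 sites × 40 years, four candidate windows, GA 24 × 15) runs in
a few seconds; the ten-seed recovery experiment takes on the order of ten
seconds; the complete test suite under half a minute. All artifacts are
plain CSV/JSON plus a checksummed manifest.
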