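# cambiomatch

Links daily climate to the timing of wood formation (cambial phenology) and
to annual radial growth of trees and shrubs growing together at alpine
treelines — and asks the question that matters for treeline dynamics under
warming: do the two life forms shift their growing season in the *same*
direction?

The package is aimed at dendroecologists and phenologists who have daily
temperature series, cambial-onset observations (the first enlarging xylem
cells of the year, as a day of year) and ring-width series, and who want to
quantify the forcing/chilling balance that controls spring reactivation.

## The model in brief

**Forcing.** Each day contributes heat units through a saturating sigmoid of
the daily mean temperature `T`:

```
D_HU(T) = 28.4 / (1 + exp(-0.185 (T - 18.4)))
```

accumulated from 1 January over days with `T > 0` °C. The heat requirement
`HU` of a tree or shrub is the accumulated sum on its onset day.

**Chilling.** Days during 1 September – 31 December of the previous year
whose mean temperature falls in a candidate window (default −5…0 °C,
half-open) count as chilling days. The heat requirement declines with
chilling:

```
HU* = a + b · chill_days        (b < 0)
```

and the analysis fits `HU ~ chilling × life form` as a linear mixed model
with site and species random intercepts, ranking candidate chilling windows
by maximum-likelihood AIC. The shrub:tree ratio of the fitted chilling
slopes measures how much more chilling-sensitive shrubs are.

**Onset response.** Onset day is regressed on spring (March–May) temperature
after the linearization `x′ = log10(1 − x)` (valid for spring means below
1 °C); the reported days-per-°C slope is the local derivative of the
back-transformed curve at the sample-mean spring temperature. A pooled
two-slope *t* test contrasts life forms, and the projected phenological
mismatch under warming ΔT is `(slope_shrub − slope_tree) · ΔT`.

**Growth.** A process-based daily simulator (Vaganov–Shashkin tradition)
turns climate into growth: piecewise-linear ramp responses to temperature
and soil moisture (leaky-bucket balance, off by default for humid treeline
sites), limited by the minimum of the two and modulated by normalized day
length. Annual sums give ring-width indices; a genetic algorithm calibrates
the temperature thresholds by maximizing the Pearson correlation with an
observed detrended chronology, retaining fits significant at P < 0.05.
Standard dendro plumbing — Tucson/RWL I/O, spline/negative-exponential
detrending, chronology building, 21-year moving correlations with summer
temperature — is included.

A synthetic-data module generates complete multi-site studies (daily
climate with an asymmetric seasonal cycle, warming trends and interannual
anomalies; onsets from the chilling-dependent heat rule with the shrub
slope 3.2× the tree slope; ring widths declining with onset) so the whole
chain can be validated as recovery of known generating parameters.

## Worked example

Generate a synthetic eight-site study and run the chilling/forcing and
response analyses:

```
$ cambiomatch synth --out demo --seed 11
wrote 8 climate series, 1248 phenology records, 32 ring-width series to demo

$ cambiomatch forcing --climate-dir demo/inputs \
      --phenology demo/inputs/phenology.csv --out demo/cf.csv
window (-5,0): AIC = 8030.02
window (-10,0): AIC = 8674.41
window (0,5): AIC = 9829.34
window (-5,5): AIC = 11932.81
                        estimate        se           t
term
Intercept             186.281846  2.008719   92.736632
Chilling               -1.971414  0.010724 -183.824911
Life form             -84.020468  1.926508  -43.612831
Chilling x life form    1.345486  0.014515   92.698366
shrub/tree chilling slope ratio: 3.15

$ cambiomatch respond --cf-table demo/cf.csv
shrub: +5.01 days/degC (R^2 = 0.06, n = 624, p = 5.4e-10)
tree: -4.21 days/degC (R^2 = 0.37, n = 624, p = 2.79e-64)
slope contrast: t = -11.18, p = 9.8e-28 (df = 1244)
projected mismatch at +2 degC: 18.4 days
```

Reading the output: the −5…0 °C chilling window is correctly identified by
lowest AIC (it is the window the generator used); the mixed-model slopes
say each chilling day lowers the shrub heat requirement by ≈ 2.0 units
versus ≈ 0.63 for trees (the positive interaction under the shrub-reference
coding; ratio 3.15, generating truth 3.2). The response fits show the
divergence this trade-off produces: one extra spring °C *delays* shrub
onset by ≈ 5 days but *advances* tree onset by ≈ 4 days, so a +2 °C spring
opens an ≈ 18-day gap between the life forms' growing seasons.

`cambiomatch pipeline --out run --seed 1` runs every stage — ingestion,
window selection, the LMM, response fits, detrending and 21-year moving
correlations, GA calibration and phenology validation — and writes a
manifest with SHA-256 checksums of every artifact; the same config and seed
reproduce all outputs bit-identically.

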