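# Methods

`grainprices` implements a continental-scale analysis of staple cereal
(maize, millet, sorghum, rice) market prices: how they vary between years
with growing-season rainfall, within the year with the cropping cycle, and
across space with remoteness and climate — and how those regularities can
be used to predict prices at unsampled locations and months.  Because the
compiled multi-source price panels and gridded rasters such an analysis
consumes are external data products, the package ships a synthetic-data
generator that emulates their structure with planted, recorded parameter
values; every stage is validated by recovering what was planted.

## Price normalization

Raw observations are monthly local-currency prices per kg at a market, for
one crop, quoted retail or wholesale.  Normalization proceeds in a fixed
order:

1. **Deflation.** value = price / CPI / PPP, using the country's monthly
   consumer price index (base year 2010 = 1) and PPP conversion factor
   (local currency units per international dollar).  The result is a 2010
   PPP-adjusted USD/kg price comparable across countries and years.  Annual
   deflator tables are accepted and broadcast across months.  Records with
   no deflator row are skipped and counted; duplicate observations for one
   (market, crop, month) key collapse to their median with a logged
   collision.
2. **Wholesale conversion.** Wholesale prices are a roughly constant
   fraction of retail prices per crop.  The fraction is estimated by a
   through-origin regression of wholesale on retail over co-reported
   (market, month) pairs, pooled across countries — through the origin
   because the quantity of interest is a price *ratio*; an intercept is
   available as an option.  Wholesale-only series are divided by the slope
   to retail equivalents; reported retail always wins where both exist.
   With fewer than two co-reporting markets for a crop the conversion falls
   back to configured default ratios (0.88 maize, 0.91 millet, 0.94
   sorghum, 0.83 rice).
3. **Maize equivalents.** For markets reporting other cereals but no maize,
   a maize price is estimated from the co-reporting markets' market-year
   *median* prices via with-intercept OLS (one map per cereal, the map with
   the lowest residual error preferred).  At least 10 co-reporting
   market-years are required; imputation never overwrites an observed maize
   price.  These rows exist only to widen spatial coverage for the maize
   price surface and are tagged `maize_equivalent`.

Every output row carries a `source_type` so downstream stages can condition
on provenance.

## Harvest calendars from precipitation

Cropping calendars are held fixed across years: season rainfall totals vary
strongly between years, but season timing barely moves.  For each location:

* the wetness threshold is the median of the 12 climatological monthly
  precipitation values, clamped to [30, 90] mm;
* growing seasons are maximal *circular* runs of consecutive months at or
  above the threshold (a run across the December–January boundary is one
  season); the minimum run length defaults to 1 month and is configurable;
* harvest begins in the month immediately after a run ends;
* locations with annual precipitation under 200 mm, or with no qualifying
  run, are arid: no harvest month, excluded from the seasonal analysis.

Design choices where the rule is underdetermined: the "median monthly
precipitation" is the median of the climatological monthly means (not of
all raw months), because a fixed calendar is wanted; if more than two runs
qualify, the two with the largest run totals are kept (one or two seasons
is the empirically relevant range), ties breaking toward the earlier start
month; a climatology in which all 12 months are wet has no post-run month,
so such locations get no harvest month either (flagged `year_round` rather
than arid).  Months-since-harvest is the smallest non-negative circular
distance to any harvest month, so two-season locations max out below 11.

## Annual variation: lagged season rainfall

Prices are aggregated into *harvest years* — windows from one harvest month
to the month before the next, hence shorter than 12 months at two-season
markets, each window one observation.  Each window gets the median
normalized price and the total observed (not climatological) rainfall of
the growing season preceding its opening harvest; windows with incomplete
season rainfall are dropped.

Per market and crop (separately per crop, since price levels differ), series
with at least 10 harvest years are detrended by the best of three
polynomials in year — intercept-only, linear, quadratic — chosen by plain
Gaussian AIC, `n ln(RSS/n) + 2k` (AICc available as an option; with 10–19
points plain AIC is the conventional default).  The year index is centered
for conditioning only.  The detrended residuals are regressed on lagged
season rainfall by OLS; the slope, rescaled to USD/kg per 100 mm, is the
market's rainfall price effect.  Across markets, effects are summarized by
an OLS meta-regression on ln(mean rainfall) with a 95% confidence band.
The rainfall axis can be the annual total (default) or the mean
growing-season total; they differ materially only at two-season locations,
where each season carries roughly half the annual total.  Market-level
slope estimates are not independent when macro price shocks are shared
within countries — the generator's country-year shocks make this explicit —
so the meta-regression accepts a cluster mapping (market to country) and
then reports cluster-robust standard errors with t critical values; classic
OLS errors remain the default for independent effects.

A known property of the two-stage procedure: when the AIC picks a linear or
quadratic trend, part of the rainfall-driven variation is absorbed by the
trend, attenuating the recovered slope by a few percent at n = 15.  The
recovery experiments below include this attenuation; it stays well inside
their tolerance.

## Seasonal variation: the temporal price index

The temporal price index of a market-crop series is the mean price in each
calendar month divided by the median of the whole series (all years — a
per-year median would absorb annual shocks into the seasonal shape).
Months without observations stay undefined; nothing is imputed.  The index
is scale-free, so market price levels drop out and seasonal shapes can be
pooled across space.

Re-keying each defined month by months since harvest aligns markets with
different calendars.  The pooled cloud (one point per market-month, all
crops pooled) is summarized by two OLS lines: a post-harvest decline and a
lean-season rise.  The integer breakpoint (candidates 1–6 months after
harvest) is chosen by exhaustive SSE minimization with the boundary month
shared by both segments — sharing the trough anchors both lines to it,
which is what makes the breakpoint identifiable when the underlying shape
is continuous.  The reported lines are then refit on the disjoint
partition (boundary month with the decline), which guarantees the
two-segment fit is never worse than a single line.  A continuity-enforced
(hinge) variant is available.  Flat input produces zero slopes and a
degenerate-breakpoint flag.  The spread of the cloud is reported as a
central-70% envelope (15th–85th percentile per month bin).

## Spatio-temporal prediction

Two random-forest regressions (500 trees, fixed seed, single-threaded for
reproducibility), each judged against an explicit null model with
10-fold cross-validation grouped by market, so no market contributes to
both sides of a fold — the question of interest is generalization to
unsampled *locations*.  Skill is reported as pooled out-of-fold Pearson r
and RMSE, and as the relative score `TE_R = 1 − RMSE/RMSE_null` (NaN and
flagged when the null RMSE is zero).  Out-of-bag R² is reported alongside;
neither is privileged.

* **Temporal model** — response: the temporal price index; features:
  longitude, latitude, that month's local precipitation (mean of the
  monthly climatology over grid cells within a 50 km great-circle buffer of
  the market; an empty buffer falls back to the nearest cell), the month,
  and its sine/cosine encoding so December and January are adjacent (raw
  month is retained; a raw-only mode exists).  Null model: index ≡ 1, i.e.
  no seasonal variation.
* **Spatial model** — response: market median maize price including maize
  equivalents; features: longitude, latitude, annual precipitation, and
  travel time to the nearest town of three population classes (20k–50k,
  200k–250k, 1M–5M inhabitants).  Null model: the training-fold mean price
  (the natural no-spatial-information baseline).

Prediction surfaces are computed per grid cell of a covariate stack held as
an xarray Dataset; cells with annual precipitation below 200 mm are masked,
matching the calendar rule's arid cutoff.  The temporal model yields one
layer per month plus a per-cell annual range (max − min) layer; the spatial
model a single USD/kg layer.  Fixed seeds make surfaces bit-reproducible.

## Country-level decomposition

For countries with more than one market, per crop (an all-cereals pooled
mode exists): the **annual** range is the max − min across years of the
national mean price, averaging market-year means over markets first so
unevenly sampled markets weigh equally, and requiring at least 6 observed
months for a year to count; the **seasonal** range is each market's range
across calendar-month means, averaged over markets; the **spatial** range
is the range across per-market mean prices.  All three are
translation-equivariant and scale by any common price rescaling.

## The synthetic continent

The generator emulates, on a rectangular lon/lat domain, the joint
structure the pipeline is meant to detect.  Defaults (all configurable):

* **Rainfall** on a 0.5° grid, monthly, 14 years: three latitude regimes —
  northern unimodal (wet Jun–Sep, harvest October), equatorial bimodal
  (Mar–May and Oct–Dec, harvests June and January), southern unimodal
  spanning the year boundary (Nov–Mar, harvest April).  Mean annual totals
  decline toward the northern edge (below the 200 mm arid cutoff at the
  extreme), with a weak west–east gradient; years scale the climatology by
  a lognormal multiplier (CV 0.18) plus small monthly noise.
* **Markets**: 160 snapped to rainfall-cell centers (plus 4 in the arid
  strip to exercise exclusion rules), grouped into 12 block-shaped
  countries with their own synthetic currency, inflation path (2–10%/yr)
  and PPP factor (20–600 local units per dollar).  Roughly 25% of markets
  report both price types, 20% wholesale only, the rest retail only.
* **Prices**, multiplicative on the log scale so the index's scale
  invariance is exact by construction:

      price = base · season(msh) · exp(β/base · Δrain/100 + macro + ε)

  `base` is a crop level (0.8–1.5 USD/kg by crop, in the range typical of
  the region's cereal panels) times a longitude trend, a remoteness premium
  per travel-minute, and a lognormal market effect.  `season(msh)` is a
  V-shape over months since harvest with slopes −0.04 (decline) and +0.02
  (rise) and trough 3 months after harvest, vertically normalized so each
  market's median seasonal factor over its own calendar is exactly 1 — so
  the temporal index recovers the curve without bias.  The slopes and the
  +1.08 pre-harvest peak follow the magnitudes typical of Sub-Saharan
  cereal seasonality; with a median-1 normalization the trough lands at
  0.92, since a continuous V cannot have trough 0.96, peak 1.08 *and* those
  slopes simultaneously.  `β` is the rainfall price effect in USD/kg per
  100 mm, a linear function of ln(mean season rainfall) anchored at
  −0.05 at 500 mm and 0 at 950 mm, with small market scatter; `Δrain` is
  the window's season-rainfall anomaly.  `macro` is a per-country linear
  log trend (sd 0.02/yr) plus a common country-year shock (sd 0.18) — the
  dominant source of between-year variation, sized so the country-level
  annual range exceeds the spatial range, which in turn exceeds the
  seasonal range, as observed for cereals in the region.  Wholesale rows
  apply the per-crop ratio with 1% noise; nominal prices multiply through
  the CPI path and PPP; 20% of market-crop-months are dropped at random.
* **Covariates** on a 0.25° grid by default (5 arc-min supported; the
  coarser default keeps a desk-scale run in seconds): travel-time surfaces
  as great-circle distance to the nearest seeded town divided by a
  class-specific speed, and precipitation layers resampled from the
  rainfall climatology.

`SyntheticTruth` records every planted value (harvest months, seasonal
slopes and breakpoint, per-market β, base prices, wholesale ratios,
reporting types, expected provenance counts), so recovery tests never
re-derive truth from generated data.  One seed fixes all randomness
end-to-end.

What the generator does **not** emulate — and what passing recovery tests
therefore do not establish about real data: spatial correlation of rainfall
anomalies (cell-year multipliers are independent), price transmission and
cointegration between markets, world-market pass-through, trade-policy
discontinuities, heteroskedastic reporting error, or non-random
missingness.  The generator shows the estimators recover known structure at
realistic sizes and noise; it cannot show the structural model is right for
any particular country.

## Numerical and scale choices

* Problem sizes are desk-scale by design: 160 markets × 14 years × 4 crops
  (~60k records), a 40×40 rainfall grid, an 80×80 covariate grid; the
  recovery experiments use 100 replicates of six-market, 15-year panels and
  20 replicates of 150-market panels.
* AIC comparisons guard RSS = 0 with the smallest positive float; the
  error-variance parameter is omitted from k as a model-constant.
* Breakpoint SSE ties (flat input) resolve to the smallest candidate and
  set the degenerate flag.
* Forests run with `n_jobs=1`; grouped folds come from scikit-learn's
  GroupKFold; determinism is asserted, not assumed.
* Grids are xarray Datasets on WGS84 lon/lat coordinates; file I/O uses
  NetCDF (scipy engine) and CSV.

## Known limitations

Pooling the seasonal fit across one- and two-season markets slightly
attenuates the lean-season slope, because two-season markets only populate
the early months-since-harvest range; per-market fits are available where
this matters.  The wholesale/retail regressions pool countries (per-country
fits would need co-reporting coverage per country).  The spatial model's
null is the overall training mean; a national-mean null would be stricter
where countries differ systematically.  Arid markets are excluded rather
than modelled.  The acceptance experiments' tolerances include the small
detrending attenuation described above.
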