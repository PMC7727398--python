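# grainprices

Spatio-temporal analysis and prediction of staple cereal prices
(maize, millet, sorghum, rice) for Sub-Saharan African markets.

Local food prices are a key food-security indicator, yet market price
observations in the region are sparse — especially for rural areas — and
analyses often fall back on a single national price.  This package
implements, as a tested and reusable pipeline, the building blocks needed
to characterize and predict how cereal prices vary:

* **between years**, with the rainfall of the preceding growing season;
* **within the year**, with the cropping cycle (cheap after harvest,
  dear in the lean season);
* **across space**, with remoteness from towns and climate.

It is aimed at food-security analysts and agricultural economists who work
with monthly market price panels (FEWS NET-, GIEWS- or RATIN-style
bulletins), gridded precipitation, and travel-time surfaces.  Because those
inputs are external data products, the package includes a first-class
synthetic-data generator that emulates their structure with known planted
parameters, so every stage of the pipeline can be exercised and validated
offline.

## The methods in brief

**Normalization.** Local-currency prices are converted to 2010
PPP-adjusted USD kg⁻¹ (`value = price / CPI / PPP`), wholesale quotes are
mapped to retail equivalents through per-crop through-origin regression
slopes (wholesale ≈ 0.88× retail for maize), and maize-equivalent prices
are imputed from other cereals via affine maps fit on market-year medians.

**Harvest calendars.** A location's growing seasons are maximal circular
runs of months whose climatological precipitation reaches the median
monthly precipitation clamped to [30, 90] mm; harvest starts the month
after a run ends; locations under 200 mm yr⁻¹ are arid and excluded.

**Annual variation.** Prices are aggregated to harvest-year medians,
detrended by the AIC-best polynomial in year (degree 0/1/2), and regressed
on lagged growing-season rainfall; the per-market slopes (USD kg⁻¹ per
100 mm) are meta-regressed on ln(rainfall), capturing the stronger price
response of dry-climate markets.

**Seasonal variation.** The temporal price index — monthly mean price over
the series median — is aligned by months since harvest and summarized by a
two-segment regression: a post-harvest decline and a lean-season rise
joined at an SSE-minimizing integer breakpoint.

**Prediction.** Random forests predict (a) the temporal index from
longitude, latitude, month, and local (50-km buffered) monthly
precipitation, and (b) the maize price surface from location, annual
precipitation, and travel time to towns of three size classes.  Skill is
measured by market-grouped 10-fold cross-validation against explicit null
models, reported as Pearson r, RMSE, and the relative score
`TE_R = 1 − RMSE/RMSE_null`.

See `docs/methods.md` for assumptions, parameter choices, and limitations.

## Worked example

```python
import grainprices as gp

report = gp.run_all(gp.RunConfig(seed=1))

print(report["seasonal"])
print(report["predict"]["temporal"])
print(report["summarize"])
```

prints:

```
{'n_indices': 418, 'breakpoint': 3, 'slope_down': -0.0388152886, 'slope_up': 0.0169400202,
 'min_index': 0.9543051751, 'max_index': 1.092063323, 'sse': 8.7434983018, 'n_points': 4896,
 'degenerate': False}
{'pearson_r': 0.7896272815, 'rmse': 0.036565784, 'rmse_null': 0.0620958531,
 'te_r': 0.4111396787, 'n': 4896, 'folds': 10}
{'n_countries': 12, 'mean_annual_range': 0.7984378684, 'mean_seasonal_range': 0.2080507963,
 'mean_spatial_range': 0.6660449582}
```

Reading these numbers: pooled across the synthetic continent's markets,
prices bottom out 3 months after harvest, falling about 3.9% of the median
price per month after harvest and climbing about 1.7% per month through
the lean season (the generator plants −4%/+2%; pooling one- and two-season
markets slightly flattens the rise).  The temporal-index forest, evaluated
only on markets held out of training, correlates 0.79 with observed
indices and beats the "no seasonal variation" null by 41%.  At the country
level, between-year price swings (0.80 USD kg⁻¹ mean range) exceed
between-market differences (0.67), which dwarf the within-year cycle
(0.21).

The same stages are available from the shell:

```bash
grainprices simulate --seed 1 --out data/
grainprices normalize --prices data/prices.csv --deflators data/deflators.csv --out panel.csv
grainprices calendar --prec data/market_rain.csv --out calendars.csv
grainprices run-all --seed 1 --out run/
```

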