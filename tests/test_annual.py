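"""Harvest-year aggregation, AIC detrending, and rain-price regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from grainprices.annual import (
    PolynomialDetrend,
    effect_vs_aridity,
    gaussian_aic,
    rain_price_effects,
    rain_price_slope,
    summarize_harvest_years,
)
from grainprices.cropcal import GrowingSeasonSet
from grainprices.panel import PricePanel


def tiny_panel(values_by_period, market="M1", crop="maize"):
    rows = [
        {"market_id": market, "crop": crop, "year": y, "month": m,
         "value": v, "source_type": "reported_retail"}
        for (y, m), v in values_by_period.items()
    ]
    markets = pd.DataFrame(
        [{"market_id": market, "country": "AAA", "lon": 0.0, "lat": 0.0}]
    )
    return PricePanel(prices=pd.DataFrame(rows), markets=markets)


def one_season_calendar(harvest=10):
    run = tuple((harvest - 2 + k - 1) % 12 + 1 for k in range(-3, 0))
    start = (harvest - 6) % 12 + 1
    months = tuple((start - 1 + k) % 12 + 1 for k in range(5))
    return GrowingSeasonSet(
        threshold=30.0, seasons=((months[0], months[-1]),),
        harvest_months=(harvest,), is_arid=False, annual_total=800.0,
        season_months=(months,),
    )


def flat_rain(market="M1", years=range(2005, 2018), value=100.0):
    return pd.DataFrame(
        [(market, y, m, value) for y in years for m in range(1, 13)],
        columns=["market_id", "year", "month", "prec_mm"],
    )


class TestHarvestYearSummaries:
    def test_constant_prices_give_median_one(self):
        vals = {(y, m): 1.0 for y in range(2006, 2017) for m in range(1, 13)}
        out = summarize_harvest_years(
            tiny_panel(vals), {"M1": one_season_calendar()}, flat_rain()
        )
        assert out and all(s.median_price == 1.0 for s in out)
        assert all(s.window_len_months == 12 for s in out)

    def test_median_of_three(self):
        # one harvest-year window holding exactly three observations
        vals = {(2010, 10): 0.8, (2010, 11): 1.0, (2010, 12): 1.4}
        out = summarize_harvest_years(
            tiny_panel(vals), {"M1": one_season_calendar(10)},
            flat_rain(years=range(2009, 2012)),
        )
        (s,) = [s for s in out if s.harvest_year == 2010]
        assert s.median_price == pytest.approx(1.0)

    def test_two_harvest_markets_have_short_windows(self, small_data, small_panel,
                                                    small_calendars):
        out = summarize_harvest_years(small_panel, small_calendars, small_data.market_rain)
        bimodal = {m for m, c in small_calendars.items() if c.n_seasons == 2}
        assert bimodal
        lengths = {s.window_len_months for s in out if s.market_id in bimodal}
        assert lengths and all(l < 12 for l in lengths)

    def test_arid_markets_excluded(self, small_data, small_panel, small_calendars):
        out = summarize_harvest_years(small_panel, small_calendars, small_data.market_rain)
        arid = set(small_data.truth.arid_markets)
        assert arid and not {s.market_id for s in out} & arid


class TestDetrendSelection:
    def test_constant_series_selects_degree_zero(self, rng):
        years = np.arange(2000, 2015)
        prices = 1.0 + rng.normal(0, 1e-4, years.size)
        assert PolynomialDetrend().fit(years, prices).degree_ == 0

    def test_linear_trend_selected_in_majority(self, rng):
        years = np.arange(2000, 2015)
        hits = 0
        for _ in range(200):
            prices = 0.5 + 0.05 * (years - 2000) + rng.normal(0, 0.01, years.size)
            hits += PolynomialDetrend().fit(years, prices).degree_ == 1
        assert hits / 200 >= 0.7

    def test_aic_matches_closed_form_oracle(self, rng):
        years = np.arange(2000, 2013).astype(float)
        for _ in range(20):
            prices = rng.normal(1.0, 0.3, years.size)
            model = PolynomialDetrend().fit(years, prices)
            x = years - years.mean()
            for deg in (0, 1, 2):
                X = np.column_stack([x**d for d in range(deg + 1)])
                rss = float(sm.OLS(prices, X).fit().ssr)
                expected = years.size * np.log(rss / years.size) + 2 * (deg + 1)
                assert model.aic_values_[deg] == pytest.approx(expected, rel=1e-9)

    def test_selection_is_exhaustive_minimum(self, rng):
        years = np.arange(2000, 2014).astype(float)
        prices = rng.normal(1.0, 0.2, years.size)
        model = PolynomialDetrend().fit(years, prices)
        assert model.aic_values_[model.degree_] == min(model.aic_values_.values())

    def test_residuals_orthogonal_to_design(self, rng):
        years = np.arange(2000, 2016).astype(float)
        prices = 1.0 + 0.03 * (years - 2008) + rng.normal(0, 0.05, years.size)
        model = PolynomialDetrend().fit(years, prices)
        resid = model.residuals(years, prices)
        assert abs(resid.sum()) < 1e-8
        x = years - model.year_center_
        for d in range(model.degree_ + 1):
            assert abs(resid @ x**d) < 1e-6


class TestRainPriceSlope:
    def test_doubling_rain_halves_slope(self, rng):
        rain = rng.uniform(300, 700, 15)
        resid = rng.normal(0, 0.05, 15)
        s1 = rain_price_slope(resid, rain).slope
        s2 = rain_price_slope(resid, 2 * rain).slope
        assert s2 == pytest.approx(s1 / 2, rel=1e-9)

    def test_translation_equivariance(self, rng):
        rain = rng.uniform(300, 700, 15)
        prices = rng.normal(1.0, 0.05, 15)
        s1 = rain_price_slope(prices, rain).slope
        s2 = rain_price_slope(prices + 3.7, rain).slope
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_zero_rain_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            rain_price_slope(np.random.default_rng(0).normal(size=12), np.full(12, 500.0))

    def test_null_simulation_slope_within_two_se(self, rng):
        ok = 0
        for _ in range(200):
            resid = rng.normal(0, 0.05, 15)
            rain = rng.uniform(300, 700, 15)
            eff = rain_price_slope(resid, rain)
            ok += abs(eff.slope) < 2 * eff.se
        assert ok / 200 >= 0.90


class TestEffectVsAridity:
    def test_equal_slopes_give_zero_meta_slope(self):
        effects = [
            rain_price_slope(
                np.array([0.0] * 11 + [1e-6]), np.linspace(300, 700, 12),
                market_id=f"M{i}", mean_annual_rain=300.0 * (i + 1),
            )
            for i in range(6)
        ]
        meta, _ = effect_vs_aridity(effects)
        assert meta.slope == pytest.approx(0.0, abs=1e-9)

    def test_recovers_generated_line_within_ci(self, rng):
        a, b = -0.53, 0.078
        covered = 0
        for _ in range(20):
            rain = rng.uniform(300, 1500, 60)
            slopes = a + b * np.log(rain) + rng.normal(0, 0.01, 60)
            effects = [
                rain_price_slope(
                    rng.normal(0, 0.02, 12) + s * (np.linspace(-1, 1, 12)),
                    np.linspace(400, 600, 12) + rng.normal(0, 5, 12),
                    market_id=f"M{i}", mean_annual_rain=r,
                )
                for i, (s, r) in enumerate(zip(slopes, rain))
            ]
            # bypass estimation noise: score the meta stage on the true slopes
            for e, s in zip(effects, slopes):
                object.__setattr__(e, "slope", float(s))
            meta, _ = effect_vs_aridity(effects)
            lo, hi = meta.conf_int[1]
            covered += lo <= b <= hi
        assert covered / 20 >= 0.9

    def test_nonpositive_rain_excluded(self):
        effects = [
            rain_price_slope(
                np.random.default_rng(i).normal(0, 0.02, 12),
                np.linspace(300, 700, 12), market_id=f"M{i}",
                mean_annual_rain=200.0 * i if i else -1.0,
            )
            for i in range(7)
        ]
        meta, _ = effect_vs_aridity(effects)
        assert meta.n == 6


class TestEndToEndRecovery:
    def test_pipeline_effects_track_truth(self):
        # controlled conditions: no macro year shocks, so the only error is
        # observation noise and the detrend stage's small absorption
        from grainprices import SyntheticConfig, build_panel, calendars_from_series, simulate

        cfg = SyntheticConfig(seed=11, n_markets=30, n_arid_markets=0,
                              year_start=2002, year_end=2017,
                              country_year_sd=0.0, country_trend_sd=0.0)
        data = simulate(cfg)
        panel = build_panel(data.records, data.deflators)
        cals = calendars_from_series(data.market_rain)
        summaries = summarize_harvest_years(panel, cals, data.market_rain)
        effects = rain_price_effects(summaries, annual_rain=data.truth.mean_annual_rain)
        assert len(effects) >= 10
        err = [e.slope - data.truth.beta[e.market_id] for e in effects]
        assert abs(float(np.mean(err))) < 0.01
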