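"""Price normalization: deflation, wholesale conversion, maize equivalents."""

import numpy as np
import pandas as pd
import pytest

from grainprices.panel import (
    DEFAULT_WHOLESALE_SLOPES,
    MaizeEquivalentRegressor,
    WholesaleRetailRegressor,
    build_panel,
    deflate_prices,
    fit_maize_equivalent,
    fit_wholesale_retail,
    wholesale_to_retail,
)


def make_records(rows):
    return pd.DataFrame(
        rows,
        columns=["market_id", "country", "lon", "lat", "crop",
                 "year", "month", "price_type", "price", "currency"],
    )


def make_deflators(rows):
    return pd.DataFrame(rows, columns=["country", "year", "month", "cpi", "ppp"])


REC = ("M1", "AAA", 10.0, 5.0, "maize", 2010, 6, "retail")


class TestDeflation:
    @pytest.mark.parametrize(
        "price, cpi, ppp, expected",
        [(100.0, 1.0, 100.0, 1.0), (200.0, 2.0, 100.0, 1.0)],
    )
    def test_base_year_identity(self, price, cpi, ppp, expected):
        records = make_records([(*REC, price, "XOF")])
        deflators = make_deflators([("AAA", 2010, 6, cpi, ppp)])
        out, skipped = deflate_prices(records, deflators)
        assert skipped == 0
        assert out["value"].iloc[0] == pytest.approx(expected)

    def test_randomized_arithmetic(self, rng):
        price = rng.uniform(1, 1e4, 50)
        cpi = rng.uniform(0.2, 5, 50)
        ppp = rng.uniform(1, 1000, 50)
        records = make_records([(*REC[:6], m + 1, "retail", p, "XOF")
                                for m, p in enumerate(price[:12])])
        deflators = make_deflators([("AAA", 2010, m + 1, cpi[m], ppp[m]) for m in range(12)])
        out, _ = deflate_prices(records, deflators)
        np.testing.assert_allclose(
            out["value"].to_numpy(), price[:12] / (cpi[:12] * ppp[:12]), rtol=1e-14
        )

    def test_common_rescaling_is_neutral(self, rng):
        records = make_records([(*REC, 150.0, "XOF")])
        base = make_deflators([("AAA", 2010, 6, 1.3, 220.0)])
        scaled_rec = records.assign(price=records["price"] * 7.5)
        scaled_def = base.assign(cpi=base["cpi"] * 7.5)
        v1, _ = deflate_prices(records, base)
        v2, _ = deflate_prices(scaled_rec, scaled_def)
        assert v1["value"].iloc[0] == pytest.approx(v2["value"].iloc[0], rel=1e-14)

    def test_missing_deflator_row_skipped_and_counted(self):
        records = make_records([(*REC, 100.0, "XOF"),
                                ("M1", "AAA", 10.0, 5.0, "maize", 2011, 6, "retail", 100.0, "XOF")])
        deflators = make_deflators([("AAA", 2010, 6, 1.0, 100.0)])
        out, skipped = deflate_prices(records, deflators)
        assert skipped == 1 and len(out) == 1

    def test_annual_deflators_broadcast_across_months(self):
        records = make_records([(*REC[:6], m, "retail", 100.0, "XOF") for m in (1, 7, 12)])
        deflators = pd.DataFrame([("AAA", 2010, 1.0, 100.0)],
                                 columns=["country", "year", "cpi", "ppp"])
        out, skipped = deflate_prices(records, deflators)
        assert skipped == 0 and (out["value"] == 1.0).all()


class TestWholesaleRetail:
    def test_recovers_generated_ratio(self, rng):
        retail = rng.uniform(0.5, 2.0, 200)
        wholesale = 0.88 * retail + rng.normal(0, 0.01, 200)
        model = WholesaleRetailRegressor().fit(retail, wholesale)
        assert model.slope_ == pytest.approx(0.88, abs=0.01)

    def test_identical_prices_give_unit_slope(self):
        x = np.linspace(0.5, 2.0, 20)
        model = WholesaleRetailRegressor().fit(x, x)
        assert model.slope_ == pytest.approx(1.0)

    def test_defaults_when_fitting_disabled(self, small_data):
        models = fit_wholesale_retail(pd.DataFrame(), use_defaults=True)
        for crop, slope in DEFAULT_WHOLESALE_SLOPES.items():
            assert models[crop].slope_ == slope
        assert DEFAULT_WHOLESALE_SLOPES == {
            "maize": 0.88, "millet": 0.91, "sorghum": 0.94, "rice": 0.83
        }

    def test_conversion_and_round_trip(self):
        model = WholesaleRetailRegressor()
        model.slope_, model.intercept_ = 0.88, 0.0
        assert model.to_retail(0.88) == pytest.approx(1.0)
        unit = WholesaleRetailRegressor()
        unit.slope_, unit.intercept_ = 1.0, 0.0
        assert unit.to_retail(1.234) == pytest.approx(1.234)
        retail = 1.37
        assert model.to_retail(model.predict([retail])[0]) == pytest.approx(retail, rel=1e-14)

    def test_reported_retail_takes_precedence(self):
        df = pd.DataFrame({
            "market_id": ["M1", "M1"], "crop": ["maize"] * 2,
            "year": [2010] * 2, "month": [6] * 2,
            "price_type": ["retail", "wholesale"], "value": [1.0, 0.5],
            "country": ["AAA"] * 2, "lon": [0.0] * 2, "lat": [0.0] * 2,
            "price": [1, 1], "currency": ["X"] * 2,
        })
        models = fit_wholesale_retail(df, use_defaults=True)
        out = wholesale_to_retail(df, models)
        assert len(out) == 1
        assert out["source_type"].iloc[0] == "reported_retail"
        assert out["value"].iloc[0] == 1.0


class TestMaizeEquivalent:
    def test_recovers_affine_map(self, rng):
        rice = rng.uniform(0.8, 2.5, 120)
        maize = 0.3 + 0.6 * rice + rng.normal(0, 0.02, 120)
        model = MaizeEquivalentRegressor().fit(rice, maize)
        assert model.intercept_ == pytest.approx(0.3, abs=0.05)
        assert model.slope_ == pytest.approx(0.6, abs=0.05)

    def test_identity_input(self):
        x = np.linspace(0.5, 2.0, 30)
        model = MaizeEquivalentRegressor().fit(x, x)
        assert model.slope_ == pytest.approx(1.0, abs=1e-10)
        assert model.intercept_ == pytest.approx(0.0, abs=1e-10)

    def test_refuses_small_samples(self):
        with pytest.raises(ValueError, match="market-years"):
            MaizeEquivalentRegressor().fit(np.ones(5), np.ones(5))

    def test_rmse_plausible_on_panel_noise(self, rng):
        # monthly price scatter comparable to reported cereal panels
        rice = rng.uniform(0.8, 2.0, 300)
        maize = 0.3 + 0.6 * rice + rng.normal(0, 0.2, 300)
        model = MaizeEquivalentRegressor().fit(rice, maize)
        assert 0.1 <= model.rmse_ <= 0.4


class TestBuildPanel:
    def test_retail_only_input_has_no_conversions(self):
        records = make_records([(*REC[:6], m, "retail", 100.0, "XOF") for m in range(1, 13)])
        deflators = make_deflators([("AAA", 2010, m, 1.0, 100.0) for m in range(1, 13)])
        panel = build_panel(records, deflators)
        assert panel.source_counts() == {"reported_retail": 12}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_panel(make_records([]), make_deflators([("AAA", 2010, 1, 1.0, 1.0)]))

    def test_source_counts_match_generator_bookkeeping(self, small_data, small_panel):
        truth = small_data.truth.source_counts
        counts = small_panel.source_counts()
        assert counts["reported_retail"] == truth["reported_retail"]
        assert counts["converted_from_wholesale"] == truth["converted_from_wholesale"]

    def test_recovered_wholesale_ratios(self, small_data, small_panel):
        for crop, model in small_panel.conversion_models.items():
            if model.n_pairs_ > 50:
                assert model.slope_ == pytest.approx(
                    small_data.truth.wholesale_ratios[crop], abs=0.01
                )

    def test_imputation_never_overwrites_observed_maize(self, small_data, small_panel):
        maize = small_panel.prices[small_panel.prices["crop"] == "maize"]
        markets_with_observed = set(
            maize.loc[maize["source_type"] != "maize_equivalent", "market_id"]
        )
        imputed_markets = set(
            maize.loc[maize["source_type"] == "maize_equivalent", "market_id"]
        )
        assert not markets_with_observed & imputed_markets

    def test_duplicate_observations_collapse_to_median(self):
        rows = [(*REC, p, "XOF") for p in (90.0, 100.0, 140.0)]
        records = make_records(rows)
        deflators = make_deflators([("AAA", 2010, 6, 1.0, 100.0)])
        panel = build_panel(records, deflators)
        assert len(panel.prices) == 1
        assert panel.prices["value"].iloc[0] == pytest.approx(1.0)

    def test_maize_equivalent_fit_on_panel(self, small_panel):
        models = fit_maize_equivalent(small_panel.prices)
        assert models  # at least one cereal co-reported with maize
        for m in models.values():
            assert m.n_market_years_ >= 10 and np.isfinite(m.rmse_)
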