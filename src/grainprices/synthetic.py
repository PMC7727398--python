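"""Synthetic rainfall, covariate, and market-price panel generator.

Stands in for the compiled multi-source price panel (FEWS NET-style monthly
market bulletins), gridded monthly precipitation, climatological annual
precipitation, and travel-time surfaces that the real analysis consumes.
Every structural feature the pipeline is meant to detect is planted with a
known value and recorded in :class:`SyntheticTruth`, so recovery tests can
score each stage without re-deriving anything from the generated data.

What is emulated
----------------
* a rectangular "continent" with three rainfall regimes by latitude band —
  a northern unimodal wet season (Jun-Sep, harvest October), an equatorial
  bimodal regime (Mar-May and Oct-Dec, harvests June and January), and a
  southern unimodal season spanning the year boundary (Nov-Mar, harvest
  April) — with mean annual rainfall declining toward the northern edge,
  where cells drop below the 200 mm arid cutoff;
* markets snapped to rainfall-cell centers, grouped into block-shaped
  countries with their own currency, CPI inflation path, and PPP factor;
* a multiplicative monthly price model per market and crop:

    price = base * season(months_since_harvest) * exp(beta/base * rain_anom/100 + eps)

  where ``base`` carries a longitude trend and a remoteness premium, the
  seasonal factor is a V-shape (decline after harvest, rise through the lean
  season) normalized so each market's median seasonal factor is 1, and
  ``beta`` (USD/kg per 100 mm of lagged season rainfall) follows a linear
  function of ln(mean season rainfall) that vanishes at wet sites;
* retail/wholesale reporting mixtures with fixed per-crop price ratios,
  nominal local-currency quoting, and missing observations.

The model is multiplicative on the log scale so the temporal price index's
scale invariance holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from .cropcal import detect_seasons, months_since_harvest, MonthlyClimatology
from .panel import CROPS, DEFAULT_WHOLESALE_SLOPES
from .spatial import haversine_km

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticDataset", "simulate"]

_WET_MONTHS = {
    "unimodal_north": ((6, 7, 8, 9),),
    "bimodal": ((3, 4, 5), (10, 11, 12)),
    "unimodal_south": ((11, 12, 1, 2, 3),),
}
_WET_FRACTION = {"unimodal_north": 0.92, "bimodal": 0.93, "unimodal_south": 0.90}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic continent; the seed fixes every draw."""

    seed: int = 0
    n_markets: int = 160
    n_arid_markets: int = 4
    year_start: int = 2004
    year_end: int = 2017
    crops: tuple[str, ...] = CROPS

    # domain and grids (decimal degrees)
    lon_min: float = 0.0
    lon_max: float = 20.0
    lat_min: float = -10.0
    lat_max: float = 10.0
    res_rain: float = 0.5
    res_cov: float = 0.25

    # rainfall field: mean annual total (mm) and variability
    annual_base: float = 1350.0
    lat_north_slope: float = 140.0  # mm lost per degree north of the equator
    lat_south_slope: float = 60.0
    lon_slope: float = 6.0
    interannual_cv: float = 0.18
    month_noise_sd: float = 0.03
    bimodal_lat: float = 4.0

    # seasonal V-shape of the price cycle (index units per month)
    slope_down: float = -0.04
    slope_up: float = 0.02
    min_month: int = 3  # months after harvest at which prices bottom out

    # rainfall price effect: beta(rain) = meta line in ln(mean season rain)
    slope_at_500mm: float = -0.05  # USD/kg per 100 mm at a 500 mm site
    zero_effect_rain: float = 950.0  # mm above which the effect vanishes
    beta_scatter_sd: float = 0.004

    # observation model
    noise_sd: float = 0.05  # sd of log price noise
    country_year_sd: float = 0.18  # sd of the common log price shock per country-year
    country_trend_sd: float = 0.02  # sd of per-country log price trend (per year)
    missing_rate: float = 0.20
    share_both: float = 0.25  # markets reporting retail and wholesale
    share_wholesale_only: float = 0.20
    wholesale_ratios: dict = field(default_factory=lambda: dict(DEFAULT_WHOLESALE_SLOPES))
    wholesale_noise_sd: float = 0.01

    # price levels
    crop_base: dict = field(
        default_factory=lambda: {"maize": 0.80, "millet": 1.00, "sorghum": 0.90, "rice": 1.50}
    )
    lon_trend: float = 0.012  # fractional price increase per degree east
    remoteness_premium: float = 0.0010  # fractional increase per travel-minute
    market_effect_sd: float = 0.08
    maize_share: float = 0.70  # markets reporting maize
    other_crop_share: float = 0.50

    # countries and deflators
    n_lon_blocks: int = 4
    n_lat_blocks: int = 3
    inflation_range: tuple[float, float] = (0.02, 0.10)
    ppp_range: tuple[float, float] = (20.0, 600.0)

    # towns per size class (small 20k-50k, mid 200k-250k, large 1M-5M)
    n_towns: tuple[int, int, int] = (25, 6, 2)
    town_speed_kmh: tuple[float, float, float] = (40.0, 60.0, 80.0)

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def meta_slope(self) -> float:
        """Slope of beta on ln(rain): fixed by the 500 mm and zero-cross anchors."""
        return -self.slope_at_500mm / math.log(self.zero_effect_rain / 500.0)

    @property
    def meta_intercept(self) -> float:
        return -self.meta_slope * math.log(self.zero_effect_rain)

    def beta_of_rain(self, mean_season_rain: float) -> float:
        return self.meta_intercept + self.meta_slope * math.log(mean_season_rain)


@dataclass
class SyntheticTruth:
    """Planted parameter values, sufficient to score every recovery test."""

    harvest_months: dict
    seasonal_slope_down: float
    seasonal_slope_up: float
    seasonal_breakpoint: int
    beta: dict  # market_id -> USD/kg per 100 mm
    mean_season_rain: dict  # market_id -> mm (averaged over seasons)
    mean_annual_rain: dict  # market_id -> mm
    base_price: dict  # (market_id, crop) -> USD/kg
    wholesale_ratios: dict
    market_type: dict  # market_id -> retail | wholesale | both
    meta_intercept: float
    meta_slope: float
    source_counts: dict  # expected panel counts by source_type
    arid_markets: tuple

    def as_jsonable(self) -> dict:
        d = asdict(self)
        d["base_price"] = {f"{m}|{c}": v for (m, c), v in self.base_price.items()}
        d["harvest_months"] = {k: list(v) for k, v in self.harvest_months.items()}
        d["arid_markets"] = list(self.arid_markets)
        return d


@dataclass
class SyntheticDataset:
    """Everything one simulation run produces."""

    config: SyntheticConfig
    records: pd.DataFrame  # raw price records (nominal local currency)
    deflators: pd.DataFrame
    markets: pd.DataFrame  # market_id, country, lon, lat, tt_*, regime
    rain: xr.Dataset  # monthly precipitation, dims (year, month, lat, lon)
    climatology: xr.DataArray  # dims (month, lat, lon)
    market_rain: pd.DataFrame  # long (market_id, year, month, prec_mm)
    covariates: xr.Dataset
    truth: SyntheticTruth


def _regime(lat: float, cfg: SyntheticConfig) -> str:
    if lat > cfg.bimodal_lat:
        return "unimodal_north"
    if lat < -cfg.bimodal_lat:
        return "unimodal_south"
    return "bimodal"


def _monthly_fractions(regime: str) -> np.ndarray:
    frac = np.zeros(12)
    wet_runs = _WET_MONTHS[regime]
    wet_months = [m for run in wet_runs for m in run]
    wet_f = _WET_FRACTION[regime] / len(wet_months)
    dry_f = (1.0 - _WET_FRACTION[regime]) / (12 - len(wet_months))
    for m in range(1, 13):
        frac[m - 1] = wet_f if m in wet_months else dry_f
    return frac


def _annual_mean(lon: np.ndarray, lat: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    a = (
        cfg.annual_base
        - cfg.lat_north_slope * np.maximum(lat, 0.0)
        - cfg.lat_south_slope * np.maximum(-lat, 0.0)
        + cfg.lon_slope * (lon - cfg.lon_min)
    )
    return np.maximum(a, 10.0)


def _gen_rainfall(cfg: SyntheticConfig, rng: np.random.Generator):
    lons = np.arange(cfg.lon_min + cfg.res_rain / 2, cfg.lon_max, cfg.res_rain)
    lats = np.arange(cfg.lat_min + cfg.res_rain / 2, cfg.lat_max, cfg.res_rain)
    glon, glat = np.meshgrid(lons, lats)
    annual = _annual_mean(glon, glat, cfg)

    frac = np.empty((12, len(lats), len(lons)))
    for i, la in enumerate(lats):
        frac[:, i, :] = _monthly_fractions(_regime(la, cfg))[:, None]
    clim_values = frac * annual[None, :, :]

    years = list(cfg.years)
    s_year = math.sqrt(math.log(1 + cfg.interannual_cv**2))
    year_mult = np.exp(rng.normal(-s_year**2 / 2, s_year, size=(len(years), len(lats), len(lons))))
    s_m = cfg.month_noise_sd
    month_mult = (
        np.exp(rng.normal(-s_m**2 / 2, s_m, size=(len(years), 12, len(lats), len(lons))))
        if s_m > 0
        else np.ones((len(years), 12, len(lats), len(lons)))
    )
    series = clim_values[None, :, :, :] * year_mult[:, None, :, :] * month_mult

    rain = xr.Dataset(
        {"prec": (("year", "month", "lat", "lon"), series)},
        coords={"year": years, "month": list(range(1, 13)), "lat": lats, "lon": lons},
    )
    clim = rain["prec"].mean("year").rename("prec_clim")
    return rain, clim


def _place_markets(cfg: SyntheticConfig, rng: np.random.Generator, rain: xr.Dataset):
    lats = rain["lat"].values
    lons = rain["lon"].values
    clim_annual = rain["prec"].mean("year").sum("month").values  # (lat, lon)
    wet_cells = np.argwhere(clim_annual >= 250.0)
    arid_cells = np.argwhere(clim_annual < 200.0)
    pick = rng.choice(len(wet_cells), size=min(cfg.n_markets, len(wet_cells)), replace=False)
    rows = []
    for k, idx in enumerate(pick):
        i, j = wet_cells[idx]
        rows.append(("M%03d" % k, float(lons[j]), float(lats[i]), i, j, False))
    if cfg.n_arid_markets and len(arid_cells):
        pick_a = rng.choice(len(arid_cells), size=min(cfg.n_arid_markets, len(arid_cells)),
                            replace=False)
        for k, idx in enumerate(pick_a):
            i, j = arid_cells[idx]
            rows.append(("A%03d" % k, float(lons[j]), float(lats[i]), i, j, True))
    df = pd.DataFrame(rows, columns=["market_id", "lon", "lat", "cell_i", "cell_j", "arid_zone"])
    # block countries: synthetic ISO-3-like codes
    li = np.minimum(
        ((df["lon"] - cfg.lon_min) / (cfg.lon_max - cfg.lon_min) * cfg.n_lon_blocks).astype(int),
        cfg.n_lon_blocks - 1,
    )
    bi = np.minimum(
        ((df["lat"] - cfg.lat_min) / (cfg.lat_max - cfg.lat_min) * cfg.n_lat_blocks).astype(int),
        cfg.n_lat_blocks - 1,
    )
    df["country"] = ["S" + chr(ord("A") + a) + chr(ord("A") + b) for a, b in zip(li, bi)]
    df["regime"] = [_regime(la, cfg) for la in df["lat"]]
    return df


def _gen_towns(cfg: SyntheticConfig, rng: np.random.Generator, lons: np.ndarray, lats: np.ndarray):
    towns = {}
    for cls, n in zip(("small", "mid", "large"), cfg.n_towns):
        ti = rng.choice(len(lats), size=n)
        tj = rng.choice(len(lons), size=n)
        towns[cls] = (lons[tj], lats[ti])
    return towns


def _travel_minutes(lon, lat, towns_cls, speed_kmh):
    tl, tb = towns_cls
    d = np.min(
        haversine_km(lon[..., None], lat[..., None], tl[None, :], tb[None, :]), axis=-1
    )
    return d / speed_kmh * 60.0


def _gen_covariates(cfg: SyntheticConfig, rng: np.random.Generator, clim: xr.DataArray):
    lons = np.arange(cfg.lon_min + cfg.res_cov / 2, cfg.lon_max, cfg.res_cov)
    lats = np.arange(cfg.lat_min + cfg.res_cov / 2, cfg.lat_max, cfg.res_cov)
    towns = _gen_towns(cfg, rng, lons, lats)
    glon, glat = np.meshgrid(lons, lats)
    layers = {}
    for cls, speed in zip(("small", "mid", "large"), cfg.town_speed_kmh):
        layers[f"tt_{cls}"] = (("lat", "lon"), _travel_minutes(glon, glat, towns[cls], speed))
    clim_on_cov = clim.sel(lon=xr.DataArray(lons, dims="lon"),
                           lat=xr.DataArray(lats, dims="lat"), method="nearest")
    clim_on_cov = clim_on_cov.assign_coords(lon=lons, lat=lats)
    ds = xr.Dataset(
        {
            **layers,
            "annual_prec": (("lat", "lon"), clim_on_cov.sum("month").values),
            "prec_clim": (("month", "lat", "lon"), clim_on_cov.values),
        },
        coords={"lat": lats, "lon": lons, "month": list(range(1, 13))},
    )
    for cls in ("small", "mid", "large"):
        ds[f"towns_{cls}_lon"] = (f"town_{cls}", towns[cls][0])
        ds[f"towns_{cls}_lat"] = (f"town_{cls}", towns[cls][1])
    return ds, towns


def _seasonal_curve(cfg: SyntheticConfig) -> np.ndarray:
    """Raw V-shape over months since harvest 0..11 (0 at the minimum)."""
    b = cfg.min_month
    f = np.empty(12)
    for msh in range(12):
        f[msh] = cfg.slope_down * (msh - b) if msh <= b else cfg.slope_up * (msh - b)
    return f


def _market_seasonal_factor(cfg: SyntheticConfig, harvests: tuple[int, ...]) -> dict[int, float]:
    """Seasonal factor per calendar month, median-1 over the market's year."""
    f = _seasonal_curve(cfg)

    class _Cal:  # minimal stand-in with the harvest months
        harvest_months = harvests

    msh_by_month = {m: months_since_harvest(m, _Cal) for m in range(1, 13)}
    vals = np.array([f[msh_by_month[m]] for m in range(1, 13)])
    med = float(np.median(vals))
    return {m: 1.0 + f[msh_by_month[m]] - med for m in range(1, 13)}


def _harvest_windows(harvests: tuple[int, ...]) -> list[tuple[int, int]]:
    """(harvest_month, window_length) pairs covering the 12-month cycle."""
    hs = sorted(harvests)
    return [(h, ((hs[(i + 1) % len(hs)] - h) % 12 or 12)) for i, h in enumerate(hs)]


def simulate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Run the full generator; same config (incl. seed) gives identical output."""
    cfg = config or SyntheticConfig()
    root = np.random.SeedSequence(cfg.seed)
    rng_rain, rng_mkt, rng_cov, rng_price = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    rain, clim = _gen_rainfall(cfg, rng_rain)
    markets = _place_markets(cfg, rng_mkt, rain)
    covariates, towns = _gen_covariates(cfg, rng_cov, clim)

    # market travel times straight from the town seeds (consistent with grid)
    for cls, speed in zip(("small", "mid", "large"), cfg.town_speed_kmh):
        markets[f"tt_{cls}"] = _travel_minutes(
            markets["lon"].to_numpy(), markets["lat"].to_numpy(), towns[cls], speed
        )

    # per-market rainfall series and calendars from the generated climatology
    market_rain_rows = []
    calendars = {}
    prec = rain["prec"].values  # (year, month, lat, lon)
    years = list(cfg.years)
    for row in markets.itertuples(index=False):
        series = prec[:, :, row.cell_i, row.cell_j]
        for yi, y in enumerate(years):
            for m in range(12):
                market_rain_rows.append((row.market_id, y, m + 1, float(series[yi, m])))
        cell_clim = clim.values[:, row.cell_i, row.cell_j]
        calendars[row.market_id] = detect_seasons(
            MonthlyClimatology(tuple(cell_clim), lon=row.lon, lat=row.lat)
        )
    market_rain = pd.DataFrame(
        market_rain_rows, columns=["market_id", "year", "month", "prec_mm"]
    )

    # countries: inflation path and PPP
    countries = sorted(markets["country"].unique())
    infl = {c: rng_price.uniform(*cfg.inflation_range) for c in countries}
    ppp = {
        c: float(np.exp(rng_price.uniform(np.log(cfg.ppp_range[0]), np.log(cfg.ppp_range[1]))))
        for c in countries
    }
    deflator_rows = []
    for c in countries:
        for y in years:
            for m in range(1, 13):
                cpi = (1 + infl[c]) ** ((y - 2010) + (m - 1) / 12.0)
                deflator_rows.append((c, y, m, cpi, ppp[c]))
    deflators = pd.DataFrame(deflator_rows, columns=["country", "year", "month", "cpi", "ppp"])
    cpi_lut = {(r[0], r[1], r[2]): r[3] for r in deflator_rows}

    # country-level real price dynamics: a log-linear trend plus a common
    # shock per country-year (macro events, trade policy, fuel costs) —
    # the dominant source of between-year price variation
    trend = {c: rng_price.normal(0, cfg.country_trend_sd) for c in countries}
    year_shock = {
        (c, y): rng_price.normal(0, cfg.country_year_sd) for c in countries for y in years
    }

    # market reporting type and crop coverage
    type_draw = rng_price.random(len(markets))
    m_type = np.where(
        type_draw < cfg.share_both, "both",
        np.where(type_draw < cfg.share_both + cfg.share_wholesale_only, "wholesale", "retail"),
    )
    markets = markets.assign(report_type=m_type)

    records = []
    truth_beta, truth_msr, truth_mar, truth_base, truth_harv = {}, {}, {}, {}, {}
    n_retail_periods = 0
    n_conv_periods = 0
    arid_ids = tuple(markets.loc[markets["arid_zone"], "market_id"])

    for row in markets.itertuples(index=False):
        mkt = row.market_id
        cal = calendars[mkt]
        country = row.country
        rain_series = market_rain[market_rain["market_id"] == mkt]
        rain_lut = {
            (int(y), int(m)): v
            for y, m, v in rain_series[["year", "month", "prec_mm"]].itertuples(index=False)
        }
        annual_by_year = rain_series.groupby("year")["prec_mm"].sum()
        truth_mar[mkt] = float(annual_by_year.mean())
        truth_harv[mkt] = tuple(cal.harvest_months)

        crops = [c for c in cfg.crops
                 if (c == "maize" and rng_price.random() < cfg.maize_share)
                 or (c != "maize" and rng_price.random() < cfg.other_crop_share)]
        if not crops:
            crops = [str(rng_price.choice(list(cfg.crops)))]

        if cal.harvest_months:
            season_by_harvest = {
                r[-1] % 12 + 1: r for r in cal.season_months
            }
            # lagged season rain per harvest window, and the market mean
            windows = _harvest_windows(tuple(cal.harvest_months))
            season_rain: dict[tuple[int, int], float] = {}
            for h, _ in windows:
                months = season_by_harvest[h]
                for y in years:
                    tot, ok = 0.0, True
                    for m in months:
                        yy = y if m < h else y - 1
                        v = rain_lut.get((yy, m))
                        if v is None:
                            ok = False
                            break
                        tot += v
                    if ok:
                        season_rain[(h, y)] = tot
            msr = float(np.mean(list(season_rain.values()))) if season_rain else float("nan")
            truth_msr[mkt] = msr
            beta = cfg.beta_of_rain(msr) + rng_price.normal(0, cfg.beta_scatter_sd)
            sfactor = _market_seasonal_factor(cfg, tuple(cal.harvest_months))
            # map each calendar (year, month) to its harvest window
            window_of: dict[tuple[int, int], tuple[int, int]] = {}
            for h, length in windows:
                for y in years:
                    for k in range(length):
                        m = (h - 1 + k) % 12 + 1
                        yy = y + (h - 1 + k) // 12
                        window_of[(yy, m)] = (h, y)
        else:
            truth_msr[mkt] = float("nan")
            beta = 0.0
            sfactor = {m: 1.0 for m in range(1, 13)}
            window_of = {}
            season_rain = {}
        truth_beta[mkt] = float(beta)

        per_harvest_mean = {}
        if season_rain:
            sr = pd.Series(season_rain)
            per_harvest_mean = sr.groupby(level=0).mean().to_dict()

        for crop in crops:
            base = (
                cfg.crop_base[crop]
                * (1 + cfg.lon_trend * (row.lon - cfg.lon_min))
                * (1 + cfg.remoteness_premium * row.tt_small)
                * float(np.exp(rng_price.normal(0, cfg.market_effect_sd)))
            )
            truth_base[(mkt, crop)] = base
            ratio = cfg.wholesale_ratios[crop]
            for y in years:
                for m in range(1, 13):
                    if rng_price.random() < cfg.missing_rate:
                        continue
                    win = window_of.get((y, m))
                    x = 0.0
                    if win is not None and win in season_rain:
                        x = (season_rain[win] - per_harvest_mean[win[0]]) / 100.0
                    eps = rng_price.normal(0, cfg.noise_sd)
                    macro = trend[country] * (y - 2010) + year_shock[(country, y)]
                    usd = base * sfactor[m] * math.exp((beta / base) * x + macro + eps)
                    nominal = usd * cpi_lut[(country, y, m)] * ppp[country]
                    cur = "CU" + country[-2:]
                    rtype = row.report_type
                    if rtype in ("retail", "both"):
                        records.append((mkt, country, row.lon, row.lat, crop, y, m,
                                        "retail", nominal, cur))
                        n_retail_periods += 1
                    if rtype in ("wholesale", "both"):
                        w_usd = ratio * usd * math.exp(rng_price.normal(0, cfg.wholesale_noise_sd))
                        w_nom = w_usd * cpi_lut[(country, y, m)] * ppp[country]
                        records.append((mkt, country, row.lon, row.lat, crop, y, m,
                                        "wholesale", w_nom, cur))
                        if rtype == "wholesale":
                            n_conv_periods += 1

    records_df = pd.DataFrame(
        records,
        columns=["market_id", "country", "lon", "lat", "crop",
                 "year", "month", "price_type", "price", "currency"],
    )
    truth = SyntheticTruth(
        harvest_months=truth_harv,
        seasonal_slope_down=cfg.slope_down,
        seasonal_slope_up=cfg.slope_up,
        seasonal_breakpoint=cfg.min_month,
        beta=truth_beta,
        mean_season_rain=truth_msr,
        mean_annual_rain=truth_mar,
        base_price=truth_base,
        wholesale_ratios=dict(cfg.wholesale_ratios),
        market_type=dict(zip(markets["market_id"], markets["report_type"])),
        meta_intercept=cfg.meta_intercept,
        meta_slope=cfg.meta_slope,
        source_counts={
            "reported_retail": n_retail_periods,
            "converted_from_wholesale": n_conv_periods,
        },
        arid_markets=arid_ids,
    )
    markets_out = markets[
        ["market_id", "country", "lon", "lat", "regime", "report_type",
         "tt_small", "tt_mid", "tt_large", "arid_zone"]
    ].copy()
    return SyntheticDataset(
        config=cfg,
        records=records_df,
        deflators=deflators,
        markets=markets_out,
        rain=rain,
        climatology=clim,
        market_rain=market_rain,
        covariates=covariates,
        truth=truth,
    )
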