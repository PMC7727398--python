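"""Country-level comparison of annual, seasonal, and spatial price ranges.

For each country with more than one market, three ranges (max minus min, in
USD/kg) decompose where price variation lives:

* annual — range across years of the national mean price (market-year means
  averaged over markets, so unevenly sampled markets weigh equally);
* seasonal — per-market range across calendar-month mean prices, averaged
  over the country's markets;
* spatial — range across the country's per-market mean prices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = ["CountryVariation", "country_ranges"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountryVariation:
    country: str
    crop: str
    annual_range: float
    seasonal_range: float
    spatial_range: float
    n_markets: int


def _ranges_for(df: pd.DataFrame, min_months_per_year: int) -> tuple[float, float, float]:
    # annual: markets averaged first, then range over years with enough coverage
    month_counts = df.groupby("year")["month"].size()
    ok_years = month_counts[month_counts >= min_months_per_year].index
    market_year = df.groupby(["market_id", "year"])["value"].mean().reset_index()
    national_year = (
        market_year[market_year["year"].isin(ok_years)].groupby("year")["value"].mean()
    )
    annual = float(national_year.max() - national_year.min()) if len(national_year) > 1 else 0.0

    monthly = df.groupby(["market_id", "month"])["value"].mean()
    per_market_season = monthly.groupby("market_id").agg(lambda s: s.max() - s.min())
    seasonal = float(per_market_season.mean())

    per_market_mean = df.groupby("market_id")["value"].mean()
    spatial = float(per_market_mean.max() - per_market_mean.min())
    return annual, seasonal, spatial


def country_ranges(
    panel,
    *,
    crop: str | None = None,
    pool_crops: bool = False,
    min_months_per_year: int = 6,
) -> list[CountryVariation]:
    """Annual/seasonal/spatial price ranges per country.

    Computed per crop by default (``crop`` restricts to one); ``pool_crops``
    pools all cereals into a single computation per country.  Countries with
    a single market are skipped with a log entry; national yearly means
    require at least ``min_months_per_year`` observed months across the
    country's markets.
    """
    df = panel.prices.merge(panel.markets[["market_id", "country"]], on="market_id")
    if crop is not None:
        df = df[df["crop"] == crop]
    crop_groups = [("all", df)] if pool_crops else list(df.groupby("crop"))
    out: list[CountryVariation] = []
    for crop_name, cdf in crop_groups:
        for country, grp in cdf.groupby("country"):
            n_markets = grp["market_id"].nunique()
            if n_markets < 2:
                logger.info("skipping %s/%s: single market", country, crop_name)
                continue
            annual, seasonal, spatial = _ranges_for(grp, min_months_per_year)
            out.append(CountryVariation(
                country=str(country), crop=str(crop_name),
                annual_range=annual, seasonal_range=seasonal,
                spatial_range=spatial, n_markets=int(n_markets),
            ))
    return out
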