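"""Harmonization of raw market price records into a comparable panel.

Raw observations are monthly local-currency prices per kg for one crop at one
market, reported as retail or wholesale.  Normalization makes them comparable
across countries and years:

1. deflation — divide by the country's monthly consumer price index (base
   year 2010 = 1) and by the PPP conversion factor (local currency units per
   international dollar), giving 2010 PPP-adjusted USD per kg;
2. wholesale-to-retail conversion — wholesale prices are a roughly constant
   fraction of retail prices per crop; the fraction is fit where both are
   co-reported and used to scale wholesale-only series up to retail
   equivalents (reported retail always takes precedence);
3. maize-equivalent imputation — for markets without maize, a maize price is
   estimated from another cereal via a linear map fit on market-year median
   prices, to widen coverage for spatial maize-price modelling.

Every output row carries a ``source_type`` recording which path produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CROPS",
    "DEFAULT_WHOLESALE_SLOPES",
    "PricePanel",
    "WholesaleRetailRegressor",
    "MaizeEquivalentRegressor",
    "deflate_prices",
    "fit_wholesale_retail",
    "wholesale_to_retail",
    "fit_maize_equivalent",
    "build_panel",
]

logger = logging.getLogger(__name__)

CROPS = ("maize", "millet", "sorghum", "rice")

#: Fallback wholesale/retail price ratios used when too few co-reported
#: pairs exist to fit one.
DEFAULT_WHOLESALE_SLOPES = {"maize": 0.88, "millet": 0.91, "sorghum": 0.94, "rice": 0.83}

RECORD_COLUMNS = [
    "market_id", "country", "lon", "lat", "crop",
    "year", "month", "price_type", "price", "currency",
]


@dataclass
class PricePanel:
    """Normalized monthly prices plus the georeferenced market registry.

    ``prices`` columns: market_id, crop, year, month, value (2010 PPP USD/kg),
    source_type (reported_retail | converted_from_wholesale | maize_equivalent).
    ``markets`` columns: market_id, country, lon, lat.
    """

    prices: pd.DataFrame
    markets: pd.DataFrame
    conversion_models: dict[str, "WholesaleRetailRegressor"] = field(default_factory=dict)
    maize_models: dict[str, "MaizeEquivalentRegressor"] = field(default_factory=dict)
    log: dict[str, int] = field(default_factory=dict)

    def series(self, market_id: str, crop: str) -> pd.DataFrame:
        sel = (self.prices["market_id"] == market_id) & (self.prices["crop"] == crop)
        return self.prices.loc[sel].sort_values(["year", "month"])

    def source_counts(self) -> dict[str, int]:
        return self.prices["source_type"].value_counts().to_dict()

    def to_csv(self, path) -> None:
        merged = self.prices.merge(self.markets, on="market_id", how="left")
        merged.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PricePanel":
        df = pd.read_csv(path)
        markets = df[["market_id", "country", "lon", "lat"]].drop_duplicates("market_id")
        prices = df[["market_id", "crop", "year", "month", "value", "source_type"]].copy()
        return cls(prices=prices, markets=markets.reset_index(drop=True))


class WholesaleRetailRegressor(BaseEstimator, RegressorMixin):
    """Linear map from retail to wholesale price for one crop.

    By default the fit is through the origin, so the single coefficient is
    the wholesale/retail price ratio; an intercept can be enabled.  The
    inverse transform (wholesale -> retail equivalent) divides by the slope
    after removing the intercept.

    Parameters
    ----------
    fit_intercept : bool, default False
        Allow a non-zero intercept in wholesale = slope * retail + intercept.

    Attributes
    ----------
    slope_ : float
    intercept_ : float
    n_pairs_ : int
    n_markets_ : int
    rmse_ : float
        Root-mean-square residual of the fit, USD/kg.
    """

    def __init__(self, fit_intercept: bool = False):
        self.fit_intercept = fit_intercept

    def fit(self, X, y, markets=None):
        retail = np.asarray(X, dtype=float).reshape(-1)
        wholesale = np.asarray(y, dtype=float).reshape(-1)
        if retail.size != wholesale.size or retail.size < 2:
            raise ValueError("need at least 2 co-reported retail/wholesale pairs")
        if self.fit_intercept:
            A = np.column_stack([retail, np.ones_like(retail)])
        else:
            A = retail[:, None]
        coef, *_ = np.linalg.lstsq(A, wholesale, rcond=None)
        self.slope_ = float(coef[0])
        self.intercept_ = float(coef[1]) if self.fit_intercept else 0.0
        resid = wholesale - A @ coef
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        self.n_pairs_ = int(retail.size)
        self.n_markets_ = int(len(set(markets))) if markets is not None else self.n_pairs_
        if not 0 < self.slope_ <= 1.2:
            raise ValueError(
                f"implausible wholesale/retail slope {self.slope_:.3f}; expected (0, 1.2]"
            )
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        retail = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * retail + self.intercept_

    def to_retail(self, wholesale):
        """Retail-equivalent price for a wholesale observation."""
        check_is_fitted(self, "slope_")
        w = np.asarray(wholesale, dtype=float)
        return (w - self.intercept_) / self.slope_

    @classmethod
    def from_default(cls, crop: str) -> "WholesaleRetailRegressor":
        est = cls(fit_intercept=False)
        est.slope_ = DEFAULT_WHOLESALE_SLOPES[crop]
        est.intercept_ = 0.0
        est.rmse_ = float("nan")
        est.n_pairs_ = 0
        est.n_markets_ = 0
        return est


class MaizeEquivalentRegressor(BaseEstimator, RegressorMixin):
    """Affine map estimating maize price from another cereal's price.

    Fit by OLS on market-year median prices where maize and the other cereal
    are co-reported.

    Attributes
    ----------
    intercept_, slope_ : float
    rmse_ : float
    n_market_years_ : int
    """

    min_market_years = 10

    def fit(self, X, y):
        other = np.asarray(X, dtype=float).reshape(-1)
        maize = np.asarray(y, dtype=float).reshape(-1)
        if other.size < self.min_market_years:
            raise ValueError(
                f"need >= {self.min_market_years} co-reporting market-years, got {other.size}"
            )
        A = np.column_stack([np.ones_like(other), other])
        coef, *_ = np.linalg.lstsq(A, maize, rcond=None)
        self.intercept_, self.slope_ = float(coef[0]), float(coef[1])
        resid = maize - A @ coef
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        self.n_market_years_ = int(other.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        other = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * other


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"price records missing columns: {sorted(missing)}")
    if records.empty:
        raise ValueError("empty price record input")
    df = records.copy()
    bad = (
        (df["price"] <= 0)
        | ~df["month"].between(1, 12)
        | ~df["lon"].between(-180, 180)
        | ~df["lat"].between(-90, 90)
        | ~df["crop"].isin(CROPS)
        | ~df["price_type"].isin(["retail", "wholesale"])
    )
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("dropping %d invalid price records", n_bad)
    return df.loc[~bad].reset_index(drop=True)


def deflate_prices(
    records: pd.DataFrame, deflators: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Convert local-currency prices to 2010 PPP-adjusted USD/kg.

    value = price / cpi / ppp, matched by (country, year, month).  Monthly
    deflator rows are used when present; a deflator table without a month
    column (annual values) is broadcast across the 12 months.  Records with
    no matching deflator row are skipped with a logged count.

    Returns the deflated frame and the number of skipped records.
    """
    defl = deflators.copy()
    if "month" not in defl.columns or defl["month"].isna().all():
        defl = defl.drop(columns=["month"], errors="ignore")
        defl = defl.merge(pd.DataFrame({"month": range(1, 13)}), how="cross")
    if (defl["cpi"] <= 0).any() or (defl["ppp"] <= 0).any():
        raise ValueError("deflators must be strictly positive")
    dup = defl.duplicated(["country", "year", "month"]).sum()
    if dup:
        raise ValueError(f"{dup} duplicate (country, period) deflator rows")

    merged = records.merge(
        defl[["country", "year", "month", "cpi", "ppp"]],
        on=["country", "year", "month"],
        how="left",
    )
    missing = merged["cpi"].isna()
    n_skipped = int(missing.sum())
    if n_skipped:
        logger.warning("skipped %d records with no deflator row", n_skipped)
    merged = merged.loc[~missing].copy()
    merged["value"] = merged["price"] / (merged["cpi"] * merged["ppp"])
    return merged.drop(columns=["cpi", "ppp"]), n_skipped


def fit_wholesale_retail(
    deflated: pd.DataFrame,
    *,
    fit_intercept: bool = False,
    use_defaults: bool = False,
    min_markets: int = 2,
) -> dict[str, WholesaleRetailRegressor]:
    """Per-crop wholesale/retail conversion models from co-reported pairs.

    Pairs are observations of both price types for the same (market, crop,
    year, month), pooled across countries.  Crops with fewer than
    ``min_markets`` co-reporting markets fall back to the default ratios.
    """
    models: dict[str, WholesaleRetailRegressor] = {}
    for crop in CROPS:
        if use_defaults:
            models[crop] = WholesaleRetailRegressor.from_default(crop)
            continue
        sub = deflated[deflated["crop"] == crop]
        wide = sub.pivot_table(
            index=["market_id", "year", "month"],
            columns="price_type",
            values="value",
            aggfunc="median",
        )
        if not {"retail", "wholesale"} <= set(wide.columns):
            pairs = wide.iloc[0:0]
        else:
            pairs = wide.dropna(subset=["retail", "wholesale"])
        n_markets = pairs.index.get_level_values("market_id").nunique() if len(pairs) else 0
        if n_markets < min_markets:
            logger.warning(
                "crop %s: only %d co-reporting markets; using default slope %.2f",
                crop, n_markets, DEFAULT_WHOLESALE_SLOPES[crop],
            )
            models[crop] = WholesaleRetailRegressor.from_default(crop)
        else:
            models[crop] = WholesaleRetailRegressor(fit_intercept=fit_intercept).fit(
                pairs["retail"], pairs["wholesale"],
                markets=pairs.index.get_level_values("market_id"),
            )
    return models


def wholesale_to_retail(
    deflated: pd.DataFrame, models: dict[str, WholesaleRetailRegressor]
) -> pd.DataFrame:
    """Collapse retail + wholesale rows to one retail-equivalent row per key.

    Reported retail takes precedence; wholesale-only observations are divided
    by the crop's slope and tagged ``converted_from_wholesale``.
    """
    df = deflated.copy()
    key = ["market_id", "crop", "year", "month"]
    # resolve duplicates within a price type first (keep median, log)
    n_dup = int(df.duplicated(key + ["price_type"]).sum())
    if n_dup:
        logger.warning("collapsing %d duplicate observations to their median", n_dup)
        df = df.groupby(key + ["price_type"], as_index=False).agg(
            {**{c: "first" for c in df.columns if c not in key + ["price_type", "value"]},
             "value": "median"}
        )
    retail = df[df["price_type"] == "retail"].copy()
    retail["source_type"] = "reported_retail"
    wholesale = df[df["price_type"] == "wholesale"].copy()
    retail_keys = set(map(tuple, retail[key].itertuples(index=False)))
    keep = [tuple(r) not in retail_keys for r in wholesale[key].itertuples(index=False)]
    wholesale = wholesale.loc[keep].copy()
    converted = []
    for crop, grp in wholesale.groupby("crop"):
        model = models.get(str(crop))
        if model is None:
            logger.warning("no conversion model for crop %s; dropping %d rows", crop, len(grp))
            continue
        g = grp.copy()
        g["value"] = model.to_retail(g["value"].to_numpy())
        g["source_type"] = "converted_from_wholesale"
        converted.append(g)
    out = pd.concat([retail, *converted], ignore_index=True)
    return out.drop(columns=["price_type"])


def fit_maize_equivalent(
    prices: pd.DataFrame,
) -> dict[str, MaizeEquivalentRegressor]:
    """Per-cereal affine maps from market-year median prices to maize.

    Fit on markets where maize and the other cereal are both reported in the
    same year.  Cereals with fewer than 10 co-reporting market-years are
    skipped with a log entry.
    """
    med = prices.groupby(["market_id", "crop", "year"], as_index=False)["value"].median()
    wide = med.pivot_table(index=["market_id", "year"], columns="crop", values="value")
    models: dict[str, MaizeEquivalentRegressor] = {}
    for crop in CROPS:
        if crop == "maize" or crop not in wide.columns or "maize" not in wide.columns:
            continue
        pairs = wide[["maize", crop]].dropna()
        if len(pairs) < MaizeEquivalentRegressor.min_market_years:
            logger.warning(
                "maize-equivalent fit for %s refused: %d co-reporting market-years",
                crop, len(pairs),
            )
            continue
        models[crop] = MaizeEquivalentRegressor().fit(pairs[crop], pairs["maize"])
    return models


def _impute_maize(
    prices: pd.DataFrame, models: dict[str, MaizeEquivalentRegressor]
) -> pd.DataFrame:
    """Add maize_equivalent rows for markets reporting no maize at all."""
    has_maize = set(prices.loc[prices["crop"] == "maize", "market_id"])
    candidates = prices[~prices["market_id"].isin(has_maize) & (prices["crop"] != "maize")]
    if candidates.empty or not models:
        return prices
    # prefer the cereal whose map has the lowest residual error
    ranked = sorted(models, key=lambda c: models[c].rmse_)
    rows = []
    for mkt, grp in candidates.groupby("market_id"):
        crop = next((c for c in ranked if c in set(grp["crop"])), None)
        if crop is None:
            continue
        src = grp[grp["crop"] == crop]
        est = models[crop].predict(src["value"].to_numpy())
        ok = est > 0
        imput = src.loc[ok].copy()
        imput["crop"] = "maize"
        imput["value"] = est[ok]
        imput["source_type"] = "maize_equivalent"
        rows.append(imput)
    if not rows:
        return prices
    return pd.concat([prices, *rows], ignore_index=True)


def build_panel(
    records: pd.DataFrame,
    deflators: pd.DataFrame,
    *,
    impute_maize: bool = False,
    use_default_slopes: bool = False,
    fit_intercept: bool = False,
) -> PricePanel:
    """Full normalization: validate, deflate, convert wholesale, impute maize.

    Steps run in that order; provenance is kept in ``source_type`` and the
    fitted conversion models and skip counts are attached to the panel.
    """
    df = _validate_records(records)
    if df.empty:
        raise ValueError("no valid price records after validation")
    deflated, n_skipped = deflate_prices(df, deflators)
    conv = fit_wholesale_retail(
        deflated, fit_intercept=fit_intercept, use_defaults=use_default_slopes
    )
    prices = wholesale_to_retail(deflated, conv)
    maize_models: dict[str, MaizeEquivalentRegressor] = {}
    if impute_maize:
        maize_models = fit_maize_equivalent(prices)
        prices = _impute_maize(prices, maize_models)
    markets = (
        df[["market_id", "country", "lon", "lat"]]
        .drop_duplicates("market_id")
        .reset_index(drop=True)
    )
    prices = prices[["market_id", "crop", "year", "month", "value", "source_type"]]
    counts = prices["source_type"].value_counts().to_dict()
    logger.info("panel built: %s (skipped %d without deflators)", counts, n_skipped)
    return PricePanel(
        prices=prices.reset_index(drop=True),
        markets=markets,
        conversion_models=conv,
        maize_models=maize_models,
        log={"skipped_no_deflator": n_skipped, **{f"n_{k}": v for k, v in counts.items()}},
    )
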