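"""Between-year price variation as a function of lagged growing-season rain.

For each market and crop, prices are aggregated into harvest years (one
window per harvest, running from a harvest month to the month before the
next harvest, so less than 12 months where there are two seasons).  Each
window gets the median normalized price and the total rainfall of the
growing season that preceded its opening harvest.  The yearly medians are
detrended with the best of an intercept-only, linear, or quadratic
polynomial in year (chosen by AIC under a Gaussian likelihood), and the
residuals are regressed on lagged season rainfall.  The slope, rescaled to
USD/kg per 100 mm, is the market's rainfall price effect; across markets
the effects are summarized by a meta-regression on the natural log of mean
annual rainfall, which captures the tendency of dry-climate markets to show
the strongest price response to rainfall shortfalls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cropcal import GrowingSeasonSet, season_rainfall_total

__all__ = [
    "HarvestYearSummary",
    "RainPriceEffect",
    "PolynomialDetrend",
    "gaussian_aic",
    "summarize_harvest_years",
    "select_detrend",
    "rain_price_slope",
    "effect_vs_aridity",
    "rain_price_effects",
]

logger = logging.getLogger(__name__)

MIN_YEARS = 10


@dataclass(frozen=True)
class HarvestYearSummary:
    market_id: str
    crop: str
    harvest_year: int
    harvest_month: int
    window_len_months: int
    median_price: float
    season_rain: float
    n_obs: int


@dataclass(frozen=True)
class RainPriceEffect:
    """OLS slope of detrended harvest-year price on lagged season rainfall."""

    market_id: str
    crop: str
    slope: float  # USD/kg per 100 mm
    se: float
    n_years: int
    mean_annual_rain: float
    mean_season_rain: float
    detrend_degree: int


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC for a Gaussian regression, up to an additive constant.

    ``k`` counts the regression coefficients; the error-variance parameter
    contributes the same constant to every candidate and is omitted.
    """
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n * float(np.log(rss / n)) + 2 * k


class PolynomialDetrend(BaseEstimator, TransformerMixin):
    """AIC-selected polynomial trend removal for short yearly price series.

    Candidates are polynomials in (centered) year of degree 0, 1 and 2; the
    degree minimizing the Gaussian AIC is kept and ``transform`` returns
    the residuals.  Centering the year index is purely for conditioning and
    does not affect fitted values or residuals.

    Parameters
    ----------
    max_degree : int, default 2
    corrected : bool, default False
        Use the small-sample corrected AICc instead of plain AIC.

    Attributes
    ----------
    degree_ : int
    coefficients_ : ndarray, highest power first (numpy polyfit order)
    aic_values_ : dict of degree -> AIC
    """

    def __init__(self, max_degree: int = 2, corrected: bool = False):
        self.max_degree = max_degree
        self.corrected = corrected

    def fit(self, X, y=None):
        years = np.asarray(X, dtype=float).reshape(-1)
        prices = np.asarray(y, dtype=float).reshape(-1)
        n = years.size
        if n < MIN_YEARS:
            raise ValueError(f"need >= {MIN_YEARS} yearly values, got {n}")
        self.year_center_ = float(years.mean())
        x = years - self.year_center_
        self.aic_values_ = {}
        fits = {}
        for deg in range(self.max_degree + 1):
            coef = np.polyfit(x, prices, deg)
            resid = prices - np.polyval(coef, x)
            rss = float(resid @ resid)
            k = deg + 1
            aic = gaussian_aic(rss, n, k)
            if self.corrected:
                aic += 2 * k * (k + 1) / max(n - k - 1, 1)
            self.aic_values_[deg] = aic
            fits[deg] = coef
        self.degree_ = min(self.aic_values_, key=self.aic_values_.get)
        self.coefficients_ = fits[self.degree_]
        return self

    def transform(self, X, y=None):
        check_is_fitted(self, "degree_")
        years = np.asarray(X, dtype=float).reshape(-1)
        x = years - self.year_center_
        return np.polyval(self.coefficients_, x)

    def residuals(self, X, y):
        """Detrended prices: observed minus the selected trend."""
        return np.asarray(y, dtype=float).reshape(-1) - self.transform(X)


def summarize_harvest_years(
    panel, calendars: dict[str, GrowingSeasonSet], rainfall: pd.DataFrame
) -> list[HarvestYearSummary]:
    """Median price and lagged season rainfall per harvest-to-harvest window.

    ``rainfall`` is a long table (market_id, year, month, prec_mm) of actual
    monthly precipitation.  Arid markets (no harvest month) are excluded;
    windows without any price observation or with incomplete season rainfall
    are dropped.
    """
    out: list[HarvestYearSummary] = []
    prices = panel.prices
    for (mkt, crop), grp in prices.groupby(["market_id", "crop"]):
        cal = calendars.get(str(mkt))
        if cal is None or not cal.harvest_months:
            continue
        rain = rainfall[rainfall["market_id"] == mkt]
        if rain.empty:
            continue
        harvests = sorted(cal.harvest_months)
        seasons_by_harvest = {
            h: months for h, months in zip(
                (r[-1] % 12 + 1 for r in cal.season_months), cal.season_months
            )
        }
        years = range(int(grp["year"].min()), int(grp["year"].max()) + 1)
        obs = grp.set_index(["year", "month"])["value"]
        for year in years:
            for i, h in enumerate(harvests):
                nxt = harvests[(i + 1) % len(harvests)]
                length = (nxt - h) % 12 or 12
                months = [((h - 1 + k) % 12 + 1, year + (h - 1 + k) // 12) for k in range(length)]
                vals = [obs.get((y, m)) for m, y in months]
                vals = [v for v in vals if v is not None and np.isfinite(v)]
                if not vals:
                    continue
                srain = season_rainfall_total(rain, seasons_by_harvest[h], year, h)
                if not np.isfinite(srain):
                    continue
                out.append(HarvestYearSummary(
                    market_id=str(mkt), crop=str(crop), harvest_year=year,
                    harvest_month=h, window_len_months=length,
                    median_price=float(np.median(vals)), season_rain=float(srain),
                    n_obs=len(vals),
                ))
    return out


def select_detrend(years, prices, **kwargs) -> PolynomialDetrend:
    """Fit the AIC-selected polynomial trend for one yearly price series."""
    return PolynomialDetrend(**kwargs).fit(years, prices)


def rain_price_slope(
    detrended: np.ndarray,
    season_rain: np.ndarray,
    *,
    market_id: str = "",
    crop: str = "",
    mean_annual_rain: float = float("nan"),
    detrend_degree: int = -1,
) -> RainPriceEffect:
    """OLS slope of detrended prices on lagged season rain, per 100 mm."""
    y = np.asarray(detrended, dtype=float).reshape(-1)
    x = np.asarray(season_rain, dtype=float).reshape(-1) / 100.0
    if y.size != x.size or y.size < MIN_YEARS:
        raise ValueError(f"need >= {MIN_YEARS} matched years, got {y.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero rainfall variance; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RainPriceEffect(
        market_id=market_id, crop=crop,
        slope=float(res.params[1]), se=float(res.bse[1]),
        n_years=int(y.size), mean_annual_rain=float(mean_annual_rain),
        mean_season_rain=float(np.mean(x) * 100.0),
        detrend_degree=detrend_degree,
    )


def rain_price_effects(
    summaries: list[HarvestYearSummary],
    annual_rain: dict[str, float] | None = None,
    *,
    min_years: int = MIN_YEARS,
    corrected_aic: bool = False,
) -> list[RainPriceEffect]:
    """Detrend-then-regress pipeline over all market-crop series.

    ``annual_rain`` optionally maps market_id to mean annual precipitation
    (mm); when absent, the mean season rainfall stands in.
    """
    df = pd.DataFrame([s.__dict__ for s in summaries])
    effects: list[RainPriceEffect] = []
    if df.empty:
        return effects
    for (mkt, crop), grp in df.groupby(["market_id", "crop"]):
        grp = grp.sort_values(["harvest_year", "harvest_month"])
        if len(grp) < min_years:
            continue
        # fractional year index so two-harvest markets keep distinct points
        t = grp["harvest_year"] + (grp["harvest_month"] - 1) / 12.0
        try:
            trend = PolynomialDetrend(corrected=corrected_aic).fit(t, grp["median_price"])
            resid = trend.residuals(t, grp["median_price"])
            eff = rain_price_slope(
                resid, grp["season_rain"].to_numpy(),
                market_id=str(mkt), crop=str(crop),
                mean_annual_rain=(annual_rain or {}).get(str(mkt), float("nan")),
                detrend_degree=trend.degree_,
            )
        except ValueError as exc:
            logger.info("skipping %s/%s: %s", mkt, crop, exc)
            continue
        if not np.isfinite(eff.mean_annual_rain):
            eff = RainPriceEffect(**{**eff.__dict__, "mean_annual_rain": eff.mean_season_rain})
        effects.append(eff)
    return effects


@dataclass(frozen=True)
class AridityMetaFit:
    """OLS of market rain-price slopes on ln(mean annual rainfall)."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r_squared: float
    n: int
    conf_int: tuple[tuple[float, float], tuple[float, float]]  # 95% for (a, b)

    def predict(self, rain_mm: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.log(np.asarray(rain_mm, dtype=float))

    def band(self, rain_mm: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """95% confidence band of the mean response along the rainfall axis."""
        lx = np.log(np.asarray(rain_mm, dtype=float))
        X = np.column_stack([np.ones_like(lx), lx])
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
        mean = X @ np.array([self.intercept, self.slope])
        return mean - 1.96 * se, mean + 1.96 * se


def effect_vs_aridity(
    effects: list[RainPriceEffect],
    *,
    rainfall_axis: str = "annual",
    cluster: dict[str, str] | None = None,
) -> tuple[AridityMetaFit, np.ndarray]:
    """Meta-regression of rainfall price effects against ln(rainfall).

    Pools all crops; markets with non-positive rainfall are excluded.
    ``rainfall_axis`` selects the x variable: mean annual precipitation
    (default) or the mean growing-season total ("season"); the two nearly
    coincide for single-season locations but diverge where two shorter
    seasons split the annual total.

    ``cluster`` optionally maps market_id to a grouping label (typically
    the country).  Market-level slope estimates are not independent when
    price shocks are shared within a group — national macro events move
    every market in a country — so clustered standard errors (with
    t-distribution critical values) give honest confidence intervals in
    that setting; without ``cluster``, classic OLS errors are used.

    Returns the fit and the parameter covariance (for the CI band).
    """
    if rainfall_axis not in ("annual", "season"):
        raise ValueError("rainfall_axis must be 'annual' or 'season'")
    attr = "mean_annual_rain" if rainfall_axis == "annual" else "mean_season_rain"
    rows = [
        (e.slope, getattr(e, attr), e.market_id)
        for e in effects if getattr(e, attr) > 0
    ]
    if len(rows) < 5:
        raise ValueError(f"need >= 5 markets with positive rainfall, got {len(rows)}")
    slopes = np.array([r[0] for r in rows])
    lrain = np.log([r[1] for r in rows])
    model = sm.OLS(slopes, sm.add_constant(lrain))
    if cluster is not None:
        groups = np.array([cluster[m] for _, _, m in rows])
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups}, use_t=True)
    else:
        res = model.fit()
    ci = np.asarray(res.conf_int(alpha=0.05))
    fit = AridityMetaFit(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        se_intercept=float(res.bse[0]), se_slope=float(res.bse[1]),
        r_squared=float(res.rsquared), n=len(rows),
        conf_int=((float(ci[0][0]), float(ci[0][1])), (float(ci[1][0]), float(ci[1][1]))),
    )
    return fit, np.asarray(res.cov_params())
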