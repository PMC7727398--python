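"""Temporal price indices and the post-harvest / lean-season price cycle.

The temporal price index of a market-crop series is its mean price in each
calendar month divided by the median of all its observations, so 1.0 means
"at the typical price level".  Re-keying the index by months since harvest
aligns markets with different cropping calendars and exposes the common
seasonal shape: prices fall for the first few months after harvest while
markets are saturated, reach a minimum, then climb through the lean season
until the next harvest.  That shape is summarized by two ordinary
least-squares lines (decline, then rise) joined at an integer breakpoint
chosen to minimize the total squared error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cropcal import GrowingSeasonSet, months_since_harvest

__all__ = [
    "TemporalPriceIndex",
    "temporal_index",
    "all_temporal_indices",
    "SeasonalVShape",
    "align_indices",
    "align_and_fit",
    "seasonal_range",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemporalPriceIndex:
    """Relative monthly price level of one market-crop series.

    ``index[m]`` is NaN for calendar months with no observation; undefined
    months are never imputed.
    """

    market_id: str
    crop: str
    index: tuple[float, ...]  # 12 values, January..December
    n_obs: tuple[int, ...]
    median_price: float

    def defined_months(self) -> list[int]:
        return [m for m in range(1, 13) if np.isfinite(self.index[m - 1])]


def temporal_index(panel, market_id: str, crop: str) -> TemporalPriceIndex:
    """index[m] = mean(prices in calendar month m) / median(all prices)."""
    series = panel.series(market_id, crop)
    if series.empty:
        raise ValueError(f"no observations for {market_id}/{crop}")
    med = float(series["value"].median())
    means = series.groupby("month")["value"].mean()
    counts = series.groupby("month")["value"].size()
    idx = tuple(
        float(means[m]) / med if m in means.index else float("nan") for m in range(1, 13)
    )
    n = tuple(int(counts.get(m, 0)) for m in range(1, 13))
    return TemporalPriceIndex(
        market_id=market_id, crop=crop, index=idx, n_obs=n, median_price=med
    )


def all_temporal_indices(panel, *, min_obs: int = 12) -> list[TemporalPriceIndex]:
    """Temporal indices for every market-crop series with enough coverage."""
    out = []
    for (mkt, crop), grp in panel.prices.groupby(["market_id", "crop"]):
        if len(grp) < min_obs:
            continue
        out.append(temporal_index(panel, str(mkt), str(crop)))
    return out


def seasonal_range(index: TemporalPriceIndex) -> float:
    """Max minus min of the defined monthly index values."""
    vals = np.asarray(index.index, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 defined months for a range")
    return float(vals.max() - vals.min())


class SeasonalVShape(BaseEstimator, RegressorMixin):
    """Two-segment linear fit of price index against months since harvest.

    The breakpoint is chosen by exhaustive search: for each candidate, two
    independent OLS lines are fit with the boundary month shared by both
    segments (sharing the trough anchors both lines to it, which is what
    makes the breakpoint identifiable when the underlying V is continuous),
    and the candidate with the smallest total squared error wins.  The
    reported lines are then refit on the disjoint partition (boundary month
    in the decline segment), so the two-segment fit can never have a larger
    SSE than a single line through the same points.  Continuity at the join
    can optionally be enforced (a connected piecewise-linear fit).

    Parameters
    ----------
    breakpoint_candidates : iterable of int, default range(1, 7)
    continuous : bool, default False

    Attributes
    ----------
    breakpoint_ : int
    slope_down_, slope_up_ : float  (index units per month)
    intercept_down_, intercept_up_ : float
    sse_ : float
    min_index_, max_index_ : float   fitted value at the breakpoint / extremes
    degenerate_ : bool               flat input (SSE ties across candidates)
    envelope_ : DataFrame            15th-85th percentile per month bin
    """

    def __init__(self, breakpoint_candidates=tuple(range(1, 7)), continuous: bool = False):
        self.breakpoint_candidates = breakpoint_candidates
        self.continuous = continuous

    @staticmethod
    def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        if x.size == 0:
            return 0.0, float("nan"), 0.0
        if np.ptp(x) == 0:
            m = float(np.mean(y))
            return 0.0, m, float(np.sum((y - m) ** 2))
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        return float(coef[0]), float(coef[1]), float(resid @ resid)

    def _fit_continuous(self, x, y, b):
        # hinge basis: y = a + c1*x + c2*max(x-b, 0), continuous at b
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - b, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sse = float(resid @ resid)
        s_down = float(coef[1])
        s_up = float(coef[1] + coef[2])
        i_down = float(coef[0])
        i_up = float(coef[0] - coef[2] * b)
        return s_down, i_down, s_up, i_up, sse

    def fit(self, X, y):
        msh = np.asarray(X, dtype=float).reshape(-1)
        idx = np.asarray(y, dtype=float).reshape(-1)
        ok = np.isfinite(msh) & np.isfinite(idx)
        msh, idx = msh[ok], idx[ok]
        if np.unique(msh).size < 3:
            raise ValueError("need >= 3 distinct months-since-harvest values")
        sses = {}
        for b in self.breakpoint_candidates:
            if self.continuous:
                sses[b] = self._fit_continuous(msh, idx, float(b))[4]
            else:
                _, _, sse1 = self._ols_line(msh[msh <= b], idx[msh <= b])
                _, _, sse2 = self._ols_line(msh[msh >= b], idx[msh >= b])
                sses[b] = sse1 + sse2
        best = min(sses, key=lambda b: (round(sses[b], 12), b))
        self.degenerate_ = bool(
            np.allclose(list(sses.values()), sses[best], atol=1e-12)
            and len(sses) > 1
        )
        if self.continuous:
            s1, i1, s2, i2, sse = self._fit_continuous(msh, idx, float(best))
        else:
            s1, i1, sse1 = self._ols_line(msh[msh <= best], idx[msh <= best])
            s2, i2, sse2 = self._ols_line(msh[msh > best], idx[msh > best])
            if not np.isfinite(i2):  # no points beyond the breakpoint
                s2, i2, sse2 = self._ols_line(msh[msh >= best], idx[msh >= best])
            sse = sse1 + sse2
        self.breakpoint_ = int(best)
        self.slope_down_, self.intercept_down_ = s1, i1
        self.slope_up_, self.intercept_up_ = s2, i2
        self.sse_ = sse
        self.min_index_ = float(s1 * best + i1)
        xmax = float(msh.max())
        self.max_index_ = float(max(i1, s2 * xmax + i2))
        env = (
            pd.DataFrame({"msh": msh.astype(int), "index": idx})
            .groupby("msh")["index"]
            .quantile([0.15, 0.85])
            .unstack()
        )
        env.columns = ["p15", "p85"]
        self.envelope_ = env.reset_index()
        self.n_points_ = int(msh.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "breakpoint_")
        x = np.asarray(X, dtype=float).reshape(-1)
        down = self.slope_down_ * x + self.intercept_down_
        up = self.slope_up_ * x + self.intercept_up_
        return np.where(x <= self.breakpoint_, down, up)

    def summary(self) -> dict:
        check_is_fitted(self, "breakpoint_")
        return {
            "breakpoint": self.breakpoint_,
            "slope_down": self.slope_down_,
            "slope_up": self.slope_up_,
            "min_index": self.min_index_,
            "max_index": self.max_index_,
            "sse": self.sse_,
            "n_points": self.n_points_,
            "degenerate": self.degenerate_,
        }


def align_indices(
    indices: list[TemporalPriceIndex], calendars: dict[str, GrowingSeasonSet]
) -> pd.DataFrame:
    """Re-key monthly indices to months since harvest, pooled over markets.

    Arid / year-round-wet markets (no harvest month) are excluded.  Returns
    a long frame with columns market_id, crop, month, msh, index.
    """
    rows = []
    for tpi in indices:
        cal = calendars.get(tpi.market_id)
        if cal is None or not cal.harvest_months:
            continue
        for m in tpi.defined_months():
            rows.append({
                "market_id": tpi.market_id,
                "crop": tpi.crop,
                "month": m,
                "msh": months_since_harvest(m, cal),
                "index": tpi.index[m - 1],
            })
    return pd.DataFrame(rows, columns=["market_id", "crop", "month", "msh", "index"])


def align_and_fit(
    indices: list[TemporalPriceIndex],
    calendars: dict[str, GrowingSeasonSet],
    **fit_kwargs,
) -> SeasonalVShape:
    """Pool aligned index points across markets and fit the two-segment line."""
    aligned = align_indices(indices, calendars)
    if aligned.empty:
        raise ValueError("no markets with harvest months to align")
    return SeasonalVShape(**fit_kwargs).fit(aligned["msh"], aligned["index"])
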