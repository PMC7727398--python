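"""Random-forest prediction of price seasonality and maize price surfaces.

Two models, both evaluated against explicit null models with grouped
cross-validation (folds split by market, so no market contributes to both
the training and the test side — the relevant generalization question is to
*unsampled locations*):

* temporal model — the temporal price index as a function of longitude,
  latitude, that month's local (50 km buffer) precipitation, and month.
  The null model assumes no seasonal variation (index identically 1); the
  relative skill TE_R = 1 - RMSE/RMSE_null measures the gain over using a
  single price level year-round.
* spatial model — the market median maize price (including maize
  equivalents) as a function of location, annual precipitation, and travel
  time to towns of three size classes.  The null is the training-fold mean
  price.

Covariates are carried as an xarray Dataset on a regular lon/lat grid;
prediction surfaces mask cells with annual precipitation below 200 mm,
where the harvest rule finds no growing season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelEvaluation",
    "haversine_km",
    "buffered_field_mean",
    "TemporalIndexForest",
    "SpatialPriceForest",
    "temporal_training_table",
    "predict_temporal_surface",
    "predict_spatial_surface",
]

logger = logging.getLogger(__name__)

ARID_MASK_MM = 200.0
EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class ModelEvaluation:
    """Cross-validated skill of a predictive model against its null."""

    pearson_r: float
    rmse: float
    rmse_null: float
    n: int
    folds: int

    @property
    def relative_skill(self) -> float:
        """TE_R = 1 - RMSE/RMSE_null; NaN when the null RMSE is zero."""
        if self.rmse_null == 0:
            return float("nan")
        return 1.0 - self.rmse / self.rmse_null

    @property
    def degenerate(self) -> bool:
        return self.rmse_null == 0

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "rmse_null": self.rmse_null,
            "te_r": self.relative_skill,
            "n": self.n,
            "folds": self.folds,
        }


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def buffered_field_mean(
    field: xr.DataArray, lon: float, lat: float, radius_km: float = 50.0
) -> float:
    """Mean of grid cells whose centers lie within a great-circle buffer.

    Falls back to the nearest cell (logged) when no center falls inside the
    buffer, which happens when the buffer radius is below the grid spacing.
    """
    glon, glat = np.meshgrid(field["lon"].values, field["lat"].values)
    d = haversine_km(glon, glat, lon, lat)
    vals = field.transpose("lat", "lon").values
    inside = d <= radius_km
    if not inside.any():
        logger.info("empty %g km buffer at (%.2f, %.2f); using nearest cell", radius_km, lon, lat)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        return float(vals[i, j])
    return float(np.nanmean(vals[inside]))


def _grouped_cv_eval(
    model_factory, X: np.ndarray, y: np.ndarray, groups: np.ndarray,
    null_predictor, n_folds: int,
) -> ModelEvaluation:
    """Pooled out-of-fold evaluation with folds grouped by market."""
    n_groups = len(set(groups))
    folds = min(n_folds, n_groups)
    cv = GroupKFold(n_splits=folds)
    pred = np.full(y.shape, np.nan)
    pred_null = np.full(y.shape, np.nan)
    for tr, te in cv.split(X, y, groups):
        assert not set(groups[tr]) & set(groups[te]), "market leaked across folds"
        m = model_factory()
        m.fit(X[tr], y[tr])
        pred[te] = m.predict(X[te])
        pred_null[te] = null_predictor(y[tr], X[te])
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    rmse_null = float(np.sqrt(np.mean((y - pred_null) ** 2)))
    if np.std(pred) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(pearsonr(y, pred)[0])
    return ModelEvaluation(pearson_r=r, rmse=rmse, rmse_null=rmse_null,
                           n=int(y.size), folds=folds)


class _ForestBase(BaseEstimator, RegressorMixin):
    """Shared scaffolding: grouped-CV evaluation then a final full fit."""

    feature_names: tuple[str, ...] = ()

    def __init__(self, n_estimators: int = 500, random_state: int = 0, n_folds: int = 10):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.n_folds = n_folds

    def _forest(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            oob_score=True,
            n_jobs=1,
        )

    def _null(self, y_train: np.ndarray, X_test: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if np.std(y) == 0:
            raise ValueError("degenerate response: zero variance")
        if groups is None:
            groups = np.arange(y.size)
        groups = np.asarray(groups)
        self.evaluation_ = _grouped_cv_eval(
            self._forest, X, y, groups, self._null, self.n_folds
        )
        self.model_ = self._forest().fit(X, y)
        self.oob_r2_ = float(self.model_.oob_score_)
        self.feature_importances_ = dict(
            zip(self.feature_names, self.model_.feature_importances_.tolist())
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))


class TemporalIndexForest(_ForestBase):
    """Random forest for the temporal price index across space and months.

    Features: longitude, latitude, local monthly precipitation (50 km buffer
    mean of the monthly climatology), month, and the month's sine/cosine
    encoding (so December and January are adjacent).  Set ``cyclic_month``
    False for a raw-month-only feature set.

    The null model predicts index = 1 everywhere (no seasonal variation);
    ``evaluation_.relative_skill`` is TE_R.
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0,
                 n_folds: int = 10, cyclic_month: bool = True):
        super().__init__(n_estimators, random_state, n_folds)
        self.cyclic_month = cyclic_month

    @property
    def feature_names(self) -> tuple[str, ...]:
        base = ("lon", "lat", "precipitation", "month")
        return base + (("month_sin", "month_cos") if self.cyclic_month else ())

    def _null(self, y_train, X_test):
        return np.ones(len(X_test))

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        cols = [df["lon"], df["lat"], df["precipitation"], df["month"]]
        if self.cyclic_month:
            ang = 2 * np.pi * (df["month"] - 1) / 12.0
            cols += [np.sin(ang), np.cos(ang)]
        return np.column_stack([np.asarray(c, dtype=float) for c in cols])

    def fit_table(self, table: pd.DataFrame) -> "TemporalIndexForest":
        """Fit from a long table (market_id, month, index, lon, lat, precipitation)."""
        if table["market_id"].nunique() < 30:
            raise ValueError("need >= 30 markets for the temporal model")
        X = self.design_matrix(table)
        return self.fit(X, table["index"].to_numpy(), groups=table["market_id"].to_numpy())


class SpatialPriceForest(_ForestBase):
    """Random forest for the market median maize price surface.

    Features: longitude, latitude, annual precipitation, and travel times to
    the nearest town of three population classes.  The null model is the
    training-fold mean price.
    """

    feature_names = ("lon", "lat", "annual_prec", "tt_small", "tt_mid", "tt_large")

    def _null(self, y_train, X_test):
        return np.full(len(X_test), float(np.mean(y_train)))

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        return df.loc[:, list(self.feature_names)].to_numpy(dtype=float)

    def fit_table(self, table: pd.DataFrame) -> "SpatialPriceForest":
        """Fit from a table (market_id, price, lon, lat, annual_prec, tt_*)."""
        if table["market_id"].nunique() < 30:
            raise ValueError("need >= 30 markets for the spatial model")
        X = self.design_matrix(table)
        return self.fit(X, table["price"].to_numpy(), groups=table["market_id"].to_numpy())


def temporal_training_table(
    indices, panel, climatology: xr.DataArray, *, buffer_km: float = 50.0
) -> pd.DataFrame:
    """Assemble the temporal model's training rows from index objects.

    ``climatology`` is a (month, lat, lon) DataArray of mean monthly
    precipitation; the precipitation feature is the 50 km buffered mean of
    the relevant month's layer around each market.
    """
    registry = panel.markets.set_index("market_id")
    buf_cache: dict[tuple[str, int], float] = {}
    rows = []
    for tpi in indices:
        if tpi.market_id not in registry.index:
            continue
        lon = float(registry.loc[tpi.market_id, "lon"])
        lat = float(registry.loc[tpi.market_id, "lat"])
        for m in tpi.defined_months():
            key = (tpi.market_id, m)
            if key not in buf_cache:
                buf_cache[key] = buffered_field_mean(
                    climatology.sel(month=m), lon, lat, buffer_km
                )
            rows.append({
                "market_id": tpi.market_id, "crop": tpi.crop, "month": m,
                "index": tpi.index[m - 1], "lon": lon, "lat": lat,
                "precipitation": buf_cache[key],
            })
    return pd.DataFrame(rows)


def _check_stack(stack: xr.Dataset, needed: tuple[str, ...]) -> None:
    missing = [v for v in needed if v not in stack]
    if missing:
        raise ValueError(f"covariate stack missing layers: {missing}")


def _arid_mask(stack: xr.Dataset) -> xr.DataArray:
    return stack["annual_prec"] >= ARID_MASK_MM


def predict_temporal_surface(
    model: TemporalIndexForest, stack: xr.Dataset, months=range(1, 13)
) -> xr.Dataset:
    """Monthly temporal-index layers plus their per-cell annual range.

    The stack must carry ``annual_prec`` (for the arid mask) and
    ``prec_clim`` with a month dimension (the precipitation feature).
    """
    _check_stack(stack, ("annual_prec", "prec_clim"))
    mask = _arid_mask(stack)
    if not bool(mask.any()):
        logger.warning("all cells are arid; returning an empty surface")
    glon, glat = np.meshgrid(stack["lon"].values, stack["lat"].values)
    flat_mask = mask.transpose("lat", "lon").values.ravel()
    layers = []
    for m in months:
        prec = stack["prec_clim"].sel(month=m).transpose("lat", "lon").values.ravel()
        df = pd.DataFrame({
            "lon": glon.ravel(), "lat": glat.ravel(),
            "precipitation": prec, "month": m,
        })
        pred = np.full(len(df), np.nan)
        if flat_mask.any():
            pred[flat_mask] = model.predict(model.design_matrix(df.loc[flat_mask]))
        layers.append(pred.reshape(glon.shape))
    cube = np.stack(layers)
    mask2d = flat_mask.reshape(glon.shape)
    rng_layer = np.full(glon.shape, np.nan)
    if mask2d.any() and len(layers) > 1:
        rng_layer[mask2d] = cube[:, mask2d].max(axis=0) - cube[:, mask2d].min(axis=0)
    elif mask2d.any():
        rng_layer[mask2d] = 0.0
    ds = xr.Dataset(
        {
            "index": (("month", "lat", "lon"), cube),
            "index_range": (("lat", "lon"), rng_layer),
        },
        coords={"month": list(months), "lat": stack["lat"].values, "lon": stack["lon"].values},
    )
    ds.attrs.update(stack.attrs)
    return ds


def predict_spatial_surface(model: SpatialPriceForest, stack: xr.Dataset) -> xr.Dataset:
    """Predicted maize price (USD/kg) per unmasked grid cell."""
    _check_stack(stack, ("annual_prec", "tt_small", "tt_mid", "tt_large"))
    mask = _arid_mask(stack)
    glon, glat = np.meshgrid(stack["lon"].values, stack["lat"].values)
    df = pd.DataFrame({
        "lon": glon.ravel(), "lat": glat.ravel(),
        "annual_prec": stack["annual_prec"].transpose("lat", "lon").values.ravel(),
        "tt_small": stack["tt_small"].transpose("lat", "lon").values.ravel(),
        "tt_mid": stack["tt_mid"].transpose("lat", "lon").values.ravel(),
        "tt_large": stack["tt_large"].transpose("lat", "lon").values.ravel(),
    })
    flat_mask = mask.transpose("lat", "lon").values.ravel()
    pred = np.full(len(df), np.nan)
    if flat_mask.any():
        pred[flat_mask] = model.predict(model.design_matrix(df.loc[flat_mask]))
    else:
        logger.warning("all cells are arid; returning an empty surface")
    return xr.Dataset(
        {"price": (("lat", "lon"), pred.reshape(glon.shape))},
        coords={"lat": stack["lat"].values, "lon": stack["lon"].values},
        attrs=dict(stack.attrs),
    )
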