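"""Growing-season and harvest-month detection from monthly precipitation.

Harvest timing is inferred from a fixed (climatological) cropping calendar:
a location's growing season is a maximal run of consecutive calendar months
whose mean precipitation meets a location-specific wetness threshold, and
harvesting starts in the month immediately after the run ends.  The threshold
is the median of the 12 climatological monthly totals, clamped to 30--90 mm.
Locations with less than 200 mm of annual precipitation, or with no wet run
at all, are flagged arid and carry no harvest month.

Months are 1-based calendar months throughout; runs are circular, so a wet
season spanning the December--January boundary is a single season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyClimatology",
    "GrowingSeasonSet",
    "wet_threshold",
    "detect_seasons",
    "months_since_harvest",
    "season_rainfall_total",
    "climatology_from_series",
    "calendars_from_series",
]

logger = logging.getLogger(__name__)

THRESHOLD_MIN_MM = 30.0
THRESHOLD_MAX_MM = 90.0
ARID_CUTOFF_MM = 200.0


@dataclass(frozen=True)
class MonthlyClimatology:
    """Mean precipitation per calendar month (mm) at one location."""

    p: tuple[float, ...]  # 12 values, January..December
    lon: float | None = None
    lat: float | None = None

    def __post_init__(self) -> None:
        if len(self.p) != 12:
            raise ValueError(f"expected 12 monthly values, got {len(self.p)}")
        arr = np.asarray(self.p, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("monthly precipitation must be finite and non-negative")

    @property
    def annual_total(self) -> float:
        return float(np.sum(self.p))


@dataclass(frozen=True)
class GrowingSeasonSet:
    """Detected wet-season runs and the harvest months that follow them.

    ``seasons`` holds (start_month, end_month) pairs on the circular calendar;
    a season's harvest month is the month after ``end_month`` (mod 12).
    ``is_arid`` marks locations where the rule found no growing season (or
    annual rainfall below the arid cutoff); ``year_round`` marks the
    degenerate case where every month is wet, which likewise yields no
    distinct harvest month.
    """

    threshold: float
    seasons: tuple[tuple[int, int], ...]
    harvest_months: tuple[int, ...]
    is_arid: bool
    year_round: bool = False
    annual_total: float = float("nan")
    season_months: tuple[tuple[int, ...], ...] = field(default=())

    @property
    def n_seasons(self) -> int:
        return len(self.seasons)


def wet_threshold(clim: MonthlyClimatology) -> float:
    """Location-specific wet-month threshold: clamped median monthly rainfall.

    The median of the 12 climatological monthly values, bounded to the
    interval [30, 90] mm.
    """
    med = float(np.median(clim.p))
    return float(np.clip(med, THRESHOLD_MIN_MM, THRESHOLD_MAX_MM))


def _circular_runs(wet: np.ndarray) -> list[list[int]]:
    """Maximal runs of True in a circular 12-vector; months returned 1-based."""
    n = len(wet)
    if wet.all():
        return [list(range(1, n + 1))]
    if not wet.any():
        return []
    # rotate so position 0 is dry, then scan linearly
    start = int(np.argmin(wet))  # first False
    runs: list[list[int]] = []
    current: list[int] = []
    for k in range(n):
        m = (start + k) % n
        if wet[m]:
            current.append(m + 1)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def detect_seasons(
    clim: MonthlyClimatology,
    *,
    min_run_length: int = 1,
    arid_cutoff: float = ARID_CUTOFF_MM,
    max_seasons: int = 2,
) -> GrowingSeasonSet:
    """Detect growing seasons as circular wet-month runs.

    A month is wet when its climatological precipitation reaches the clamped
    median threshold.  Runs shorter than ``min_run_length`` are discarded; if
    more than ``max_seasons`` runs remain, the wettest (largest run total)
    are kept.  Harvest is the month after each run.  Locations with annual
    rainfall below ``arid_cutoff`` or without any qualifying run are arid.
    """
    thr = wet_threshold(clim)
    p = np.asarray(clim.p, dtype=float)
    annual = float(p.sum())
    wet = p >= thr
    runs = [r for r in _circular_runs(wet) if len(r) >= min_run_length]

    if annual < arid_cutoff or not runs:
        return GrowingSeasonSet(
            threshold=thr, seasons=(), harvest_months=(), is_arid=True,
            annual_total=annual,
        )

    if len(runs) == 1 and len(runs[0]) == 12:
        # every month wet: no post-run month exists, so no harvest is defined
        return GrowingSeasonSet(
            threshold=thr,
            seasons=((runs[0][0], runs[0][-1]),),
            harvest_months=(),
            is_arid=False,
            year_round=True,
            annual_total=annual,
            season_months=(tuple(runs[0]),),
        )

    if len(runs) > max_seasons:
        totals = [p[[m - 1 for m in r]].sum() for r in runs]
        # ties between equally wet runs break toward the earlier start month
        order = sorted(range(len(runs)), key=lambda i: (-totals[i], runs[i][0]))[:max_seasons]
        kept = [runs[i] for i in sorted(order)]
        logger.info(
            "kept %d wettest of %d detected runs (totals %s)",
            max_seasons, len(runs), [round(t, 1) for t in totals],
        )
        runs = kept

    seasons = tuple((r[0], r[-1]) for r in runs)
    harvests = tuple(r[-1] % 12 + 1 for r in runs)
    return GrowingSeasonSet(
        threshold=thr,
        seasons=seasons,
        harvest_months=harvests,
        is_arid=False,
        annual_total=annual,
        season_months=tuple(tuple(r) for r in runs),
    )


def months_since_harvest(month: int, seasons: GrowingSeasonSet) -> int:
    """Circular months elapsed since the most recent harvest month.

    With two harvests per year the attainable maximum is below 11 because the
    clock resets at each harvest.
    """
    if not seasons.harvest_months:
        raise ValueError("location has no harvest month (arid or year-round wet)")
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return min((month - h) % 12 for h in seasons.harvest_months)


def season_rainfall_total(
    monthly_series: pd.DataFrame,
    season_months: tuple[int, ...],
    harvest_year: int,
    harvest_month: int,
) -> float:
    """Total observed rainfall over the growing season preceding a harvest.

    ``monthly_series`` has columns year, month, prec_mm with one row per
    observed month.  The season months are the run ending the month before
    ``harvest_month``; months later in the calendar than the harvest month
    belong to the previous calendar year (a wet run crossing the December
    boundary).  Returns NaN when any season month is missing, so incomplete
    totals can be excluded.
    """
    lut = {
        (int(y), int(m)): float(v)
        for y, m, v in monthly_series[["year", "month", "prec_mm"]].itertuples(index=False)
    }
    total = 0.0
    for m in season_months:
        y = harvest_year if m < harvest_month else harvest_year - 1
        v = lut.get((y, m))
        if v is None or not np.isfinite(v):
            return float("nan")
        total += v
    return total


def climatology_from_series(
    series: pd.DataFrame, *, lon: float | None = None, lat: float | None = None
) -> MonthlyClimatology:
    """Average a (year, month, prec_mm) series into a 12-month climatology."""
    means = series.groupby("month")["prec_mm"].mean()
    if not set(range(1, 13)) <= set(means.index):
        missing = sorted(set(range(1, 13)) - set(means.index))
        raise ValueError(f"climatology is missing months {missing}")
    return MonthlyClimatology(tuple(float(means[m]) for m in range(1, 13)), lon=lon, lat=lat)


def calendars_from_series(
    series: pd.DataFrame, **kwargs
) -> dict[str, GrowingSeasonSet]:
    """Per-market calendars from a long table (market_id, year, month, prec_mm)."""
    out: dict[str, GrowingSeasonSet] = {}
    for mkt, grp in series.groupby("market_id"):
        out[str(mkt)] = detect_seasons(climatology_from_series(grp), **kwargs)
    return out
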