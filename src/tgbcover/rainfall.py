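"""Per-cell rainfall metrics from daily precipitation.

From a multi-year daily rainfall series this module derives, for one grid
cell:

* ``MAR`` — mean annual rainfall (mm/y);
* ``SI`` — the Walsh–Lawler seasonality index, the annual-rainfall-normalised
  sum of absolute deviations of the monthly climatology from its mean,
  ranging from 0 (uniform) to 22/12 ≈ 1.83 (all rain in one month);
* the wet season — the set of months whose climatological rainfall exceeds a
  fraction ``p_thr`` (default 50%) of the mean monthly rainfall — and its
  length ``L_w`` in days;
* ``L_w_SI`` — an alternative wet-season length mapped linearly from SI;
* ``alpha_w`` — mean depth on wet days (depth > 0.1 mm/d) inside the wet
  season, i.e. wet-season daily rainfall intensity (mm/d);
* ``lambda_w`` — average number of wet days per year divided by ``L_w``,
  i.e. wet-season daily rainfall frequency (1/d);
* ``MAR_w`` — mean annual rainfall inside the wet season, and the closing
  term ``c`` of the water balance ``MAR_w = alpha_w * lambda_w * L_w + c``;
  ``c`` collects sub-threshold wet-season rain, so the identity holds by
  construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._calendar import DAYS_PER_YEAR, MONTH_STARTS, day_mask, days_in_months

__all__ = [
    "SI_MAX",
    "DailyRainfallSeries",
    "MonthlyClimatology",
    "RainfallMetrics",
    "PthrCalibration",
    "monthly_climatology",
    "mean_annual_rainfall",
    "seasonality_index",
    "wet_season",
    "season_length_from_si",
    "wet_day_stats",
    "WetDayStats",
    "compute_metrics",
    "calibrate_pthr",
]

#: Upper bound of the Walsh–Lawler seasonality index (all rain in one month).
SI_MAX = 22.0 / 12.0

#: Default wet-month threshold: a month is wet when its climatological
#: rainfall exceeds this fraction of the mean monthly rainfall.
DEFAULT_P_THR = 0.5

#: Depths above this (mm/d) count as wet days; smaller depths are treated as
#: measurement noise.
DEFAULT_WET_DAY_THRESHOLD = 0.1


class SeasonalityUndefinedError(ValueError):
    """Raised when SI is requested for a climatology with zero annual rain."""


@dataclass(frozen=True)
class DailyRainfallSeries:
    """Daily rainfall depths for one cell, shape ``(n_years, 365)``, mm/d."""

    depths: np.ndarray

    def __post_init__(self):
        depths = np.asarray(self.depths, dtype=float)
        if depths.ndim != 2 or depths.shape[1] != DAYS_PER_YEAR:
            raise ValueError(
                f"depths must have shape (n_years, {DAYS_PER_YEAR}), got {depths.shape}"
            )
        if depths.shape[0] < 1:
            raise ValueError("at least one complete year is required")
        if not np.all(np.isfinite(depths)) or np.any(depths < 0):
            raise ValueError("depths must be finite and non-negative")
        object.__setattr__(self, "depths", depths)

    @property
    def n_years(self) -> int:
        return self.depths.shape[0]


@dataclass(frozen=True)
class MonthlyClimatology:
    """Mean rainfall per calendar month (mm/month), averaged over years."""

    mean_monthly: np.ndarray

    def __post_init__(self):
        mm = np.asarray(self.mean_monthly, dtype=float)
        if mm.shape != (12,):
            raise ValueError("mean_monthly must have 12 entries")
        if np.any(mm < 0):
            raise ValueError("monthly rainfall must be non-negative")
        object.__setattr__(self, "mean_monthly", mm)

    @property
    def annual_mean(self) -> float:
        """Climatological annual rainfall, mm/y (sum of the monthly means)."""
        return float(self.mean_monthly.sum())


@dataclass(frozen=True)
class WetDayStats:
    alpha_w: float  # mean wet-day depth, mm/d (nan when no wet day exists)
    lambda_w: float  # mean wet-day count per year / L_w, 1/d
    c: float  # closing term of the water balance, mm/y
    mar_w: float  # mean annual wet-season rainfall, mm/y
    n_wet_days_per_year: float


@dataclass(frozen=True)
class RainfallMetrics:
    """All per-cell rainfall metrics."""

    mar: float
    mar_w: float
    si: float
    wet_months: frozenset[int]
    l_w: int
    l_w_si: float
    alpha_w: float
    lambda_w: float
    c: float


def monthly_climatology(series: DailyRainfallSeries) -> MonthlyClimatology:
    """Average, over years, of the total rainfall in each calendar month."""
    monthly = np.add.reduceat(series.depths, MONTH_STARTS[:-1], axis=1)
    return MonthlyClimatology(monthly.mean(axis=0))


def mean_annual_rainfall(series: DailyRainfallSeries) -> float:
    """Mean over years of the annual rainfall total (mm/y)."""
    return float(series.depths.sum(axis=1).mean())


def seasonality_index(clim: MonthlyClimatology) -> float:
    """Walsh–Lawler seasonality index of a monthly climatology.

    ``SI = (1/R) * sum_m |x_m - R/12|`` with ``R`` the annual total and
    ``x_m`` the monthly means. 0 for uniform rain, 22/12 for single-month
    rain.
    """
    annual = clim.annual_mean
    if annual <= 0:
        raise SeasonalityUndefinedError("SI undefined for zero annual rainfall")
    return float(np.abs(clim.mean_monthly - annual / 12.0).sum() / annual)


def wet_season(
    clim: MonthlyClimatology, p_thr: float = DEFAULT_P_THR
) -> tuple[frozenset[int], int]:
    """Wet months and wet-season length ``L_w`` (days).

    A month is wet when its climatological rainfall strictly exceeds
    ``p_thr`` times the mean monthly rainfall ``annual/12``. Ties count as
    dry. The wet months need not be contiguous. An all-zero climatology
    yields an empty season with ``L_w = 0``.
    """
    if not 0.0 < p_thr < 1.0:
        raise ValueError(f"p_thr must be in (0, 1), got {p_thr}")
    annual = clim.annual_mean
    if annual == 0.0:
        return frozenset(), 0
    wet = clim.mean_monthly > p_thr * annual / 12.0
    months = frozenset(int(m) for m in np.nonzero(wet)[0] + 1)
    return months, days_in_months(months)


def season_length_from_si(si: float) -> float:
    """Wet-season length mapped linearly from SI:
    ``L_w_SI = 365/12 * (11*(1 - SI/1.83) + 1)``.

    365 d at SI = 0, about 30.4 d at the single-month maximum; strictly
    decreasing in SI.
    """
    if not -1e-12 <= si <= SI_MAX + 1e-12:
        raise ValueError(f"SI must lie in [0, {SI_MAX:.4f}], got {si}")
    return 365.0 / 12.0 * (11.0 * (1.0 - si / 1.83) + 1.0)


def wet_day_stats(
    series: DailyRainfallSeries,
    wet_months: Iterable[int],
    wet_day_threshold: float = DEFAULT_WET_DAY_THRESHOLD,
) -> WetDayStats:
    """Intensity ``alpha_w``, frequency ``lambda_w`` and closing term ``c``.

    Wet days are wet-season days with depth strictly above
    ``wet_day_threshold``. ``alpha_w`` is the mean depth pooled over all wet
    days of all years (nan, flagged, when no wet day exists); ``lambda_w``
    is the mean annual wet-day count divided by the climatological
    wet-season length. The pooled mean makes the water balance
    ``MAR_w = alpha_w*lambda_w*L_w + c`` exact, with ``c`` the mean annual
    sub-threshold wet-season rainfall.
    """
    if wet_day_threshold <= 0:
        raise ValueError("wet_day_threshold must be positive")
    wet_months = frozenset(wet_months)
    if not wet_months:
        raise ValueError("wet_months must be non-empty")
    l_w = days_in_months(wet_months)
    in_season = series.depths[:, day_mask(wet_months)]
    mar_w = float(in_season.sum(axis=1).mean())
    wet = in_season > wet_day_threshold
    n_wet = float(wet.sum()) / series.n_years
    if n_wet == 0:
        return WetDayStats(np.nan, 0.0, mar_w, mar_w, 0.0)
    alpha = float(in_season[wet].mean())
    lam = n_wet / l_w
    c = mar_w - alpha * lam * l_w
    return WetDayStats(alpha, lam, c, mar_w, n_wet)


def compute_metrics(
    series: DailyRainfallSeries,
    p_thr: float = DEFAULT_P_THR,
    wet_day_threshold: float = DEFAULT_WET_DAY_THRESHOLD,
) -> RainfallMetrics:
    """All rainfall metrics of one cell; raises for an all-zero series."""
    clim = monthly_climatology(series)
    mar = mean_annual_rainfall(series)
    si = seasonality_index(clim)  # raises if annual rain is zero
    wet_months, l_w = wet_season(clim, p_thr)
    l_w_si = season_length_from_si(si)
    if not wet_months:
        # annual > 0 guarantees at least one month above any p_thr < 1
        raise RuntimeError("empty wet season with positive rainfall")
    stats = wet_day_stats(series, wet_months, wet_day_threshold)
    return RainfallMetrics(
        mar=mar,
        mar_w=stats.mar_w,
        si=si,
        wet_months=wet_months,
        l_w=l_w,
        l_w_si=l_w_si,
        alpha_w=stats.alpha_w,
        lambda_w=stats.lambda_w,
        c=stats.c,
    )


@dataclass(frozen=True)
class PthrCalibration:
    """Result of the wet-month threshold calibration."""

    chosen: float
    thresholds: tuple[float, ...]
    r_squared: tuple[float, ...]  # squared Pearson corr of L_w with L_w_SI

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.thresholds, self.r_squared))


def calibrate_pthr(
    cells: Sequence[DailyRainfallSeries],
    candidates: Sequence[float],
) -> PthrCalibration:
    """Choose the wet-month threshold maximising agreement of the two
    wet-season length measures.

    For each candidate threshold, computes the squared Pearson correlation
    across cells between ``L_w`` (threshold rule) and ``L_w_SI`` (mapped
    from SI), and returns the candidate with the largest correlation plus
    the full curve. Ties go to the first of the tied candidates in the
    given order.
    """
    candidates = tuple(float(p) for p in candidates)
    if len(candidates) < 1:
        raise ValueError("at least one candidate threshold is required")
    if len(cells) < 3 and len(candidates) > 1:
        raise ValueError("at least 3 cells are required to calibrate")
    clims = [monthly_climatology(s) for s in cells]
    l_w_si = np.array([season_length_from_si(seasonality_index(c)) for c in clims])
    curve = []
    for p in candidates:
        l_w = np.array([wet_season(c, p)[1] for c in clims], dtype=float)
        if len(cells) < 2 or np.std(l_w) == 0 or np.std(l_w_si) == 0:
            curve.append(np.nan)
        else:
            r = np.corrcoef(l_w, l_w_si)[0, 1]
            curve.append(float(r * r))
    curve = np.array(curve)
    if np.all(np.isnan(curve)):
        if len(candidates) == 1:
            return PthrCalibration(candidates[0], candidates, (np.nan,))
        raise ValueError(
            "degenerate calibration: wet-season length has no variance across cells"
        )
    best = int(np.nanargmax(curve))
    return PthrCalibration(candidates[best], candidates, tuple(curve))
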