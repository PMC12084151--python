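"""MDA8 ozone metrics and paired-scenario (Base vs UG) analysis.

The exposure metric throughout is MDA8 O3: the daily maximum of all valid
8-hour running means of hourly ozone. The window convention is the common
regulatory one: 24 candidate windows per day, starting 00:00-23:00 local
time and assigned to their start day; windows crossing midnight draw hours
from the next day; a window needs >= 6 of its 8 hours valid, and a day
needs >= 18 valid windows, otherwise the day is NaN.

Scenario pairs hold hourly ozone from two runs that differ only in whether
urban-vegetation BVOC emissions are included ("Base" excludes them, "UG"
includes them); their MDA8 difference isolates the urban-greening effect.
The first ``spinup_days`` days of a pair are model spin-up and are dropped
before any statistic is computed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .grid import Grid

WINDOW = 8
MIN_VALID_HOURS_PER_WINDOW = 6
MIN_VALID_WINDOWS_PER_DAY = 18


@dataclass
class ScenarioPair:
    """Aligned hourly O3 fields (ppb) for the Base and UG scenarios."""

    grid: Grid
    base: np.ndarray          # (n_hours, ny, nx), ppb
    ug: np.ndarray            # same shape/axes
    spinup_days: int = 4
    labels: tuple[str, str] = ("Base", "UG")

    def __post_init__(self) -> None:
        if self.base.shape != self.ug.shape:
            raise ValueError("Base and UG fields must share shape and axes")
        if self.base.shape[0] % 24:
            raise ValueError("hourly series length must be a multiple of 24")
        if np.nanmin(self.base) < 0 or np.nanmin(self.ug) < 0:
            raise ValueError("ozone concentrations must be nonnegative")

    @property
    def n_days(self) -> int:
        return self.base.shape[0] // 24

    def swapped(self) -> "ScenarioPair":
        return ScenarioPair(self.grid, self.ug, self.base, self.spinup_days,
                            (self.labels[1], self.labels[0]))


@dataclass
class ExposureSurface:
    """Per-day and seasonal MDA8 statistics for a scenario pair."""

    grid: Grid
    mda8_base: np.ndarray       # (n_days, ny, nx)
    mda8_ug: np.ndarray
    delta_daily: np.ndarray     # UG - Base, per day
    seasonal_base: np.ndarray = field(init=False)   # (ny, nx)
    seasonal_ug: np.ndarray = field(init=False)
    delta_seasonal: np.ndarray = field(init=False)
    relative_pct: np.ndarray = field(init=False)    # 100 * delta / base

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore", divide="ignore"):
            self.seasonal_base = np.nanmean(self.mda8_base, axis=0)
            self.seasonal_ug = np.nanmean(self.mda8_ug, axis=0)
            self.delta_seasonal = self.seasonal_ug - self.seasonal_base
            rel = 100.0 * self.delta_seasonal / self.seasonal_base
        rel[self.seasonal_base == 0] = np.nan   # flagged, excluded from stats
        self.relative_pct = rel


def mda8(hourly: np.ndarray) -> np.ndarray:
    """Daily maximum 8-h running mean of an hourly series.

    Parameters
    ----------
    hourly
        ``(n_hours, ...)`` array, ``n_hours`` a multiple of 24. NaNs mark
        missing hours.

    Returns
    -------
    ``(n_days, ...)`` array of MDA8 values; NaN where a day has fewer than
    the minimum number of valid windows.
    """
    hourly = np.asarray(hourly, dtype=float)
    n_hours = hourly.shape[0]
    if n_hours % 24:
        raise ValueError("series length must be a multiple of 24 hours")
    n_days = n_hours // 24

    # pad so the 23:00 window of the last day has a full 8-hour view
    pad = np.full((WINDOW - 1,) + hourly.shape[1:], np.nan)
    padded = np.concatenate([hourly, pad], axis=0)
    win = sliding_window_view(padded, WINDOW, axis=0)     # (n_hours, ..., 8)
    n_valid = np.sum(~np.isnan(win), axis=-1)
    means = np.full(n_valid.shape, np.nan)
    ok = n_valid >= MIN_VALID_HOURS_PER_WINDOW
    np.divide(np.nansum(win, axis=-1), n_valid, out=means, where=ok)
    means[~ok] = np.nan

    daily = means.reshape((n_days, 24) + hourly.shape[1:])
    valid_windows = np.sum(~np.isnan(daily), axis=1)
    out = np.full(valid_windows.shape, np.nan)
    day_ok = valid_windows >= MIN_VALID_WINDOWS_PER_DAY
    if day_ok.any():
        filled = np.where(np.isnan(daily), -np.inf, daily)
        out[day_ok] = filled.max(axis=1)[day_ok]
    return out


def delta_mda8(pair: ScenarioPair) -> ExposureSurface:
    """Per-cell daily and seasonal-mean MDA8 difference UG - Base.

    Spin-up days are dropped before computing MDA8, so a window starting on
    the last spin-up day never leaks into the retained record.
    """
    start = pair.spinup_days * 24
    if start >= pair.base.shape[0]:
        raise ValueError("spin-up exhausts the whole record")
    m_base = mda8(pair.base[start:])
    m_ug = mda8(pair.ug[start:])
    return ExposureSurface(pair.grid, m_base, m_ug, m_ug - m_base)


def _boxplot_stats(values: np.ndarray) -> dict[str, float]:
    v = values[~np.isnan(values)]
    if v.size == 0:
        raise ValueError("empty stratum")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return {"min": float(v.min()), "p25": float(q25), "p50": float(q50),
            "p75": float(q75), "max": float(v.max()),
            "mean": float(v.mean()), "n": int(v.size)}


def stratify(surface_2d: np.ndarray, urban_mask: np.ndarray) -> pd.DataFrame:
    """Urban vs suburban/rural summary of a per-cell field.

    Returns a two-row frame (index ``urban``/``suburban``) with boxplot
    statistics (min, p25, p50, p75, max) and the mean. Raises if either
    stratum is empty.
    """
    urban_mask = np.asarray(urban_mask, dtype=bool)
    if urban_mask.shape != surface_2d.shape:
        raise ValueError("mask and field must share the grid")
    if not urban_mask.any():
        raise ValueError("empty stratum: no urban cells")
    if urban_mask.all():
        raise ValueError("empty stratum: no suburban cells")
    rows = {"urban": _boxplot_stats(surface_2d[urban_mask]),
            "suburban": _boxplot_stats(surface_2d[~urban_mask])}
    return pd.DataFrame(rows).T


def temperature_relationship(delta_daily: np.ndarray,
                             t_daily_mean: np.ndarray,
                             urban_mask: np.ndarray | None = None,
                             bins: np.ndarray | int = 6,
                             per_cell: bool = False) -> dict:
    """Relate daily MDA8 enhancement to daily-mean 2 m temperature.

    By default the correlation uses one value per day: the urban-mean (or
    domain-mean if no mask) enhancement against the domain daily-mean
    temperature. ``per_cell=True`` instead pools every (day, cell) sample.

    Returns Pearson r with a two-sided p-value plus per-temperature-bin
    boxplot statistics of the enhancement.
    """
    delta_daily = np.asarray(delta_daily, dtype=float)
    if t_daily_mean.ndim == 3:
        t_series = t_daily_mean.mean(axis=(1, 2))
    else:
        t_series = np.asarray(t_daily_mean, dtype=float)
    if t_series.shape[0] != delta_daily.shape[0]:
        raise ValueError("temperature and exposure day axes differ")

    if urban_mask is not None:
        sel = delta_daily[:, np.asarray(urban_mask, dtype=bool)]
    else:
        sel = delta_daily.reshape(delta_daily.shape[0], -1)
    daily_mean_delta = np.nanmean(sel, axis=1)

    if per_cell:
        x = np.repeat(t_series, sel.shape[1])
        y = sel.ravel()
    else:
        x, y = t_series, daily_mean_delta
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 days for a correlation")
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        r, p = np.nan, np.nan          # correlation undefined for constants
    else:
        r, p = stats.pearsonr(x[ok], y[ok])

    edges = np.histogram_bin_edges(t_series, bins=bins)
    binned = []
    idx = np.clip(np.digitize(t_series, edges[1:-1]), 0, len(edges) - 2)
    for b in range(len(edges) - 1):
        days = idx == b
        if not days.any():
            continue
        row = _boxplot_stats(sel[days].ravel())
        row.update(t_low=float(edges[b]), t_high=float(edges[b + 1]),
                   n_days=int(days.sum()))
        binned.append(row)
    return {"r": float(r), "p_value": float(p),
            "daily_mean_delta": daily_mean_delta, "t_daily": t_series,
            "bins": pd.DataFrame(binned)}


def population_weighted_mean(surface_2d: np.ndarray,
                             population: np.ndarray) -> float:
    """Population-weighted mean of a per-cell field, Σ(P·x)/Σ(P)."""
    p = np.asarray(population, dtype=float)
    if p.shape != surface_2d.shape:
        raise ValueError("population must be regridded to the analysis grid")
    if np.nanmin(p) < 0:
        raise ValueError("population must be nonnegative")
    total = np.nansum(p)
    if total <= 0:
        raise ValueError("total population is zero")
    return float(np.nansum(p * surface_2d) / total)
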