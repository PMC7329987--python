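"""Thaw-degree-day (TDD) metrics from hourly soil-temperature series.

TDD is the sum of daily mean soil temperatures strictly above 0 degC over the
logged window; it measures the magnitude of warming a plot's rooting zone
experienced.  Cumulative TDD up to a phenophase date links thermal forcing to
phenological timing: the cutoff is the floor of the (possibly fractional)
community-weighted date and the cutoff day itself is included.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .datasets import Bundle, PHENOPHASES


def daily_means(series: pd.DataFrame) -> pd.Series:
    """Daily mean temperature per Julian day from hourly readings.

    Parameters
    ----------
    series : DataFrame
        Hourly readings for a single plot, columns julian_day and temp_c.
        Partial first/last days are averaged over the readings available.
    """
    if series.empty:
        raise ValueError("empty temperature series")
    return series.groupby("julian_day")["temp_c"].mean().sort_index()


def thaw_degree_days(daily: pd.Series) -> float:
    """Sum of daily means strictly greater than 0 degC (degC-day)."""
    values = np.asarray(daily, dtype=float)
    return float(values[values > 0].sum())


def cumulative_tdd(daily: pd.Series, cwm_date: float) -> float:
    """Cumulative sum of positive daily means up to floor(cwm_date), inclusive.

    A cutoff before the first logged day yields 0 with a warning: no thermal
    forcing was recorded before the event.
    """
    cutoff = math.floor(cwm_date)
    days = np.asarray(daily.index, dtype=int)
    if cutoff < days.min():
        warnings.warn(
            f"cumulative TDD cutoff {cutoff} precedes first logged day {days.min()}; returning 0",
            stacklevel=2,
        )
        return 0.0
    values = np.asarray(daily, dtype=float)
    sel = values[days <= cutoff]
    return float(sel[sel > 0].sum())


def thermal_summary(bundle: Bundle, cwm_dates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-plot TDD, optionally with one cumulative-TDD column per phenophase.

    Parameters
    ----------
    bundle : Bundle
        Validated survey bundle (after flooded-plot filtering).
    cwm_dates : DataFrame, optional
        Specific community-weighted dates, one row per plot, one column per
        phenophase (as produced by :func:`thawpheno.community.cwm_wide`).
        Missing dates yield missing cumulative TDD.
    """
    rows = {}
    grouped = bundle.temperature.groupby("plot_id")
    for plot_id, sub in grouped:
        daily = daily_means(sub)
        row = {"tdd": thaw_degree_days(daily)}
        if cwm_dates is not None and plot_id in cwm_dates.index:
            for phase in PHENOPHASES:
                date = cwm_dates.at[plot_id, phase] if phase in cwm_dates.columns else np.nan
                row[f"cum_tdd_{phase}"] = (
                    cumulative_tdd(daily, float(date)) if np.isfinite(date) else np.nan
                )
        rows[plot_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "plot_id"
    return out


def daily_mean_matrix(bundle: Bundle) -> tuple[np.ndarray, np.ndarray, list]:
    """Vectorized daily means for all plots at once.

    Returns ``(days, matrix, plot_ids)`` where ``matrix`` is plots x days.
    Fast path used by the pipeline and the synthetic-scenario simulations.
    """
    temp = bundle.temperature
    piv = temp.pivot_table(
        index="plot_id", columns="julian_day", values="temp_c", aggfunc="mean"
    )
    return piv.columns.to_numpy(dtype=int), piv.to_numpy(dtype=float), list(piv.index)
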