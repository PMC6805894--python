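"""1-day and 3-day greenness summary products.

Sub-daily per-image chromatic coordinates are aggregated to the 90th
percentile within 1-day or 3-day windows; the high quantile damps the
darkening effect of clouds, rain and shadows while tracking the seasonal
envelope of canopy greenness. 3-day windows are non-overlapping, anchored at
January 1 of each year, and the aggregate is assigned to the middle day
(day of year 2, 5, 8, ...); the short final window of a year is aggregated
as-is. Windows with no retained images stay in the table with a missing
marker and an image count of zero so downstream smoothing sees an even date
grid.

Smoothing fits a locally weighted linear regression (tricube weights) to
the non-flagged percentile values and evaluates it on the full grid; the
confidence band comes from a residual-resampling bootstrap: residuals of the
fit are resampled with replacement onto the fitted values, the fit is
repeated, and the 2.5/97.5 percentiles of the bootstrap curves at each date
form the band.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .imageio import RoiStatsTable, SummarySeries, ValidationError

__all__ = ["aggregate_percentile", "smooth_series", "SMOOTH_BANDWIDTH_DAYS"]

#: Default smoothing bandwidth, in days of data per local fit. Wide enough
#: to suppress day-to-day weather noise, narrow enough that the local linear
#: fit tracks a green-up whose logistic time constant is a few days without
#: biasing its threshold crossings.
SMOOTH_BANDWIDTH_DAYS = 12.0

DEFAULT_QUANTILE = 0.90


def aggregate_percentile(
    roistats: RoiStatsTable, interval: int, q: float = DEFAULT_QUANTILE
) -> SummarySeries:
    """Build the 1-day or 3-day summary product from QC-filtered roistats.

    For each window the gcc_90/rcc_90/bcc_90 columns hold the q-quantile
    (linear interpolation between order statistics) of all retained
    per-image values; ``midday_gcc`` is the gcc of the image nearest local
    noon on the window's center date. The input is expected to be already
    screened (darkness filter applied, undefined coordinates removed).
    """
    if interval not in (1, 3):
        raise ValidationError(f"interval must be 1 or 3, got {interval}")
    df = roistats.df
    out_cols = [
        "date", "year", "doy", "image_count", "midday_gcc",
        "gcc_90", "rcc_90", "bcc_90",
        "smooth_gcc", "ci_low", "ci_high", "outlier_flag",
    ]
    if df.empty:
        return SummarySeries(
            roistats.site, roistats.veg_type, roistats.roi_id, interval,
            pd.DataFrame(columns=out_cols),
        )

    obs = df[df["gcc"].notna()].copy()
    source = obs if not obs.empty else df
    dates = pd.to_datetime(source["date"]).dt.date
    first, last = min(dates), max(dates)
    obs_dates = pd.to_datetime(obs["date"]).dt.date if not obs.empty else dates

    centers = _window_centers(first, last, interval)
    win_of_obs = (
        np.array([_window_center(d, interval) for d in obs_dates])
        if not obs.empty
        else np.array([], dtype=object)
    )

    rows = []
    for center in centers:
        in_win = obs.iloc[np.where(win_of_obs == center)[0]] if not obs.empty else obs
        n = len(in_win)
        if n:
            gcc_q = float(np.percentile(in_win["gcc"], 100 * q))
            rcc_q = float(np.percentile(in_win["rcc"], 100 * q))
            bcc_q = float(np.percentile(in_win["bcc"], 100 * q))
        else:
            gcc_q = rcc_q = bcc_q = np.nan
        rows.append(
            {
                "date": center,
                "year": center.year,
                "doy": center.timetuple().tm_yday,
                "image_count": n,
                "midday_gcc": _midday_gcc(in_win, center),
                "gcc_90": gcc_q,
                "rcc_90": rcc_q,
                "bcc_90": bcc_q,
                "smooth_gcc": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "outlier_flag": 0,
            }
        )
    return SummarySeries(
        roistats.site, roistats.veg_type, roistats.roi_id, interval,
        pd.DataFrame(rows, columns=out_cols),
    )


def _window_center(d: _dt.date, interval: int) -> _dt.date:
    if interval == 1:
        return d
    jan1 = _dt.date(d.year, 1, 1)
    w = (d - jan1).days // 3
    return jan1 + _dt.timedelta(days=3 * w + 1)  # DOY 2, 5, 8, ...


def _window_centers(first: _dt.date, last: _dt.date, interval: int) -> list[_dt.date]:
    lo, hi = _window_center(first, interval), _window_center(last, interval)
    if interval == 1:
        n = (hi - lo).days + 1
        return [lo + _dt.timedelta(days=i) for i in range(n)]
    centers = []
    for year in range(lo.year, hi.year + 1):
        jan1 = _dt.date(year, 1, 1)
        n_days = (_dt.date(year + 1, 1, 1) - jan1).days
        for w in range((n_days + 2) // 3):
            c = jan1 + _dt.timedelta(days=3 * w + 1)  # DOY 2, 5, ..., always in-year
            if lo <= c <= hi:
                centers.append(c)
    return centers


def _midday_gcc(in_win: pd.DataFrame, center: _dt.date) -> float:
    if in_win.empty:
        return np.nan
    on_day = in_win[pd.to_datetime(in_win["date"]).dt.date == center]
    if on_day.empty:
        return np.nan
    seconds = pd.to_datetime(on_day["local_std_time"], format="%H:%M:%S")
    offset = (
        seconds.dt.hour * 3600 + seconds.dt.minute * 60 + seconds.dt.second - 12 * 3600
    ).abs()
    return float(on_day.loc[offset.idxmin(), "gcc"])


def smooth_series(
    series: SummarySeries,
    span: float | None = None,
    n_boot: int = 200,
    seed: int | None = None,
) -> SummarySeries:
    """Fill ``smooth_gcc`` and the bootstrap band ``ci_low``/``ci_high``.

    Points flagged as outliers (``outlier_flag != 0``) or missing are
    excluded from the fit; the fitted curve is evaluated at every center
    date. ``span`` is the LOESS window as a fraction of the observations;
    when None it is derived from :data:`SMOOTH_BANDWIDTH_DAYS` (at least 7
    points). The band holds the 2.5/97.5 percentiles of ``n_boot``
    residual-resampling refits, reproducible under ``seed``.
    """
    df = series.df.copy()
    use = df["gcc_90"].notna() & (df["outlier_flag"] == 0)
    if not use.any():
        raise ValidationError("no usable points to smooth")
    x_all = np.array([float(d.toordinal()) for d in df["date"]])
    x = x_all[use.to_numpy()]
    y = df.loc[use, "gcc_90"].to_numpy(dtype=float)
    n = len(x)
    if span is None:
        span_days = x.max() - x.min()
        frac = 1.0 if span_days == 0 else max(
            SMOOTH_BANDWIDTH_DAYS / max(span_days, 1.0), 7.0 / n
        )
        frac = min(frac, 1.0)
    else:
        frac = span

    smooth = lowess(y, x, frac=frac, it=0, xvals=x_all)
    fitted_at_obs = lowess(y, x, frac=frac, it=0, xvals=x)
    resid = y - fitted_at_obs

    rng = np.random.default_rng(seed)
    if n_boot > 0:
        boots = np.empty((n_boot, len(x_all)))
        for b in range(n_boot):
            y_b = fitted_at_obs + rng.choice(resid, size=n, replace=True)
            boots[b] = lowess(y_b, x, frac=frac, it=0, xvals=x_all)
        ci_low = np.percentile(boots, 2.5, axis=0)
        ci_high = np.percentile(boots, 97.5, axis=0)
    else:
        ci_low = ci_high = smooth

    df["smooth_gcc"] = smooth
    df["ci_low"] = np.minimum(ci_low, smooth)
    df["ci_high"] = np.maximum(ci_high, smooth)
    return SummarySeries(
        series.site, series.veg_type, series.roi_id, series.interval, df
    )
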