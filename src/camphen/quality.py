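"""Quality screening for canopy-camera image stacks and greenness series.

Four screens are implemented:

* **AWB-suspect detection.** Cameras left on grey-world automatic white
  balance keep the whole-image mean color grey, so the deviation-from-grey
  statistic delta stays near zero. A calendar day is "low-delta" when every
  defined per-image delta that day falls below the threshold (0.02 by
  default); maximal runs of consecutive low-delta days longer than 30 days
  are reported as suspect intervals.
* **Haze degree.** A 0-100% per-image fog/haze score built from whole-image
  brightness and contrast; images scoring above 40% are flagged hazy but
  never removed.
* **Darkness screening.** Night and adverse-illumination exposures are
  dropped by a local-time window plus a whole-image brightness floor.
* **LOESS outlier flagging.** Greenness observations are compared against a
  locally weighted regression; points whose residual exceeds k robust
  standard deviations (1.4826 x the median absolute deviation of the
  residuals) are flagged, and flags are finalized against one refit with the
  flagged points removed.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .imageio import ImageRecord, RoiStatsTable

__all__ = [
    "AWBReport",
    "HazeStatistics",
    "HazeReport",
    "OutlierFlags",
    "detect_awb_suspects",
    "haze_statistics",
    "haze_degree",
    "flag_hazy",
    "darkness_filter",
    "loess_outlier_filter",
]

log = logging.getLogger(__name__)

DELTA_THRESHOLD = 0.02      # grey-deviation ceiling for an AWB-suspect day
AWB_MIN_DAYS = 30           # suspect only for runs strictly longer than this
HAZE_THRESHOLD = 40.0       # percent; hazy when strictly above
MIN_BRIGHTNESS = 30.0 / 255.0   # whole-image brightness floor (mean DN 30)
DAY_WINDOW = (_dt.time(7, 0), _dt.time(17, 0))  # local-time retention window


@dataclass
class AWBReport:
    """Per-image grey deviations plus detected suspect day-runs."""

    per_image: pd.DataFrame          # columns: timestamp, delta
    suspect_intervals: list[tuple[_dt.date, _dt.date, int]] = field(default_factory=list)


@dataclass(frozen=True)
class HazeStatistics:
    """Whole-image brightness/darkness/contrast and the derived haze degree.

    brightness is the mean over pixels of the per-pixel maximum channel value
    scaled to [0, 1]; darkness the analogous per-pixel minimum; contrast the
    root-mean-square spread of per-pixel brightness scaled by its theoretical
    maximum of 0.5.
    """

    brightness: float
    darkness: float
    contrast: float
    haze_degree: float


@dataclass
class HazeReport:
    per_image: pd.DataFrame          # columns: timestamp, haze_degree, hazy
    threshold: float = HAZE_THRESHOLD


@dataclass
class OutlierFlags:
    per_point: pd.DataFrame  # columns: date, observed_gcc, fitted_gcc, residual, is_outlier


# ---------------------------------------------------------------------------
# AWB suspects
# ---------------------------------------------------------------------------


def detect_awb_suspects(
    deltas,
    delta_threshold: float = DELTA_THRESHOLD,
    min_days: int = AWB_MIN_DAYS,
) -> AWBReport:
    """Find sustained runs of near-grey whole-image color.

    ``deltas`` is a chronologically sorted iterable of ``(timestamp, delta)``
    (or an equivalent two-column DataFrame). A calendar day is low-delta when
    it has at least one defined delta and every defined delta that day is
    below ``delta_threshold``; maximal runs of *consecutive* calendar
    low-delta days of length strictly greater than ``min_days`` become
    suspect intervals. Days without observations break a run.
    """
    if isinstance(deltas, pd.DataFrame):
        df = deltas.rename(columns=dict(zip(deltas.columns, ["timestamp", "delta"])))
    else:
        df = pd.DataFrame(list(deltas), columns=["timestamp", "delta"])
    if df.empty:
        return AWBReport(per_image=df)
    df = df.copy()
    days = df["timestamp"].map(
        lambda t: t.date() if isinstance(t, _dt.datetime) else t
    )
    defined = df["delta"].notna()
    by_day = (
        pd.DataFrame({"day": days[defined], "low": df.loc[defined, "delta"] < delta_threshold})
        .groupby("day")["low"]
        .all()
    )
    intervals: list[tuple[_dt.date, _dt.date, int]] = []
    run_start: _dt.date | None = None
    prev_day: _dt.date | None = None

    def close_run(end_day: _dt.date) -> None:
        nonlocal run_start
        if run_start is not None:
            n = (end_day - run_start).days + 1
            if n > min_days:
                intervals.append((run_start, end_day, n))
        run_start = None

    for day, low in by_day.items():
        contiguous = prev_day is not None and (day - prev_day).days == 1
        if low:
            if run_start is None or (prev_day is not None and not contiguous):
                if not contiguous and prev_day is not None:
                    close_run(prev_day)
                run_start = day
        else:
            if prev_day is not None:
                close_run(prev_day)
        prev_day = day
    if run_start is not None and prev_day is not None:
        close_run(prev_day)
    return AWBReport(per_image=df, suspect_intervals=intervals)


# ---------------------------------------------------------------------------
# Haze
# ---------------------------------------------------------------------------


def haze_statistics(image: ImageRecord) -> HazeStatistics:
    """Brightness, darkness, RMS contrast and the haze-degree composite.

    The haze degree is ``100 * (brightness + (1 - contrast)) / 2``: a bright
    low-contrast frame (fog, haze, washed-out sky) scores high, a dark or
    well-contrasted frame low. It depends only on per-pixel channel
    statistics, so it is invariant to permuting pixel positions.
    """
    px = image.pixels.astype(np.float64) / 255.0
    per_pixel_bright = px.max(axis=2)
    brightness = float(per_pixel_bright.mean())
    darkness = float(px.min(axis=2).mean())
    contrast = float(min(per_pixel_bright.std() / 0.5, 1.0))
    omega = 100.0 * (brightness + (1.0 - contrast)) / 2.0
    return HazeStatistics(
        brightness=brightness, darkness=darkness, contrast=contrast, haze_degree=omega
    )


def haze_degree(image: ImageRecord) -> float:
    """Haze-degree percentage in [0, 100] for one exposure."""
    return haze_statistics(image).haze_degree


def flag_hazy(haze, threshold: float = HAZE_THRESHOLD) -> HazeReport:
    """Annotate a per-image ``(timestamp, haze_degree)`` series.

    Images scoring strictly above ``threshold`` percent are flagged hazy;
    flagged images are annotated, never removed from the record.
    """
    if isinstance(haze, pd.DataFrame):
        df = haze.rename(columns=dict(zip(haze.columns, ["timestamp", "haze_degree"])))
    else:
        df = pd.DataFrame(list(haze), columns=["timestamp", "haze_degree"])
    df = df.copy()
    df["hazy"] = df["haze_degree"] > threshold
    return HazeReport(per_image=df, threshold=threshold)


# ---------------------------------------------------------------------------
# Darkness / illumination screening
# ---------------------------------------------------------------------------


def darkness_filter(
    roistats: RoiStatsTable,
    min_brightness: float = MIN_BRIGHTNESS,
    time_window: tuple[_dt.time, _dt.time] = DAY_WINDOW,
) -> RoiStatsTable:
    """Drop rows outside the local-time window or below the brightness floor.

    Both defaults (07:00-17:00 and whole-image mean brightness >= 30/255) are
    deliberately conservative; the removed-row count is logged.
    """
    df = roistats.df
    if df.empty:
        return roistats
    times = pd.to_datetime(df["local_std_time"], format="%H:%M:%S").dt.time
    in_window = (times >= time_window[0]) & (times <= time_window[1])
    bright = df["brightness"] >= min_brightness
    keep = in_window & bright
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("darkness filter removed %d of %d rows", n_removed, len(df))
    return RoiStatsTable(
        site=roistats.site,
        veg_type=roistats.veg_type,
        roi_id=roistats.roi_id,
        df=df[keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# LOESS outlier flagging
# ---------------------------------------------------------------------------

MIN_POINTS_FOR_LOESS = 10

#: Default trend bandwidth for outlier detection, days of data per local
#: fit: wide enough to average over weather, narrow enough that a steep
#: green-up is trend, not outlier.
OUTLIER_BANDWIDTH_DAYS = 15.0

#: Floor on the robust residual scale, in Gcc units. 8-bit digital numbers
#: quantize Gcc at roughly this step, so residual spreads below it carry no
#: information and must not shrink the outlier cutoff toward zero.
MIN_RESIDUAL_SIGMA = 0.002


def loess_outlier_filter(
    series, span: float | None = None, k: float = 4.0
) -> OutlierFlags:
    """Flag greenness observations that sit far from a LOESS trend.

    ``series`` is ``(date, gcc)`` pairs (or a two-column DataFrame). A
    locally weighted linear regression (tricube weights, robustified) of gcc
    on date is fitted; observations with ``|residual| > k * max(1.4826 *
    MAD(residuals), MIN_RESIDUAL_SIGMA)`` are flagged, the fit is re-run
    once without them, and flags are finalized against the refit. ``span``
    is the window as a fraction of the observations; when None it is derived
    from :data:`OUTLIER_BANDWIDTH_DAYS` (at least 10 points). With fewer
    than 10 points nothing is flagged and a warning is logged.
    """
    if isinstance(series, pd.DataFrame):
        df = series.rename(columns=dict(zip(series.columns, ["date", "observed_gcc"])))
    else:
        df = pd.DataFrame(list(series), columns=["date", "observed_gcc"])
    df = df.copy().reset_index(drop=True)
    df["fitted_gcc"] = np.nan
    df["residual"] = np.nan
    df["is_outlier"] = False

    defined = df["observed_gcc"].notna()
    x = np.array([_to_ordinal(d) for d in df["date"]], dtype=float)
    y = df["observed_gcc"].to_numpy(dtype=float)
    idx = np.where(defined)[0]
    if len(idx) < MIN_POINTS_FOR_LOESS:
        log.warning(
            "LOESS outlier filter needs >= %d points, got %d; nothing flagged",
            MIN_POINTS_FOR_LOESS, len(idx),
        )
        return OutlierFlags(per_point=df)

    if span is None:
        span_days = x[idx].max() - x[idx].min()
        frac = 1.0 if span_days == 0 else max(
            OUTLIER_BANDWIDTH_DAYS / max(span_days, 1.0),
            MIN_POINTS_FOR_LOESS / len(idx),
        )
        frac = min(frac, 1.0)
    else:
        frac = span

    def robust_flags(fit_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # fit at the sample points, then interpolate onto the full grid
        # (robust iterations cannot be combined with direct xvals evaluation)
        curve = lowess(y[fit_idx], x[fit_idx], frac=frac, it=2, return_sorted=True)
        fitted = np.interp(x[idx], curve[:, 0], curve[:, 1])
        resid = y[idx] - fitted
        mad = np.median(np.abs(resid - np.median(resid)))
        cutoff = k * max(1.4826 * mad, MIN_RESIDUAL_SIGMA)
        flags = np.abs(resid) > cutoff
        return fitted, flags

    fitted, flags = robust_flags(idx)
    if flags.any() and (~flags).sum() >= MIN_POINTS_FOR_LOESS:
        fitted, flags = robust_flags(idx[~flags])

    df.loc[idx, "fitted_gcc"] = fitted
    df.loc[idx, "residual"] = y[idx] - fitted
    df.loc[idx, "is_outlier"] = flags
    return OutlierFlags(per_point=df)


def _to_ordinal(d) -> float:
    if isinstance(d, _dt.datetime):
        return d.toordinal() + (d.hour * 3600 + d.minute * 60 + d.second) / 86400.0
    if isinstance(d, _dt.date):
        return float(d.toordinal())
    return float(d)
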