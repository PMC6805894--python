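"""Phenophase transition dates from smoothed greenness series.

The smoothed greenness curve is segmented into alternating rising
(green-up) and falling (senescence) phases delimited by local minima and
maxima; extrema shallower than a minimum amplitude or closer together than
a minimum phase length are suppressed, so multi-cycle years (e.g. bimodal
grasslands) segment naturally while noise wiggles do not.

Within each cycle, the transition date for threshold p percent is the date
at which the smoothed curve first crosses

    baseline + (p/100) * (peak - baseline)

in the cycle's direction, located by linear interpolation between grid
dates (ties broken toward the earlier date). Baseline and peak are taken
from the smoothed curve *within* the cycle, not from annual extremes, so
each cycle of a multi-cycle year is scaled by its own amplitude. Date
uncertainties are read off the bootstrap confidence band: the earliest and
latest dates at which either band bound crosses the same target.

``compare_transition_sets`` reproduces the dataset-intercomparison metrics
(squared Pearson correlation, median absolute difference, root-mean-square
deviation and the fraction of pairs differing by more than 20 days) between
two transition-date sets, pairing dates of equal direction and threshold by
nearest date within a matching window.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .imageio import SummarySeries, TransitionSet

__all__ = [
    "SeasonalCycle",
    "ComparisonStats",
    "segment_cycles",
    "transition_dates",
    "extract_transitions",
    "compare_transition_sets",
]

log = logging.getLogger(__name__)

MIN_AMPLITUDE = 0.02       # Gcc units; suppresses noise cycles
MIN_PHASE_DAYS = 30        # minimum spacing between retained extrema
THRESHOLDS = (10, 25, 50)  # percent of cycle amplitude
LARGE_GAP_DAYS = 20        # intercomparison "large discrepancy" cutoff


@dataclass
class SeasonalCycle:
    """One rising or falling limb of a seasonal greenness cycle."""

    direction: str                 # "rising" | "falling"
    start_date: _dt.date
    end_date: _dt.date
    baseline_gcc: float            # cycle minimum of the smoothed curve
    peak_gcc: float                # cycle maximum of the smoothed curve
    start_idx: int                 # indices into the smoothed grid
    end_idx: int

    @property
    def amplitude(self) -> float:
        return self.peak_gcc - self.baseline_gcc


@dataclass
class ComparisonStats:
    n_pairs: int
    r_squared: float
    median_abs_error_days: float
    rmsd_days: float
    frac_gt_20d: float


# ---------------------------------------------------------------------------
# Cycle segmentation
# ---------------------------------------------------------------------------


def segment_cycles(
    series: SummarySeries,
    min_amplitude: float = MIN_AMPLITUDE,
    min_phase_days: float = MIN_PHASE_DAYS,
) -> list[SeasonalCycle]:
    """Split the smoothed curve into rising and falling cycles.

    Peaks are local maxima of ``smooth_gcc`` with prominence at least
    ``min_amplitude`` and spacing at least ``min_phase_days``; each peak is
    bracketed by the curve minima toward the neighbouring peaks (or the
    series ends), giving one rising (min -> max) and one falling
    (max -> min) cycle per peak, kept only when its amplitude exceeds
    ``min_amplitude``. An empty list (with a warning) means no seasonal
    cycle was found.
    """
    sdf = series.df[series.df["smooth_gcc"].notna()].reset_index()
    if sdf.empty:
        log.warning("no smoothed values; cannot segment cycles")
        return []
    y = sdf["smooth_gcc"].to_numpy(dtype=float)
    x = np.array([float(d.toordinal()) for d in sdf["date"]])
    step = float(np.median(np.diff(x))) if len(x) > 1 else 1.0
    distance = max(1, int(round(min_phase_days / step)))
    peaks, _ = find_peaks(y, prominence=min_amplitude, distance=distance)
    if len(peaks) == 0:
        log.warning("no seasonal peaks found (flat or low-amplitude series)")
        return []

    cycles: list[SeasonalCycle] = []
    bounds = [0, *peaks, len(y) - 1]
    for i, p in enumerate(peaks):
        left_lo = bounds[i] + int(np.argmin(y[bounds[i]: p + 1]))
        right_hi = peaks[i + 1] if i + 1 < len(peaks) else len(y) - 1
        right_lo = p + int(np.argmin(y[p: right_hi + 1]))
        for direction, a, b in (("rising", left_lo, p), ("falling", p, right_lo)):
            if b <= a:
                continue
            baseline = float(min(y[a], y[b]))
            peak = float(y[p])
            if peak - baseline <= min_amplitude:
                continue
            cycles.append(
                SeasonalCycle(
                    direction=direction,
                    start_date=sdf.loc[a, "date"],
                    end_date=sdf.loc[b, "date"],
                    baseline_gcc=baseline,
                    peak_gcc=peak,
                    start_idx=a,
                    end_idx=b,
                )
            )
    return cycles


# ---------------------------------------------------------------------------
# Threshold crossing dates
# ---------------------------------------------------------------------------


def _first_crossing(
    x: np.ndarray, y: np.ndarray, target: float, direction: str
) -> float:
    """Ordinal date of the first crossing of ``target`` along the limb.

    Rising limbs cross upward, falling limbs downward; linear interpolation
    between grid points, ties toward the earlier date. NaN if never crossed.
    """
    if direction == "rising":
        above = y >= target
    else:
        above = y <= target
    if above[0]:
        return float(x[0])
    hits = np.where(~above[:-1] & above[1:])[0]
    if len(hits) == 0:
        return float("nan")
    j = hits[0]
    y0, y1 = y[j], y[j + 1]
    if y1 == y0:
        return float(x[j])
    return float(x[j] + (target - y0) / (y1 - y0) * (x[j + 1] - x[j]))


def transition_dates(
    cycle: SeasonalCycle,
    series: SummarySeries,
    thresholds=THRESHOLDS,
    cycle_id: int = 0,
) -> pd.DataFrame:
    """Rows of threshold-crossing dates (with CI dates) for one cycle."""
    sdf = series.df[series.df["smooth_gcc"].notna()].reset_index(drop=True)
    sel = sdf.iloc[cycle.start_idx: cycle.end_idx + 1]
    x = np.array([float(d.toordinal()) for d in sel["date"]])
    y = sel["smooth_gcc"].to_numpy(dtype=float)
    lo = sel["ci_low"].to_numpy(dtype=float)
    hi = sel["ci_high"].to_numpy(dtype=float)
    has_band = not (np.isnan(lo).all() or np.isnan(hi).all())

    rows = []
    for p in thresholds:
        target = cycle.baseline_gcc + (p / 100.0) * cycle.amplitude
        xc = _first_crossing(x, y, target, cycle.direction)
        if np.isnan(xc):
            log.warning(
                "threshold %d%% never crossed in %s cycle starting %s",
                p, cycle.direction, cycle.start_date,
            )
            rows.append(
                {
                    "cycle_id": cycle_id,
                    "direction": cycle.direction,
                    "threshold_percent": p,
                    "transition_date": None,
                    "ci_low_date": None,
                    "ci_high_date": None,
                    "gcc_at_threshold": target,
                }
            )
            continue
        if has_band:
            c_lo = _first_crossing(x, lo, target, cycle.direction)
            c_hi = _first_crossing(x, hi, target, cycle.direction)
            candidates = [c for c in (c_lo, c_hi) if not np.isnan(c)]
            early = min([xc, *candidates])
            late = max([xc, *candidates])
        else:
            early = late = xc
        rows.append(
            {
                "cycle_id": cycle_id,
                "direction": cycle.direction,
                "threshold_percent": p,
                "transition_date": _from_ordinal(xc),
                "ci_low_date": _from_ordinal(early),
                "ci_high_date": _from_ordinal(late),
                "gcc_at_threshold": target,
            }
        )
    return pd.DataFrame(rows)


def _from_ordinal(x: float) -> _dt.date:
    # round to the nearest day for reporting; sub-day precision is not
    # meaningful on a 1- or 3-day grid
    return _dt.date.fromordinal(int(round(x)))


def extract_transitions(
    series: SummarySeries,
    min_amplitude: float = MIN_AMPLITUDE,
    min_phase_days: float = MIN_PHASE_DAYS,
    thresholds=THRESHOLDS,
) -> TransitionSet:
    """Segment a smoothed summary series and extract all transition rows."""
    cycles = segment_cycles(series, min_amplitude, min_phase_days)
    frames = [
        transition_dates(c, series, thresholds, cycle_id=i)
        for i, c in enumerate(cycles)
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "cycle_id", "direction", "threshold_percent",
                "transition_date", "ci_low_date", "ci_high_date",
                "gcc_at_threshold",
            ]
        )
    )
    return TransitionSet(
        site=series.site, veg_type=series.veg_type, roi_id=series.roi_id,
        interval=series.interval, df=df,
    )


# ---------------------------------------------------------------------------
# Intercomparison of two transition-date sets
# ---------------------------------------------------------------------------


def compare_transition_sets(
    a: TransitionSet | pd.DataFrame,
    b: TransitionSet | pd.DataFrame,
    match_window_days: float = 30.0,
) -> dict[int, ComparisonStats]:
    """Agreement metrics between two transition-date sets, per threshold.

    Dates of equal direction and threshold are paired greedily by nearest
    date (each date used at most once, only pairs within
    ``match_window_days``). For each threshold the paired dates give the
    squared Pearson correlation, median absolute difference, RMSD and the
    fraction of pairs differing by more than 20 days. MAE/RMSD/fraction are
    symmetric in the arguments and invariant to shifting both sets by a
    constant number of days.
    """
    df_a = a.df if isinstance(a, TransitionSet) else a
    df_b = b.df if isinstance(b, TransitionSet) else b
    pairs: dict[int, list[tuple[float, float]]] = {}
    keys = set()
    for df in (df_a, df_b):
        keys |= set(map(tuple, df[["direction", "threshold_percent"]].values))
    for direction, threshold in sorted(keys):
        xa = _dates_for(df_a, direction, threshold)
        xb = _dates_for(df_b, direction, threshold)
        pairs.setdefault(int(threshold), []).extend(
            _greedy_pairs(xa, xb, match_window_days)
        )

    out: dict[int, ComparisonStats] = {}
    for threshold, pp in sorted(pairs.items()):
        if not pp:
            out[threshold] = ComparisonStats(0, np.nan, np.nan, np.nan, np.nan)
            continue
        da = np.array([p[0] for p in pp])
        db = np.array([p[1] for p in pp])
        diff = da - db
        out[threshold] = ComparisonStats(
            n_pairs=len(pp),
            r_squared=_r_squared(da, db),
            median_abs_error_days=float(np.median(np.abs(diff))),
            rmsd_days=float(np.sqrt(np.mean(diff**2))),
            frac_gt_20d=float(np.mean(np.abs(diff) > LARGE_GAP_DAYS)),
        )
    return out


def _dates_for(df: pd.DataFrame, direction: str, threshold: int) -> np.ndarray:
    sel = df[
        (df["direction"] == direction)
        & (df["threshold_percent"] == threshold)
        & df["transition_date"].notna()
    ]
    return np.sort(
        np.array([float(d.toordinal()) for d in sel["transition_date"]])
    )


def _greedy_pairs(
    xa: np.ndarray, xb: np.ndarray, window: float
) -> list[tuple[float, float]]:
    if len(xa) == 0 or len(xb) == 0:
        return []
    cand = [
        (abs(va - vb), i, j)
        for i, va in enumerate(xa)
        for j, vb in enumerate(xb)
        if abs(va - vb) <= window
    ]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((float(xa[i]), float(xb[j])))
    return pairs


def _r_squared(da: np.ndarray, db: np.ndarray) -> float:
    if len(da) < 2:
        return float("nan")
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        # degenerate: no spread on one axis; perfect only if identical
        return 1.0 if np.array_equal(da, db) else float("nan")
    r = np.corrcoef(da, db)[0, 1]
    return float(r * r)
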