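"""Ground-truthed synthetic camera stacks and greenness series.

The generator emulates the phenomena the processing chain must survive:

* a double-logistic seasonal greenness trajectory (spring green-up and
  autumn senescence), whose threshold crossings are recoverable exactly and
  therefore serve as ground truth for transition-date extraction;
* rendered frames split into a blue-grey "sky" band (top 40%, excluded
  from the canopy ROI) and a "canopy" band whose chromatic coordinates
  carry the seasonal signal plus per-image Gaussian noise;
* fog events (blending the frame toward uniform bright grey), snow events
  (near-white canopy) and grey-world automatic white balance applied over a
  configurable date interval;
* archive-convention artifacts on disk: a JPEG stack with
  ``<site>_YYYY_MM_DD_HHMMSS.jpg`` names, a TIFF canopy mask, an ROI list
  CSV and a truth table of per-date greenness and analytic transition
  dates.

Everything is reproducible from the config seed. Rendering adds a +/-0.5 DN
uniform dither before 8-bit quantization so that region means are unbiased;
JPEGs are written at maximum quality, which keeps the quantization error
budget within about one digital number.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.special import expit

from .imageio import (
    ImageRecord,
    ROIDefinition,
    ValidationError,
    format_image_filename,
    write_mask,
    write_roi_definition,
    OPEN_END,
)

__all__ = [
    "SceneConfig",
    "GeneratedSite",
    "seasonal_gcc_curve",
    "true_transition_dates",
    "simulate_gcc_series",
    "render_image",
    "apply_grey_world",
    "generate_site",
]

SKY_FRACTION = 0.4            # top band of the frame, outside the canopy ROI
SKY_RGB = (100.0, 125.0, 185.0)   # fixed blue sky tone; keeps the whole-image
                                  # mean color clearly non-grey when AWB is off
CANOPY_TOTAL_DN = 330.0       # r+g+b digital-number sum of the canopy tone
FOG_DN = 242.0                # uniform bright grey that fog blends toward
SNOW_DN = 238.0               # near-white canopy on snow days


@dataclass
class SceneConfig:
    """Study conditions for one synthetic site-year.

    Defaults describe a temperate deciduous-broadleaf canopy: winter
    baseline Gcc 0.33, seasonal amplitude 0.10, green-up centered at day of
    year 140 with a 5-day logistic time constant, senescence at day 270
    with an 8-day constant, and per-image greenness noise of 0.003 Gcc.
    """

    site: str = "simcam"
    start_date: _dt.date = _dt.date(2018, 1, 1)
    end_date: _dt.date = _dt.date(2018, 12, 31)
    images_per_day: int = 2
    image_size: tuple[int, int] = (96, 144)       # (height, width)
    baseline_gcc: float = 0.33
    amplitude: float = 0.10
    green_up_mid: float = 140.0                   # DOY of 50% green-up
    green_down_mid: float = 270.0                 # DOY of 50% senescence
    slope_up: float = 5.0                         # logistic time constants, days
    slope_down: float = 8.0
    noise_sd: float = 0.003                       # per-image Gcc noise
    fog_days: dict = field(default_factory=dict)  # {date: alpha in [0, 1]}
    snow_days: frozenset = frozenset()
    awb_interval: tuple[_dt.date, _dt.date] | None = None
    veg_type: str = "DB"
    roi_id: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_gcc + self.amplitude > 0.9:
            raise ValidationError("baseline_gcc + amplitude must not exceed 0.9")
        if self.end_date < self.start_date:
            raise ValidationError("end_date before start_date")


@dataclass
class GeneratedSite:
    image_dir: Path
    image_paths: list[Path]
    mask_path: Path
    roi_csv_path: Path
    roi_definition: ROIDefinition
    truth: pd.DataFrame
    truth_path: Path


# ---------------------------------------------------------------------------
# Seasonal truth model
# ---------------------------------------------------------------------------


def seasonal_gcc_curve(config: SceneConfig, when) -> float:
    """True canopy Gcc at a date (or fractional day of year).

    Double logistic: ``baseline + amplitude * [expit((t - m_up)/s_up)
    - expit((t - m_down)/s_down)]`` with t the day of year; deterministic,
    repeats annually.
    """
    t = _doy(when)
    rise = expit((t - config.green_up_mid) / config.slope_up)
    fall = expit((t - config.green_down_mid) / config.slope_down)
    return float(config.baseline_gcc + config.amplitude * (rise - fall))


def _doy(when) -> float:
    if isinstance(when, _dt.datetime):
        return when.timetuple().tm_yday + (
            when.hour * 3600 + when.minute * 60 + when.second
        ) / 86400.0
    if isinstance(when, _dt.date):
        return float(when.timetuple().tm_yday)
    return float(when)


def true_transition_dates(
    config: SceneConfig, thresholds=(10, 25, 50), year: int | None = None
) -> pd.DataFrame:
    """Exact threshold-crossing dates of the noise-free seasonal curve.

    The curve is evaluated on a 0.01-day grid over one year; each limb's
    baseline/peak come from the curve itself, and crossings are located by
    linear interpolation, mirroring the definition the pipeline estimates.
    """
    year = year or config.start_date.year
    grid = np.arange(1.0, 366.0, 0.01)
    y = config.baseline_gcc + config.amplitude * (
        expit((grid - config.green_up_mid) / config.slope_up)
        - expit((grid - config.green_down_mid) / config.slope_down)
    )
    p_idx = int(np.argmax(y))
    rows = []
    for direction in ("rising", "falling"):
        if direction == "rising":
            seg, gx = y[: p_idx + 1], grid[: p_idx + 1]
        else:
            seg, gx = y[p_idx:], grid[p_idx:]
        baseline = float(seg.min())
        amp = float(y[p_idx] - baseline)
        for p in thresholds:
            target = baseline + (p / 100.0) * amp
            if direction == "rising":
                j = int(np.argmax(seg >= target))
            else:
                j = int(np.argmax(seg <= target))
            if j == 0:
                doy = float(gx[0])
            else:
                y0, y1 = seg[j - 1], seg[j]
                doy = float(gx[j - 1] + (target - y0) / (y1 - y0) * (gx[j] - gx[j - 1]))
            rows.append(
                {
                    "direction": direction,
                    "threshold_percent": p,
                    "true_doy": doy,
                    "true_date": _dt.date(year, 1, 1)
                    + _dt.timedelta(days=int(round(doy)) - 1),
                    "true_gcc": target,
                }
            )
    return pd.DataFrame(rows)


def simulate_gcc_series(config: SceneConfig, rng=None) -> pd.DataFrame:
    """Daily (date, gcc) observations: true curve plus Gaussian noise.

    A fast series-level stand-in for the full renderer, for experiments
    where image formation is not under test.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = (config.end_date - config.start_date).days + 1
    dates = [config.start_date + _dt.timedelta(days=i) for i in range(n)]
    gcc = np.array([seasonal_gcc_curve(config, d) for d in dates])
    gcc = gcc + rng.normal(0.0, config.noise_sd, size=n)
    return pd.DataFrame({"date": dates, "gcc": gcc})


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_image(
    true_gcc: float,
    config: SceneConfig,
    timestamp: _dt.datetime,
    rng,
    fog_alpha: float = 0.0,
    snow: bool = False,
    color_cast: tuple[float, float, float] | None = None,
) -> ImageRecord:
    """Render one frame whose canopy carries the requested greenness.

    The canopy band's chromatic coordinates are ``(rcc, true_gcc + eps,
    bcc)`` with ``eps ~ Normal(0, noise_sd)`` and the red/blue remainder
    split 55/45; the sky band is a fixed blue-grey. ``fog_alpha`` blends
    the whole frame toward uniform bright grey, ``snow`` paints the canopy
    near-white, and ``color_cast`` multiplies the channels by the given
    gains (emulating a misbalanced camera).
    """
    h, w = config.image_size
    sky_rows = int(round(SKY_FRACTION * h))
    frame = np.empty((h, w, 3), dtype=np.float64)
    frame[:sky_rows] = SKY_RGB

    gcc = float(np.clip(true_gcc + rng.normal(0.0, config.noise_sd), 0.02, 0.95))
    if snow:
        canopy_rgb = (SNOW_DN, SNOW_DN, SNOW_DN)
    else:
        rcc = 0.55 * (1.0 - gcc)
        bcc = 0.45 * (1.0 - gcc)
        canopy_rgb = (
            rcc * CANOPY_TOTAL_DN, gcc * CANOPY_TOTAL_DN, bcc * CANOPY_TOTAL_DN
        )
    frame[sky_rows:] = canopy_rgb

    if fog_alpha > 0.0:
        frame = (1.0 - fog_alpha) * frame + fog_alpha * FOG_DN
    if color_cast is not None:
        frame = frame * np.asarray(color_cast, dtype=np.float64)

    # unbiased 8-bit quantization: +/-0.5 DN uniform dither before rounding
    frame = frame + rng.uniform(-0.5, 0.5, size=frame.shape)
    pixels = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return ImageRecord(
        pixels=pixels, timestamp=timestamp, site=config.site, source_path="synthetic"
    )


def canopy_mask_array(config: SceneConfig) -> np.ndarray:
    """Boolean inside-ROI array covering the canopy band of the frame."""
    h, w = config.image_size
    mask = np.zeros((h, w), dtype=bool)
    mask[int(round(SKY_FRACTION * h)):] = True
    return mask


def apply_grey_world(image: ImageRecord) -> ImageRecord:
    """Grey-world automatic white balance: rescale each channel so its
    whole-image mean equals the grand mean of the three channel means.

    The output's whole-image chromatic coordinates are equal (about 0.33
    each) up to 8-bit quantization, i.e. the mean color is grey.
    """
    px = image.pixels.astype(np.float64)
    means = px.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0):
        raise ValidationError("grey-world rescaling undefined for a zero-mean channel")
    gains = means.mean() / means
    out = np.clip(np.rint(px * gains), 0, 255).astype(np.uint8)
    return ImageRecord(
        pixels=out, timestamp=image.timestamp, site=image.site,
        source_path=image.source_path,
    )


# ---------------------------------------------------------------------------
# Full-site generation
# ---------------------------------------------------------------------------


def _daily_times(images_per_day: int) -> list[_dt.time]:
    if images_per_day == 1:
        return [_dt.time(12, 0, 0)]
    minutes = np.linspace(9 * 60, 15 * 60, images_per_day)
    return [_dt.time(int(m) // 60, int(m) % 60, 0) for m in minutes]


def generate_site(config: SceneConfig, out_dir: str | Path) -> GeneratedSite:
    """Write a complete synthetic site to disk.

    Produces the JPEG image stack (archive filename convention), the canopy
    ROI mask TIFF, the ROI list CSV with one open-ended interval, and a
    truth CSV (per-limb analytic transition dates). Byte-reproducible from
    ``config.seed``.
    """
    out_dir = Path(out_dir)
    image_dir = out_dir / "images"
    image_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    times = _daily_times(config.images_per_day)
    image_paths: list[Path] = []
    n_days = (config.end_date - config.start_date).days + 1
    for i in range(n_days):
        day = config.start_date + _dt.timedelta(days=i)
        fog_alpha = float(config.fog_days.get(day, 0.0))
        snow = day in config.snow_days
        awb = (
            config.awb_interval is not None
            and config.awb_interval[0] <= day <= config.awb_interval[1]
        )
        true_gcc = seasonal_gcc_curve(config, day)
        for t in times:
            ts = _dt.datetime.combine(day, t)
            image = render_image(
                true_gcc, config, ts, rng, fog_alpha=fog_alpha, snow=snow
            )
            if awb:
                image = apply_grey_world(image)
            path = image_dir / format_image_filename(config.site, ts)
            Image.fromarray(image.pixels).save(path, quality=100, subsampling=0)
            image_paths.append(path)

    mask_name = f"{config.site}_{config.veg_type}_{config.roi_id:04d}_01.tif"
    mask_path = out_dir / mask_name
    write_mask(canopy_mask_array(config), mask_path)

    roidef = ROIDefinition(
        site=config.site,
        veg_type=config.veg_type,
        roi_id=config.roi_id,
        intervals=[
            (mask_name, _dt.datetime.combine(config.start_date, _dt.time()), OPEN_END)
        ],
    )
    roi_csv_path = out_dir / f"{config.site}_{config.veg_type}_{config.roi_id:04d}_roi.csv"
    write_roi_definition(roidef, roi_csv_path)

    truth = true_transition_dates(config)
    truth_path = out_dir / f"{config.site}_truth.csv"
    truth.to_csv(truth_path, index=False)

    return GeneratedSite(
        image_dir=image_dir,
        image_paths=image_paths,
        mask_path=mask_path,
        roi_csv_path=roi_csv_path,
        roi_definition=roidef,
        truth=truth,
        truth_path=truth_path,
    )
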