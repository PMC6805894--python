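"""Per-image color statistics: channel means, chromatic coordinates, and the
deviation-from-grey statistic used to detect auto-white-balanced cameras.

The canopy greenness index is the green chromatic coordinate

    Gcc = G_DN / (R_DN + G_DN + B_DN)

where R_DN, G_DN, B_DN are the mean red, green and blue digital numbers over
the region of interest; Rcc and Bcc are the analogous normalized red and
blue coordinates. The deviation from grey,

    delta = sqrt((Rcc - 1/3)^2 + (Gcc - 1/3)^2 + (Bcc - 1/3)^2),

is computed from *whole-image* channel means: a camera whose automatic white
balance enforces the "grey world" model keeps the whole-image mean color
grey, so delta stays near zero regardless of season.

All statistics operate on raw 8-bit JPEG digital numbers in double
precision; no gamma linearization or radiometric calibration is applied.
An all-black region has an undefined chromatic decomposition; it yields a
NaN-filled result that downstream screening drops, not an exception, since
night exposures are expected in real image stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imageio import ImageRecord, ROIMask, RoiStatsTable, ROIDefinition, ValidationError
from . import quality as _quality

__all__ = [
    "MAX_DELTA",
    "ChannelMeans",
    "ChromaticCoordinates",
    "channel_means",
    "chromatic_coordinates",
    "grey_deviation",
    "image_statistics",
    "build_roistats",
]

#: Largest possible deviation from grey over the chromatic simplex.
MAX_DELTA = math.sqrt(2.0 / 3.0)


@dataclass(frozen=True)
class ChannelMeans:
    """Mean (and standard deviation) of each 8-bit channel over a region."""

    r_dn: float
    g_dn: float
    b_dn: float
    r_sd: float = 0.0
    g_sd: float = 0.0
    b_sd: float = 0.0
    scope: str = "roi"


@dataclass(frozen=True)
class ChromaticCoordinates:
    """Normalized channel fractions; NaN when the decomposition is undefined."""

    rcc: float
    gcc: float
    bcc: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.gcc)


UNDEFINED_COORDS = ChromaticCoordinates(float("nan"), float("nan"), float("nan"))


def channel_means(image: ImageRecord, mask: ROIMask | None = None) -> ChannelMeans:
    """Arithmetic mean and standard deviation of the digital numbers in each
    channel, over the ROI if a mask is given, otherwise over the whole frame.
    """
    px = image.pixels.astype(np.float64)
    if mask is None:
        sel = px.reshape(-1, 3)
        scope = "whole_image"
    else:
        if mask.mask.shape != image.shape:
            raise ValidationError(
                f"mask shape {mask.mask.shape} does not match image shape {image.shape}"
            )
        sel = px[mask.mask]
        scope = "roi"
    means = sel.mean(axis=0)
    sds = sel.std(axis=0)
    return ChannelMeans(
        r_dn=float(means[0]), g_dn=float(means[1]), b_dn=float(means[2]),
        r_sd=float(sds[0]), g_sd=float(sds[1]), b_sd=float(sds[2]),
        scope=scope,
    )


def chromatic_coordinates(means: ChannelMeans) -> ChromaticCoordinates:
    """Normalize channel means to the chromatic simplex (Rcc + Gcc + Bcc = 1)."""
    total = means.r_dn + means.g_dn + means.b_dn
    if total <= 0:
        return UNDEFINED_COORDS
    return ChromaticCoordinates(
        rcc=means.r_dn / total, gcc=means.g_dn / total, bcc=means.b_dn / total
    )


def grey_deviation(means: ChannelMeans) -> float:
    """Euclidean distance of the chromatic coordinates from (1/3, 1/3, 1/3).

    Intended for whole-image means; NaN when the coordinates are undefined.
    """
    cc = chromatic_coordinates(means)
    if not cc.defined:
        return float("nan")
    return math.sqrt(
        (cc.rcc - 1 / 3) ** 2 + (cc.gcc - 1 / 3) ** 2 + (cc.bcc - 1 / 3) ** 2
    )


def image_statistics(image: ImageRecord, mask: ROIMask) -> dict:
    """One roistats row for a single exposure.

    ROI-scope channel means/SDs and chromatic coordinates, plus whole-image
    brightness, darkness, contrast, haze degree and deviation from grey.
    """
    roi_means = channel_means(image, mask)
    cc = chromatic_coordinates(roi_means)
    whole = channel_means(image, None)
    haze = _quality.haze_statistics(image)
    ts = image.timestamp
    return {
        "filename": image.source_path.rsplit("/", 1)[-1] if image.source_path else "",
        "date": ts.date(),
        "local_std_time": ts.strftime("%H:%M:%S"),
        "doy": ts.timetuple().tm_yday,
        "r_mean": roi_means.r_dn, "r_std": roi_means.r_sd,
        "g_mean": roi_means.g_dn, "g_std": roi_means.g_sd,
        "b_mean": roi_means.b_dn, "b_std": roi_means.b_sd,
        "rcc": cc.rcc, "gcc": cc.gcc, "bcc": cc.bcc,
        "brightness": haze.brightness,
        "darkness": haze.darkness,
        "contrast": haze.contrast,
        "haze_degree": haze.haze_degree,
        "delta": grey_deviation(whole),
        "qc_flag": 0,
    }


def build_roistats(
    images, roidef: ROIDefinition, masks: dict[str, ROIMask]
) -> RoiStatsTable:
    """Assemble the per-image color-statistics table (Data Record 3 analogue).

    ``masks`` maps mask filenames from the ROI definition to loaded masks;
    images whose timestamp falls outside every ROI interval are skipped.
    """
    rows = []
    for image in images:
        mask_path = roidef.mask_path_for(image.timestamp)
        if mask_path is None:
            continue
        rows.append(image_statistics(image, masks[mask_path]))
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["date", "local_std_time"], kind="stable").reset_index(
            drop=True
        )
    return RoiStatsTable(
        site=roidef.site, veg_type=roidef.veg_type, roi_id=roidef.roi_id, df=df
    )
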