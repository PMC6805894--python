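"""Readers and writers for camera imagery, ROI masks and data-record CSVs.

The on-disk layout mirrors the PhenoCam archive convention:

* images named ``<sitename>_YYYY_MM_DD_HHMMSS.jpg`` (timestamp is site-local
  clock time; no timezone conversion is ever applied),
* binary ROI masks as single-band 8-bit TIFFs in which pixel value 0 marks
  the region of interest and 255 marks excluded area,
* an ROI list CSV (``<site>_<veg>_<roi_id>_roi.csv``) giving the date
  interval over which each mask applies,
* derived products as comma-separated files with a ``#``-commented header
  block: per-image color statistics (``_roistats.csv``), 1-day/3-day summary
  series (``_1day.csv`` / ``_3day.csv``) and phenophase transition dates
  (``_transition_dates.csv``).

All writers and readers in this module round-trip losslessly: integer and
date fields bit-exactly, real-valued fields to 5 decimals.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "VEG_TYPES",
    "OPEN_END",
    "FormatError",
    "ValidationError",
    "FilenameParseError",
    "ImageRecord",
    "ROIMask",
    "ROIDefinition",
    "RoiStatsTable",
    "SummarySeries",
    "TransitionSet",
    "parse_image_filename",
    "format_image_filename",
    "read_image",
    "read_mask",
    "write_mask",
    "read_roi_definition",
    "write_roi_definition",
    "write_data_record",
    "read_data_record",
]

#: Two-letter vegetation-type codes accepted in ROI identifiers: agriculture,
#: deciduous broadleaf, deciduous needleleaf, evergreen broadleaf, evergreen
#: needleleaf, grassland, shrub, tundra, understory and wetland.
VEG_TYPES = frozenset({"AG", "DB", "DN", "EB", "EN", "GR", "SH", "TN", "UN", "WL"})

#: Sentinel end-datetime for an open-ended ROI interval (mask still active).
OPEN_END = _dt.datetime(9999, 1, 1, 0, 0, 0)


class FormatError(ValueError):
    """An input file is not in the expected physical format."""


class ValidationError(ValueError):
    """An input parses but violates a semantic invariant."""


class FilenameParseError(ValueError):
    """An image filename does not follow the archive naming convention."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ImageRecord:
    """One camera exposure: an 8-bit RGB pixel array plus provenance.

    ``pixels`` has shape (height, width, 3) with channels ordered red, green,
    blue; ``timestamp`` is site-local clock time.
    """

    pixels: np.ndarray
    timestamp: _dt.datetime
    site: str
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"image must be height x width x 3, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ROIMask:
    """A binary region-of-interest mask; ``mask`` is True inside the ROI."""

    mask: np.ndarray
    n_inside: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if self.n_inside != int(self.mask.sum()):
            raise ValidationError("n_inside inconsistent with mask")
        if self.n_inside == 0:
            raise ValidationError("empty ROI: no pixels inside the mask")

    @classmethod
    def from_array(cls, mask: np.ndarray) -> "ROIMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, n_inside=int(mask.sum()))


@dataclass
class ROIDefinition:
    """A vegetation-type ROI with the date interval each mask applies to.

    ``intervals`` is a chronologically ordered, non-overlapping list of
    ``(mask_path, start_datetime, end_datetime)``; an open-ended final
    interval carries :data:`OPEN_END`.
    """

    site: str
    veg_type: str
    roi_id: int
    intervals: list[tuple[str, _dt.datetime, _dt.datetime]]

    def __post_init__(self) -> None:
        if self.veg_type not in VEG_TYPES:
            raise ValidationError(
                f"unknown vegetation type {self.veg_type!r}; expected one of "
                + ", ".join(sorted(VEG_TYPES))
            )
        prev_end = None
        for maskfile, start, end in self.intervals:
            if end <= start:
                raise ValidationError(
                    f"interval for {maskfile!r} ends ({end}) before it starts ({start})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"interval for {maskfile!r} starting {start} overlaps the "
                    f"previous interval ending {prev_end}"
                )
            prev_end = end

    def mask_path_for(self, timestamp: _dt.datetime) -> str | None:
        """Mask file applying at ``timestamp``, or None if no interval covers it."""
        for maskfile, start, end in self.intervals:
            if start <= timestamp < end:
                return maskfile
        return None


@dataclass
class RoiStatsTable:
    """Per-image color statistics over an ROI (one row per exposure)."""

    site: str
    veg_type: str
    roi_id: int
    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    record_type = "roistats"
    int_columns = ("doy", "qc_flag")
    float_columns = (
        "r_mean", "r_std", "g_mean", "g_std", "b_mean", "b_std",
        "rcc", "gcc", "bcc",
        "brightness", "darkness", "contrast", "delta", "haze_degree",
    )
    date_columns = ("date",)


@dataclass
class SummarySeries:
    """A 1-day or 3-day aggregated greenness product on an even date grid."""

    site: str
    veg_type: str
    roi_id: int
    interval: int
    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    record_type = "summary"
    int_columns = ("year", "doy", "image_count", "outlier_flag")
    float_columns = (
        "midday_gcc", "gcc_90", "rcc_90", "bcc_90",
        "smooth_gcc", "ci_low", "ci_high",
    )
    date_columns = ("date",)

    def __post_init__(self) -> None:
        if self.interval not in (1, 3):
            raise ValidationError(f"interval must be 1 or 3, got {self.interval}")


@dataclass
class TransitionSet:
    """Per seasonal cycle, rising/falling 10/25/50% dates with uncertainties."""

    site: str
    veg_type: str
    roi_id: int
    interval: int
    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    record_type = "transitions"
    int_columns = ("cycle_id", "threshold_percent")
    float_columns = ("gcc_at_threshold",)
    date_columns = ("transition_date", "ci_low_date", "ci_high_date")


# ---------------------------------------------------------------------------
# Image filenames
# ---------------------------------------------------------------------------

_FILENAME_RE = re.compile(
    r"^(?P<site>.+?)_(?P<year>\d{4})_(?P<month>\d{2})_(?P<day>\d{2})"
    r"_(?P<hms>\d{6})\.(?P<ext>jpe?g|png|tiff?)$",
    re.IGNORECASE,
)


def parse_image_filename(filename: str) -> tuple[str, _dt.datetime]:
    """Parse ``<site>_YYYY_MM_DD_HHMMSS.<ext>`` into (site, local timestamp).

    The site name may itself contain underscores. Raises
    :class:`FilenameParseError` naming the offending component on bad input.
    """
    name = Path(filename).name
    m = _FILENAME_RE.match(name)
    if not m:
        raise FilenameParseError(
            f"{name!r} does not match <sitename>_YYYY_MM_DD_HHMMSS.<ext>"
        )
    year = int(m.group("year"))
    month = int(m.group("month"))
    day = int(m.group("day"))
    hms = m.group("hms")
    hour, minute, second = int(hms[:2]), int(hms[2:4]), int(hms[4:6])
    if not 1 <= month <= 12:
        raise FilenameParseError(f"{name!r}: month {month} out of range 1-12")
    if hour > 23:
        raise FilenameParseError(f"{name!r}: hour {hour} out of range 0-23")
    if minute > 59:
        raise FilenameParseError(f"{name!r}: minute {minute} out of range 0-59")
    if second > 59:
        raise FilenameParseError(f"{name!r}: second {second} out of range 0-59")
    try:
        ts = _dt.datetime(year, month, day, hour, minute, second)
    except ValueError as exc:  # e.g. day 31 in a 30-day month
        raise FilenameParseError(f"{name!r}: invalid day {day} ({exc})") from None
    return m.group("site"), ts


def format_image_filename(site: str, timestamp: _dt.datetime, ext: str = ".jpg") -> str:
    """Inverse of :func:`parse_image_filename` for valid inputs."""
    return f"{site}_{timestamp:%Y_%m_%d_%H%M%S}{ext}"


def read_image(path: str | Path) -> ImageRecord:
    """Read a JPEG/PNG exposure; site and timestamp come from the filename."""
    site, ts = parse_image_filename(str(path))
    with Image.open(path) as im:
        rgb = im.convert("RGB")
        pixels = np.asarray(rgb, dtype=np.uint8)
    return ImageRecord(pixels=pixels, timestamp=ts, site=site, source_path=str(path))


# ---------------------------------------------------------------------------
# ROI masks and definitions
# ---------------------------------------------------------------------------


def read_mask(path: str | Path, invert: bool = False) -> ROIMask:
    """Read a single-band 8-bit TIFF mask.

    Pixel value 0 marks the inside of the ROI and 255 the excluded area
    (excluded area is painted white by convention); ``invert=True`` flips
    the polarity for masks drawn the other way around.
    """
    with Image.open(path) as im:
        if im.mode != "L":
            raise FormatError(
                f"{path}: expected a single-band 8-bit mask, got mode {im.mode!r}"
            )
        arr = np.asarray(im, dtype=np.uint8)
    inside = (arr != 0) if invert else (arr == 0)
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValidationError(f"{path}: empty ROI (no inside pixels)")
    return ROIMask(mask=inside, n_inside=n_inside)


def write_mask(mask: np.ndarray | ROIMask, path: str | Path) -> None:
    """Write a boolean inside-ROI array as an 8-bit TIFF (0 inside, 255 outside)."""
    if isinstance(mask, ROIMask):
        mask = mask.mask
    arr = np.where(np.asarray(mask, dtype=bool), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def _parse_roi_csv_name(path: Path) -> tuple[str, str, int]:
    parts = path.stem.split("_")
    if len(parts) < 4 or parts[-1] != "roi":
        raise FormatError(
            f"{path.name!r} does not match <sitename>_<veg_type>_<roi_id>_roi.csv"
        )
    site = "_".join(parts[:-3])
    veg_type = parts[-3]
    try:
        roi_id = int(parts[-2])
    except ValueError:
        raise FormatError(f"{path.name!r}: ROI id {parts[-2]!r} is not an integer")
    return site, veg_type, roi_id


def read_roi_definition(path: str | Path) -> ROIDefinition:
    """Read an ROI list CSV (columns start_date, start_time, end_date,
    end_time, maskfile; '#' lines ignored). Site, vegetation type and ROI id
    are taken from the filename."""
    path = Path(path)
    site, veg_type, roi_id = _parse_roi_csv_name(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    required = {"start_date", "start_time", "end_date", "end_time", "maskfile"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    intervals: list[tuple[str, _dt.datetime, _dt.datetime]] = []
    for _, row in df.iterrows():
        start = _parse_roi_datetime(row["start_date"], row["start_time"])
        if start is None:
            raise ValidationError(f"{path}: interval with missing start date")
        end = _parse_roi_datetime(row["end_date"], row["end_time"])
        intervals.append((str(row["maskfile"]), start, end or OPEN_END))
    return ROIDefinition(site=site, veg_type=veg_type, roi_id=roi_id, intervals=intervals)


def _parse_roi_datetime(date_s: object, time_s: object) -> _dt.datetime | None:
    if date_s is None or (isinstance(date_s, float) and np.isnan(date_s)):
        return None
    date_s = str(date_s).strip()
    if date_s in ("", "NA", "9999-01-01"):
        return None if date_s != "9999-01-01" else OPEN_END
    time_s = "" if time_s is None else str(time_s).strip()
    if time_s in ("", "NA", "nan"):
        time_s = "00:00:00"
    return _dt.datetime.fromisoformat(f"{date_s} {time_s}")


def write_roi_definition(roidef: ROIDefinition, path: str | Path) -> None:
    path = Path(path)
    lines = [
        "#",
        f"# ROI list for {roidef.site} ({roidef.veg_type} {roidef.roi_id:04d})",
        "#",
        "start_date,start_time,end_date,end_time,maskfile",
    ]
    for maskfile, start, end in roidef.intervals:
        if end == OPEN_END:
            end_date, end_time = "9999-01-01", "00:00:00"
        else:
            end_date, end_time = f"{end:%Y-%m-%d}", f"{end:%H:%M:%S}"
        lines.append(
            f"{start:%Y-%m-%d},{start:%H:%M:%S},{end_date},{end_time},{maskfile}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Data-record CSVs (roistats / summary / transition products)
# ---------------------------------------------------------------------------

_RECORD_CLASSES = {
    "roistats": RoiStatsTable,
    "summary": SummarySeries,
    "transitions": TransitionSet,
}

_FLOAT_FMT = "{:.5f}"
_NA = "NA"


def write_data_record(
    table: RoiStatsTable | SummarySeries | TransitionSet, path: str | Path
) -> None:
    """Write a data-record CSV with a '#'-commented header block.

    Integer and date fields round-trip bit-exactly, real-valued fields to
    5 decimals; missing values are written as "NA".
    """
    path = Path(path)
    header = [
        "#",
        f"# record_type: {table.record_type}",
        f"# site: {table.site}",
        f"# veg_type: {table.veg_type}",
        f"# roi_id: {table.roi_id}",
    ]
    if hasattr(table, "interval"):
        header.append(f"# interval_days: {table.interval}")
    header.append(f"# created: {_dt.date.today().isoformat()}")
    header.append("#")

    df = table.df.copy()
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        s = df[col]
        if col in table.float_columns:
            out[col] = s.map(lambda v: _NA if pd.isna(v) else _FLOAT_FMT.format(v))
        elif col in table.int_columns:
            out[col] = s.map(lambda v: _NA if pd.isna(v) else str(int(v)))
        elif col in table.date_columns:
            out[col] = s.map(_format_date)
        else:
            out[col] = s.map(lambda v: _NA if pd.isna(v) else str(v))
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        out.to_csv(fh, index=False, lineterminator="\n")


def _format_date(v: object) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return _NA
    if isinstance(v, (pd.Timestamp, _dt.datetime)):
        return pd.Timestamp(v).date().isoformat()
    return str(v)


def read_data_record(path: str | Path):
    """Read any data-record CSV back into its container class."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    record_type = meta.get("record_type")
    if record_type not in _RECORD_CLASSES:
        raise FormatError(f"{path}: unknown or missing record_type {record_type!r}")
    cls = _RECORD_CLASSES[record_type]
    df = pd.read_csv(path, comment="#", na_values=[_NA], keep_default_na=False)
    for col in cls.date_columns:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.date
    for col in cls.int_columns:
        if col in df.columns and not df[col].isna().any():
            df[col] = df[col].astype(int)
    for col in cls.float_columns:
        if col in df.columns:
            df[col] = df[col].astype(float)
    kwargs = dict(
        site=meta.get("site", ""),
        veg_type=meta.get("veg_type", "UN"),
        roi_id=int(meta.get("roi_id", 0)),
        df=df,
    )
    if "interval_days" in meta and cls is not RoiStatsTable:
        kwargs["interval"] = int(meta["interval_days"])
    return cls(**kwargs)
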