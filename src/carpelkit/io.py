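"""File readers and writers for the pipeline's CSV/PNG interchange formats.

All CSVs are UTF-8 with '.' decimal separators; masks are single-channel
PNGs binarised at >127; images are 8-bit RGB (JPEG accepted on input, all
artifacts written as lossless PNG).  Readers validate schemas strictly and
report offending columns/lines rather than guessing.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .morphometry import MEASUREMENT_COLUMNS
from .synthetic import CarpelImage, TemperatureSeries

__all__ = [
    "SchemaError",
    "read_manifest",
    "write_manifest",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_masks",
    "read_temperature",
    "write_temperature",
    "read_measurements",
    "write_measurements",
]

MANIFEST_COLUMNS = ["image_id", "cultivar", "timepoint_days", "fixation",
                    "mm_per_px", "seed"]


class SchemaError(ValueError):
    """An input file violates its declared schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_manifest(path) -> pd.DataFrame:
    """Batch manifest: image_id, cultivar, timepoint_days, fixation,
    mm_per_px, seed."""
    df = pd.read_csv(path)
    _require_columns(df, MANIFEST_COLUMNS, path)
    if df["image_id"].duplicated().any():
        dups = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
        raise SchemaError(f"{path}: duplicate image_id(s) {dups}")
    scale = pd.to_numeric(df["mm_per_px"], errors="coerce")
    bad = df.index[scale.isna() | (scale <= 0)].tolist()
    if bad:
        lines = [i + 2 for i in bad]   # +1 header, +1 one-based
        raise SchemaError(f"{path}: non-numeric or non-positive mm_per_px "
                          f"on line(s) {lines}")
    df["mm_per_px"] = scale
    df["fixation"] = df["fixation"].astype(bool)
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_image(path, mm_per_px: float = 1.0, **meta) -> CarpelImage:
    px = np.asarray(iio.imread(path))
    if px.ndim == 2:
        raise SchemaError(f"{path}: grayscale image; RGB input required")
    if px.shape[2] == 4:
        px = px[:, :, :3]
    return CarpelImage(pixels=px.astype(np.uint8), mm_per_px=mm_per_px, **meta)


def write_image(image, path) -> None:
    px = image.pixels if isinstance(image, CarpelImage) else np.asarray(image)
    iio.imwrite(os.fspath(path), px.astype(np.uint8))


def read_mask(path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(os.fspath(path),
                (np.asarray(mask).astype(bool) * 255).astype(np.uint8))


def read_masks(directory, suffix: str = ".png") -> dict:
    """All masks in a directory keyed by file stem."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"mask directory {directory} does not exist")
    return {p.stem: read_mask(p) for p in sorted(directory.glob(f"*{suffix}"))}


def read_temperature(path) -> TemperatureSeries:
    """Temperature CSV with columns date, mean_temp_C; dates must be gap-free."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "mean_temp_C"], path)
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    vals = pd.to_numeric(df["mean_temp_C"], errors="coerce")
    if vals.isna().any():
        lines = [i + 2 for i in df.index[vals.isna()].tolist()]
        raise SchemaError(f"{path}: non-numeric mean_temp_C on line(s) {lines}")
    try:
        return TemperatureSeries(dates=dates, daily_mean=vals.to_numpy())
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_temperature(series: TemperatureSeries, path) -> None:
    pd.DataFrame({"date": series.dates.strftime("%Y-%m-%d"),
                  "mean_temp_C": series.daily_mean}).to_csv(path, index=False)


def write_measurements(df: pd.DataFrame, path) -> None:
    """Measurement CSV with the canonical (bit-exact) column header."""
    df.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"image_id": str, "cultivar": str, "flags": str})
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    for col in ("timepoint_days", "stigma_area_mm2", "ovary_diameter_mm",
                "mm_per_px"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["fixation"] = df["fixation"].astype(str).str.lower().isin(
        ("true", "1", "yes"))
    return df
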