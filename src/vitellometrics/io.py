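"""Readers and writers for the plain-text measurement formats.

All tabular inputs are CSV with documented headers (the original binary
instrument formats are out of scope); images are TIFF or PNG grayscale.
Bench units at the file boundary: mm, mL, g/cm^3, grams, mN, um, hours.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .morphometry import AxisLandmarkSeries, FibreImage
from .probe import ProbeTrace
from .scale import DEFAULT_STRIP_WIDTH_M, ScaleTrace

__all__ = [
    "read_puddle_table",
    "read_scale_trace",
    "read_probe_trace",
    "read_landmark_series",
    "read_fibre_image",
    "write_scale_trace",
    "write_probe_trace",
    "write_landmark_series",
]

DEFAULT_VOLUME_ML = 17.0
DEFAULT_DENSITY_G_CM3 = 1.035

PUDDLE_COLUMNS = [
    "sample_id", "day", "height_mm", "diameter_mm", "volume_ml",
    "density_g_per_cm3",
]
LANDMARK_COLUMNS = [
    "time_h", "somite_ref_x", "somite_ref_y", "post_end_x", "post_end_y",
    "pnt_left_x", "pnt_right_x", "somite_pairs",
]


def read_puddle_table(
    path,
    default_volume_ml: float = DEFAULT_VOLUME_ML,
    default_density: float = DEFAULT_DENSITY_G_CM3,
) -> pd.DataFrame:
    """Puddle-geometry table; missing volume/density filled from defaults."""
    table = pd.read_csv(path)
    missing = [c for c in ("sample_id", "day", "height_mm", "diameter_mm")
               if c not in table.columns]
    if missing:
        raise ValueError(f"puddle table {path} missing columns {missing}")
    if "volume_ml" not in table.columns:
        table["volume_ml"] = default_volume_ml
    if "density_g_per_cm3" not in table.columns:
        table["density_g_per_cm3"] = default_density
    table["volume_ml"] = table["volume_ml"].fillna(default_volume_ml)
    table["density_g_per_cm3"] = table["density_g_per_cm3"].fillna(default_density)
    return table[PUDDLE_COLUMNS]


def read_scale_trace(path, width_m: float = DEFAULT_STRIP_WIDTH_M) -> ScaleTrace:
    """Scale trace CSV with columns ``time_s, reading_g``."""
    df = pd.read_csv(path)
    return ScaleTrace(
        df["time_s"].to_numpy(float), df["reading_g"].to_numpy(float),
        width_m=width_m,
    )


def write_scale_trace(trace: ScaleTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "reading_g": trace.reading_g}).to_csv(
        path, index=False
    )


def read_probe_trace(path) -> ProbeTrace:
    """Probe trace CSV with columns ``time_s, position_mm, force_mN``."""
    df = pd.read_csv(path)
    return ProbeTrace(
        df["time_s"].to_numpy(float),
        df["position_mm"].to_numpy(float),
        df["force_mN"].to_numpy(float),
    )


def write_probe_trace(trace: ProbeTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "position_mm": trace.position_mm,
            "force_mN": trace.force_mN,
        }
    ).to_csv(path, index=False)


def read_landmark_series(path, pixel_size_um: float = 1.0) -> AxisLandmarkSeries:
    """Landmark CSV with the ``LANDMARK_COLUMNS`` schema (um, hours)."""
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark table {path} missing columns {missing}")
    return AxisLandmarkSeries(
        time_h=df["time_h"].to_numpy(float),
        somite_ref=df[["somite_ref_x", "somite_ref_y"]].to_numpy(float),
        post_end=df[["post_end_x", "post_end_y"]].to_numpy(float),
        pnt_left_x=df["pnt_left_x"].to_numpy(float),
        pnt_right_x=df["pnt_right_x"].to_numpy(float),
        somite_pairs=df["somite_pairs"].to_numpy(float),
        pixel_size_um=pixel_size_um,
    )


def write_landmark_series(series: AxisLandmarkSeries, path) -> None:
    pd.DataFrame(
        {
            "time_h": series.time_h,
            "somite_ref_x": series.somite_ref[:, 0],
            "somite_ref_y": series.somite_ref[:, 1],
            "post_end_x": series.post_end[:, 0],
            "post_end_y": series.post_end[:, 1],
            "pnt_left_x": series.pnt_left_x,
            "pnt_right_x": series.pnt_right_x,
            "somite_pairs": series.somite_pairs,
        }
    ).to_csv(path, index=False)


def read_fibre_image(path, pixel_size_um: float = 1.0) -> FibreImage:
    """Grayscale TIFF/PNG; integer images are rescaled to [0, 1]."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse RGB(A) stains to luminance
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / 255.0 if arr.max() <= 255 else arr / arr.max()
    return FibreImage(arr, pixel_size_um=pixel_size_um)
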