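"""Embryo phenotype metrics from landmark series and fibre-stain images.

Speeds are least-squares slopes over all frames rather than endpoint
differences, which is robust to per-frame landmark noise:

- elongation speed: slope of the Euclidean distance between a fixed
  reference somite and the posterior end of the body axis (um/h); negative
  values mean axis shortening;
- convergence speed: minus the slope of the posterior neural tube (pNT)
  width, measured between the outer neural-tube wall boundaries (um/h);
  negative values mean widening;
- segmentation speed: slope of the somite-pair count (pairs/h).

Fibre density: a glycoprotein-stain image is binarized with Otsu's
threshold (fibres white), square regions of interest are placed uniformly
at random fully inside the image, and the white-pixel fraction is averaged
across ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .errors import InsufficientDataError

__all__ = [
    "AxisLandmarkSeries",
    "FibreImage",
    "FibreDensityResult",
    "elongation_speed",
    "convergence_speed",
    "segmentation_speed",
    "fibre_density",
]


@dataclass(frozen=True)
class AxisLandmarkSeries:
    """Per-frame landmark record of one embryo.

    Positions in um (or any consistent length unit); times in hours.
    ``somite_ref`` and ``post_end`` are ``(n, 2)`` arrays of (x, y);
    ``pnt_left_x``/``pnt_right_x`` the outer neural-tube wall positions;
    ``somite_pairs`` the per-frame somite-pair count.
    """

    time_h: np.ndarray
    somite_ref: np.ndarray
    post_end: np.ndarray
    pnt_left_x: np.ndarray
    pnt_right_x: np.ndarray
    somite_pairs: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("time_h must be strictly increasing")
        for name in ("somite_ref", "post_end"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (t.size, 2):
                raise ValueError(f"{name} must have shape (n_frames, 2)")
            object.__setattr__(self, name, a)
        for name in ("pnt_left_x", "pnt_right_x", "somite_pairs"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != t.shape:
                raise ValueError(f"{name} must match time_h in length")
            object.__setattr__(self, name, a)
        object.__setattr__(self, "time_h", t)
        if np.any(self.pnt_right_x - self.pnt_left_x <= 0):
            raise ValueError("pNT width (right - left) must be positive")
        if np.any(np.diff(self.somite_pairs) < 0):
            raise ValueError("somite count must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.time_h.size

    @property
    def axis_length(self) -> np.ndarray:
        """Per-frame somite-to-posterior-end distance."""
        return np.hypot(*(self.post_end - self.somite_ref).T)

    @property
    def pnt_width(self) -> np.ndarray:
        return self.pnt_right_x - self.pnt_left_x


@dataclass(frozen=True)
class FibreImage:
    """2-D grayscale fibre-stain image with physical pixel size."""

    intensity: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self):
        a = np.asarray(self.intensity, dtype=float)
        if a.ndim != 2:
            raise ValueError("intensity must be 2-D")
        if not np.all(np.isfinite(a)):
            raise ValueError("intensity must be finite")
        object.__setattr__(self, "intensity", a)


@dataclass(frozen=True)
class FibreDensityResult:
    """Mean white-pixel fraction over random ROIs of a binarized image."""

    density: float
    degenerate: bool
    seed: int
    roi_origins: np.ndarray = field(repr=False)
    roi_size: int = 0


def _slope(t, y):
    if t.size < 2:
        raise InsufficientDataError("need >= 2 frames for a speed estimate")
    return float(np.polyfit(t, y, 1)[0])


def elongation_speed(series: AxisLandmarkSeries) -> float:
    """Least-squares slope of axis length vs time, um/h."""
    return _slope(series.time_h, series.axis_length)


def convergence_speed(series: AxisLandmarkSeries) -> float:
    """Minus the slope of pNT width vs time, um/h (positive = narrowing)."""
    return -_slope(series.time_h, series.pnt_width)


def segmentation_speed(series: AxisLandmarkSeries) -> float:
    """Slope of somite-pair count vs time, pairs/h."""
    return _slope(series.time_h, series.somite_pairs)


def fibre_density(
    image: FibreImage,
    n_rois: int = 10,
    roi_size: int = 128,
    seed: int = 0,
    fibres_dark: bool = False,
) -> FibreDensityResult:
    """Binarize (Otsu) and average the white fraction over random ROIs.

    Parameters
    ----------
    image : FibreImage
        Grayscale stain image; set ``fibres_dark=True`` if the stain renders
        fibres darker than background (the image is inverted before
        thresholding so fibres always end up white).
    n_rois, roi_size : int
        Number and side length (px) of square ROIs, placed uniformly at
        random fully inside the image (with replacement).  A ``roi_size``
        matching the whole image forces a single deterministic ROI.
    seed : int
        RNG seed for ROI placement, recorded in the result.

    A constant image has no Otsu threshold; by convention the density is 0
    with ``degenerate=True``.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    img = image.intensity
    if roi_size > min(img.shape):
        raise ValueError(
            f"roi_size {roi_size} exceeds image extent {min(img.shape)}"
        )
    if fibres_dark:
        img = -img
    if np.ptp(img) == 0:
        return FibreDensityResult(
            density=0.0,
            degenerate=True,
            seed=seed,
            roi_origins=np.empty((0, 2), dtype=int),
            roi_size=roi_size,
        )
    binary = img > threshold_otsu(img)

    rng = np.random.default_rng(seed)
    max_row = img.shape[0] - roi_size
    max_col = img.shape[1] - roi_size
    rows = rng.integers(0, max_row + 1, size=n_rois)
    cols = rng.integers(0, max_col + 1, size=n_rois)
    fractions = [
        binary[r : r + roi_size, c : c + roi_size].mean()
        for r, c in zip(rows, cols)
    ]
    return FibreDensityResult(
        density=float(np.mean(fractions)),
        degenerate=False,
        seed=seed,
        roi_origins=np.column_stack([rows, cols]),
        roi_size=roi_size,
    )
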