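"""Percentage-greenness (green chromatic coordinate) time series.

The vegetation signal throughout this package is the green chromatic
coordinate

    gcc = g / (r + g + b),

the share of the green channel in the total pixel intensity.  It is robust
against overall brightness changes (multiplying all channels by a constant
leaves it unchanged), which is what makes it usable on uncontrolled webcam
imagery.  Deciduous canopies trace a characteristic annual gcc curve — flat
in winter, a steep spring rise at leaf-out, a summer plateau, an autumn
decline — and everything downstream (the two optimality criteria, ROI
growth, clustering, date estimation) consumes gcc series on a day-of-year
axis.

Multiple frames falling on the same DOY are averaged into a single daily
value so that all downstream windows count calendar days.  Days without any
usable frame stay missing (NaN); nothing is interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .image_stack import ImageStack

__all__ = [
    "GreennessSeries",
    "pixel_greenness",
    "roi_series",
    "pixel_series_matrix",
    "series_from_matrix",
    "series_to_csv",
    "series_from_csv",
    "N_DOY",
]

#: Fixed day-of-year axis length; frames on DOY 366 are excluded with a warning.
N_DOY = 365


@dataclass
class GreennessSeries:
    """Daily %greenness values on the DOY 1..365 axis; NaN marks missing days.

    ``source_size`` is the pixel count of the region the series came from.
    """

    values: np.ndarray
    source_size: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (N_DOY,):
            raise ValueError(f"series must have shape ({N_DOY},), got {v.shape}")
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("non-missing %greenness values must lie in [0, 1]")
        self.values = v

    @property
    def n_obs(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    @property
    def observed_doys(self) -> np.ndarray:
        """1-based DOYs with a non-missing value."""
        return np.nonzero(~np.isnan(self.values))[0] + 1


def pixel_greenness(r, g, b):
    """Green chromatic coordinate ``g / (r + g + b)``.

    Accepts scalars or arrays of channel intensities in [0, 1]; returns NaN
    where the denominator is zero (a fully black pixel carries no colour
    information).
    """
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    for name, ch in (("r", r), ("g", g), ("b", b)):
        if ch.size and (np.nanmin(ch) < 0.0 or np.nanmax(ch) > 1.0):
            raise ValueError(f"channel {name} outside [0, 1]")
    denom = r + g + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, g / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def _frame_gcc(stack: ImageStack) -> np.ndarray:
    """Per-frame gcc images, shape (T, n1, n2), NaN at zero-intensity pixels."""
    arr = stack.pixel_array()
    denom = arr.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, arr[..., 1] / np.where(denom > 0, denom, 1.0), np.nan)


def _daily_mean(per_frame: np.ndarray, doys: np.ndarray) -> np.ndarray:
    """Average frame-level values sharing a DOY; output indexed by DOY 1..365.

    ``per_frame`` has shape (T, ...); the result has shape (365, ...).
    """
    out_shape = (N_DOY,) + per_frame.shape[1:]
    sums = np.zeros(out_shape)
    counts = np.zeros(out_shape)
    if np.any(doys > N_DOY):
        warnings.warn("frames on DOY 366 are excluded from the daily series")
    for t, doy in enumerate(doys):
        if doy > N_DOY:
            continue
        vals = per_frame[t]
        ok = ~np.isnan(vals)
        sums[doy - 1] += np.where(ok, vals, 0.0)
        counts[doy - 1] += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)


def roi_series(stack: ImageStack, mask: np.ndarray, aggregate: str = "mean_of_pixels") -> GreennessSeries:
    """Daily %greenness of a region: per frame the mean of pixel gcc over the
    mask (pixels without colour information dropped), then frames sharing a
    DOY averaged into one value.
    """
    if aggregate != "mean_of_pixels":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (stack.n1, stack.n2):
        raise ValueError(f"mask shape {mask.shape} does not match stack grid ({stack.n1}, {stack.n2})")
    size = int(mask.sum())
    if size < 1:
        raise ValueError("empty ROI mask")
    gcc = _frame_gcc(stack)[:, mask]  # (T, size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        per_frame = np.nanmean(gcc, axis=1)  # (T,)
    values = _daily_mean(per_frame[:, None], stack.doys)[:, 0]
    return GreennessSeries(values=values, source_size=size)


def pixel_series_matrix(stack: ImageStack) -> np.ndarray:
    """Daily gcc series of every pixel: an ``(n, 365)`` array, NaN = missing.

    Pixels are in row-major order.  ``series_from_matrix`` averages rows of
    this matrix into region series; for day-aligned missingness this equals
    :func:`roi_series` on the same mask.
    """
    if stack.T < 1:
        raise ValueError("stack holds no frames")
    gcc = _frame_gcc(stack).reshape(stack.T, stack.n)
    return _daily_mean(gcc, stack.doys).T


def series_from_matrix(matrix: np.ndarray, mask: np.ndarray) -> GreennessSeries:
    """Region series as the pixel-wise mean of per-pixel daily series."""
    flat = np.asarray(mask, dtype=bool).ravel()
    size = int(flat.sum())
    if size < 1:
        raise ValueError("empty ROI mask")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(matrix[flat], axis=0)
    return GreennessSeries(values=values, source_size=size)


def series_to_csv(series: GreennessSeries, path) -> None:
    obs = series.observed_doys
    df = pd.DataFrame(
        {
            "doy": obs,
            "greenness": series.values[obs - 1],
            "n_pixels": series.source_size,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def series_from_csv(path) -> GreennessSeries:
    df = pd.read_csv(path)
    values = np.full(N_DOY, np.nan)
    doys = df["doy"].to_numpy(dtype=int)
    if np.any((doys < 1) | (doys > N_DOY)):
        raise ValueError("doy column must lie in 1..365")
    values[doys - 1] = df["greenness"].to_numpy(dtype=float)
    size = int(df["n_pixels"].iloc[0]) if len(df) else 1
    return GreennessSeries(values=values, source_size=size)
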