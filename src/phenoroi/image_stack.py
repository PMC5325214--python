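"""Fixed-view camera image sequences as day-of-year indexed stacks.

A phenological webcam takes one or more pictures per day of the same motive
over (part of) a year.  This module reads such a directory of JPEG/PNG
frames — the filename convention is ``yyyymmdd_hhmmss.jpg`` — into an
:class:`ImageStack`: an ordered list of frames on a common pixel grid with
channels normalised to [0, 1] and a day-of-year (DOY) axis.  Boolean ROI
masks on that grid round-trip through 0/255 PNG files.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "Frame",
    "ImageStack",
    "load_stack",
    "pixel_count",
    "read_mask",
    "write_mask",
    "mask_size",
    "jaccard",
    "FILENAME_RE",
]

#: Timestamped filename dialect, e.g. ``20140501_134500.jpg``.
FILENAME_RE = re.compile(r"^(\d{4})(\d{2})(\d{2})_(\d{2})(\d{2})(\d{2})\.(jpe?g|png)$", re.IGNORECASE)


@dataclass
class Frame:
    """One camera image: a timestamp plus an ``(n1, n2, 3)`` RGB array in [0, 1]."""

    timestamp: datetime
    pixels: np.ndarray

    @property
    def doy(self) -> int:
        """Day of year in the frame's own calendar year (Feb 29 -> 60)."""
        return self.timestamp.timetuple().tm_yday

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"frame pixels must be (n1, n2, 3), got {px.shape}")
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise ValueError("channel intensities must lie in [0, 1]")
        self.pixels = px


@dataclass
class ImageStack:
    """T timestamped frames on a common ``n1 x n2`` grid, sorted by time.

    ``frames`` may be empty when only the geometry is declared (e.g. for
    pixel-count arithmetic on a camera whose archive is not at hand).
    """

    frames: List[Frame]
    n1: int
    n2: int

    def __post_init__(self) -> None:
        for f in self.frames:
            if f.pixels.shape[:2] != (self.n1, self.n2):
                raise ValueError(
                    f"inconsistent frame shape {f.pixels.shape[:2]} vs declared ({self.n1}, {self.n2})"
                )
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("frame timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return self.n1 * self.n2

    @property
    def T(self) -> int:
        return len(self.frames)

    @property
    def year(self) -> Optional[int]:
        return self.frames[0].timestamp.year if self.frames else None

    @property
    def doys(self) -> np.ndarray:
        return np.array([f.doy for f in self.frames], dtype=int)

    def pixel_array(self) -> np.ndarray:
        """All frames stacked to a ``(T, n1, n2, 3)`` array."""
        if not self.frames:
            raise ValueError("stack holds no frames")
        return np.stack([f.pixels for f in self.frames])


def _decode_image(path: Path) -> np.ndarray:
    """Decode one image file to a float RGB array in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: grayscale image replicated into three channels")
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError(f"{path.name}: float image not in [0, 1]")
    return arr


def _parse_timestamp(name: str) -> Optional[datetime]:
    m = FILENAME_RE.match(name)
    if m is None:
        return None
    y, mo, d, h, mi, s = (int(g) for g in m.groups()[:6])
    try:
        return datetime(y, mo, d, h, mi, s)
    except ValueError:
        return None


def _read_manifest(manifest: Path) -> List[Tuple[str, datetime]]:
    entries = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append((row["filename"], datetime.fromisoformat(row["datetime"])))
    return entries


def load_stack(
    directory,
    crop_top_rows: int = 0,
    hour_filter: Optional[int] = None,
    manifest=None,
) -> ImageStack:
    """Read a directory of timestamped camera images into an :class:`ImageStack`.

    Parameters
    ----------
    directory : path
        Directory holding JPEG/PNG frames named ``yyyymmdd_hhmmss.(jpg|png)``.
    crop_top_rows : int
        Number of top pixel rows to discard from every frame (webcams often
        burn a time stamp or location banner into the top of the image).
    hour_filter : int, optional
        Keep only frames whose hour-of-day equals this value.
    manifest : path, optional
        CSV with columns ``filename,datetime`` (ISO format) for archives whose
        filenames do not follow the timestamp dialect.
    """
    directory = Path(directory)
    if crop_top_rows < 0:
        raise ValueError("crop_top_rows must be non-negative")

    if manifest is not None:
        named = _read_manifest(Path(manifest))
    else:
        named = []
        for p in sorted(directory.iterdir()):
            if not p.is_file():
                continue
            ts = _parse_timestamp(p.name)
            if ts is None:
                warnings.warn(f"skipping {p.name}: filename does not parse as yyyymmdd_hhmmss")
                continue
            named.append((p.name, ts))

    frames: List[Frame] = []
    shape: Optional[Tuple[int, int]] = None
    for fname, ts in sorted(named, key=lambda e: e[1]):
        if hour_filter is not None and ts.hour != hour_filter:
            continue
        path = directory / fname
        try:
            arr = _decode_image(path)
        except (UnidentifiedImageError, OSError) as exc:
            warnings.warn(f"skipping {fname}: not decodable ({exc})")
            continue
        if crop_top_rows >= arr.shape[0]:
            raise ValueError(f"crop_top_rows={crop_top_rows} removes the whole {arr.shape[0]}-row image")
        arr = arr[crop_top_rows:]
        if shape is None:
            shape = arr.shape[:2]
        elif arr.shape[:2] != shape:
            raise ValueError(f"inconsistent image resolutions: {shape} vs {arr.shape[:2]} ({fname})")
        frames.append(Frame(timestamp=ts, pixels=arr))

    if not frames:
        raise ValueError(f"no loadable frames found in {directory}")
    assert shape is not None
    return ImageStack(frames=frames, n1=shape[0], n2=shape[1])


def pixel_count(stack: ImageStack) -> int:
    """Number of pixels per frame, ``n = n1 * n2``."""
    return stack.n1 * stack.n2


def read_mask(path, stack: Optional[ImageStack] = None) -> np.ndarray:
    """Read a boolean ROI mask from a single-channel 0/255 (or 0/1) PNG."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    values = np.unique(arr)
    if not np.all(np.isin(values, [0, 1, 255])):
        raise ValueError(f"mask image must be binary (0/255 or 0/1), found values {values[:10]}")
    mask = arr > 0
    if stack is not None and mask.shape != (stack.n1, stack.n2):
        raise ValueError(f"mask shape {mask.shape} does not match stack grid ({stack.n1}, {stack.n2})")
    return mask


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    mask = np.asarray(mask, dtype=bool)
    Image.fromarray((mask * np.uint8(255))).save(path)


def mask_size(mask: np.ndarray) -> int:
    return int(np.asarray(mask, dtype=bool).sum())


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
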