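"""Ground-truthed synthetic camera scenes for testing the ROI pipeline.

A scene is a pixel grid partitioned into labelled regions — deciduous
canopy, evergreen conifer, grassland, sky, building — each following its
own seasonal %greenness profile.  The deciduous profile is an affine copy
of the piecewise-linear template family with known spring-onset ``a`` and
autumn-end ``b``, so recovery of the planted region and its dates can be
scored exactly.  Channels are constructed so the green chromatic coordinate
inverts the profile exactly at zero noise:

    g = gcc * s,    r = b = (1 - gcc) * s / 2,

with s the region's base brightness, hence g / (r + g + b) = gcc.  On top,
iid Gaussian channel noise (clipped to [0, 1]) emulates sensor and
illumination variation.  Everything is deterministic under the scene seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from PIL import Image

from .criteria import make_template
from .greenness import N_DOY
from .image_stack import Frame, ImageStack, write_mask

__all__ = [
    "DeciduousProfile",
    "EvergreenProfile",
    "GrassProfile",
    "SkyProfile",
    "ConstantProfile",
    "RegionSpec",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "default_scene",
    "write_scene_images",
    "save_truth",
]


@dataclass(frozen=True)
class DeciduousProfile:
    """Deciduous canopy: winter floor ``low`` rising to ``high`` along the
    template with spring onset ``a`` and autumn end ``b``."""

    a: int = 105
    b: int = 308
    c: Optional[int] = None
    d: Optional[int] = None
    e: Optional[int] = None
    plateau_level: float = 0.7
    low: float = 0.25
    high: float = 0.60

    def gcc(self, doys: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        tpl = make_template(self.a, self.b, self.c, self.d, self.e, self.plateau_level)
        return self.low + (self.high - self.low) * tpl.values[doys - 1]


@dataclass(frozen=True)
class EvergreenProfile:
    """Near-constant conifer greenness with a small May-shoot bump."""

    level: float = 0.42
    bump: float = 0.05
    bump_start: int = 120
    bump_end: int = 170

    def gcc(self, doys: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        vals = np.full(doys.shape, self.level, dtype=float)
        vals[(doys >= self.bump_start) & (doys <= self.bump_end)] += self.bump
        return vals


@dataclass(frozen=True)
class GrassProfile:
    """Grassland: a flatter, lower-amplitude seasonal curve."""

    a: int = 90
    b: int = 290
    plateau_level: float = 0.9
    low: float = 0.30
    high: float = 0.45

    def gcc(self, doys: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        tpl = make_template(self.a, self.b, plateau_level=self.plateau_level)
        return self.low + (self.high - self.low) * tpl.values[doys - 1]


@dataclass(frozen=True)
class SkyProfile:
    """Sky: constant level plus daily illumination jitter (no seasonality)."""

    level: float = 0.30
    jitter_sd: float = 0.01

    def gcc(self, doys: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        vals = self.level + rng.normal(0.0, self.jitter_sd, size=doys.shape)
        return np.clip(vals, 0.0, 1.0)


@dataclass(frozen=True)
class ConstantProfile:
    """Buildings, roads, rock: no temporal variation at all."""

    level: float = 0.33

    def gcc(self, doys: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return np.full(doys.shape, self.level, dtype=float)


Profile = Union[DeciduousProfile, EvergreenProfile, GrassProfile, SkyProfile, ConstantProfile]


@dataclass
class RegionSpec:
    name: str
    mask: np.ndarray  # boolean (n1, n2)
    profile: Profile
    base_brightness: float = 0.9


@dataclass
class SceneSpec:
    n1: int
    n2: int
    doys: np.ndarray  # strictly increasing, within 1..365
    regions: List[RegionSpec]
    noise_sd: float = 0.02
    seed: int = 0
    year: int = 2014

    def __post_init__(self) -> None:
        d = np.asarray(self.doys, dtype=int)
        if d.size == 0 or np.any((d < 1) | (d > N_DOY)) or np.any(np.diff(d) <= 0):
            raise ValueError("doys must be strictly increasing within 1..365")
        self.doys = d
        cover = np.zeros((self.n1, self.n2), dtype=int)
        for reg in self.regions:
            if reg.mask.shape != (self.n1, self.n2):
                raise ValueError(f"region {reg.name}: mask shape mismatch")
            cover += reg.mask
        if np.any(cover > 1):
            raise ValueError("region masks overlap")
        if np.any(cover == 0):
            raise ValueError("region masks do not cover the grid")


@dataclass
class GroundTruth:
    masks: Dict[str, np.ndarray]
    profiles: Dict[str, Profile]


def render_scene(spec: SceneSpec) -> Tuple[ImageStack, GroundTruth]:
    """Render a scene spec into an image stack plus its ground truth.

    Randomness (sky jitter, then channel noise) is drawn in a fixed order
    from the spec seed, so rendering the same spec twice is bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    doys = spec.doys
    T = doys.size
    profiles = {reg.name: reg.profile.gcc(doys, rng) for reg in spec.regions}

    stack_arr = np.zeros((T, spec.n1, spec.n2, 3))
    for reg in spec.regions:
        gcc = profiles[reg.name]  # (T,)
        s = reg.base_brightness
        g = gcc * s
        rb = (1.0 - gcc) * s / 2.0
        stack_arr[:, reg.mask, 0] = rb[:, None]
        stack_arr[:, reg.mask, 1] = g[:, None]
        stack_arr[:, reg.mask, 2] = rb[:, None]
    if spec.noise_sd > 0:
        stack_arr += rng.normal(0.0, spec.noise_sd, size=stack_arr.shape)
        np.clip(stack_arr, 0.0, 1.0, out=stack_arr)

    origin = datetime(spec.year, 1, 1, 12, 0, 0)
    frames = [
        Frame(timestamp=origin + timedelta(days=int(doy) - 1), pixels=stack_arr[i])
        for i, doy in enumerate(doys)
    ]
    stack = ImageStack(frames=frames, n1=spec.n1, n2=spec.n2)
    truth = GroundTruth(
        masks={reg.name: reg.mask.copy() for reg in spec.regions},
        profiles={reg.name: reg.profile for reg in spec.regions},
    )
    return stack, truth


def default_scene(
    seed: int = 0,
    n1: int = 64,
    n2: int = 64,
    doys: Optional[Sequence[int]] = None,
    noise_sd: float = 0.02,
    year: int = 2014,
) -> SceneSpec:
    """The standard four-region test scene on a 64 x 64 grid, daily frames.

    Sky band on top, an evergreen strip and a large deciduous block
    (a=105, b=308) in the middle, a building band at the bottom.
    """
    if doys is None:
        doys = np.arange(1, N_DOY + 1)

    def rect(r0, r1, c0, c1):
        m = np.zeros((n1, n2), dtype=bool)
        m[r0:r1, c0:c1] = True
        return m

    rows_sky = n1 // 4
    rows_bld = n1 - n1 // 4
    cols_ever = n2 // 4
    regions = [
        RegionSpec("sky", rect(0, rows_sky, 0, n2), SkyProfile()),
        RegionSpec("evergreen", rect(rows_sky, rows_bld, 0, cols_ever), EvergreenProfile()),
        RegionSpec("deciduous", rect(rows_sky, rows_bld, cols_ever, n2), DeciduousProfile()),
        RegionSpec("building", rect(rows_bld, n1, 0, n2), ConstantProfile()),
    ]
    return SceneSpec(n1=n1, n2=n2, doys=np.asarray(doys), regions=regions,
                     noise_sd=noise_sd, seed=seed, year=year)


def write_scene_images(stack: ImageStack, directory) -> List[Path]:
    """Write one 8-bit PNG per frame, named ``yyyymmdd_hhmmss.png``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in stack.frames:
        name = frame.timestamp.strftime("%Y%m%d_%H%M%S") + ".png"
        arr = np.round(frame.pixels * 255.0).astype(np.uint8)
        path = directory / name
        Image.fromarray(arr).save(path)
        paths.append(path)
    return paths


def save_truth(truth: GroundTruth, directory) -> None:
    """Persist ground truth: one 0/255 mask PNG per region + a params CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "truth_params.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region", "profile", "params"])
        for name, profile in truth.profiles.items():
            write_mask(truth.masks[name], directory / f"mask_{name}.png")
            writer.writerow([name, type(profile).__name__, repr(profile)])
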