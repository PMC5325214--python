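"""Shared fixtures: rendered synthetic scenes and small random stacks."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from phenoroi.image_stack import Frame, ImageStack
from phenoroi.synthetic_scenes import default_scene, render_scene


@pytest.fixture(scope="session")
def scene():
    """The default 64x64 four-region scene (noise sd 0.02, seed 1)."""
    spec = default_scene(seed=1)
    stack, truth = render_scene(spec)
    return stack, truth, spec


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free variant of the default scene for analytic checks."""
    spec = default_scene(seed=1, noise_sd=0.0)
    stack, truth = render_scene(spec)
    return stack, truth, spec


def random_stack(
    n1: int = 8,
    n2: int = 8,
    T: int = 12,
    seed: int = 0,
    year: int = 2014,
    duplicate_doys: bool = False,
) -> ImageStack:
    """A small stack of uniformly random (strictly positive) RGB frames."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(T):
        ts = datetime(year, 1, 1, 12, 0, 0) + timedelta(days=i)
        if duplicate_doys:
            ts = datetime(year, 1, 1, 8, 0, 0) + timedelta(days=i // 2, hours=4 * (i % 2))
        pixels = rng.uniform(0.05, 1.0, size=(n1, n2, 3))
        frames.append(Frame(timestamp=ts, pixels=pixels))
    return ImageStack(frames=frames, n1=n1, n2=n2)
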