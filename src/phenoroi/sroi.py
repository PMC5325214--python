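"""Semi-supervised ROI growth from pinprick seed pixels.

Instead of drawing a full expert ROI, the user (or a random generator) sets
a tiny "pinprick" square — e.g. 6 x 6 pixels — in the crown of a deciduous
tree.  The pinprick's mean %greenness series is correlated, pixel by pixel,
with every pixel's own daily series, giving a correlation image.
Thresholding that image at a level tau grows the pinprick into a candidate
ROI (the set of pixels whose seasonality tracks the seed); a grid of
thresholds yields nested candidates, and the best (pinprick, tau)
combination under OC1 or OC2 is the final sROI.

The automated variant drops q pinpricks at random positions and optimises
over all q x m (pinprick, threshold) candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import criteria
from .criteria import OC1Result, OC2Result, TemplateBank
from .greenness import GreennessSeries, pixel_series_matrix, series_from_matrix
from .image_stack import ImageStack

__all__ = [
    "Pinprick",
    "CorrelationImage",
    "CandidateROI",
    "default_thresholds",
    "default_min_size",
    "correlation_image",
    "threshold_candidates",
    "sroi_semi",
    "sroi_auto",
]

log = logging.getLogger(__name__)

DEFAULT_SIDE = 6


@dataclass(frozen=True)
class Pinprick:
    """A small seed square: centre (row, col) and side length in pixels."""

    center: Tuple[int, int]
    side: int = DEFAULT_SIDE

    def mask(self, n1: int, n2: int) -> np.ndarray:
        r0 = self.center[0] - self.side // 2
        c0 = self.center[1] - self.side // 2
        if r0 < 0 or c0 < 0 or r0 + self.side > n1 or c0 + self.side > n2:
            raise ValueError(f"pinprick {self.center} (side {self.side}) not fully inside {n1}x{n2} grid")
        m = np.zeros((n1, n2), dtype=bool)
        m[r0 : r0 + self.side, c0 : c0 + self.side] = True
        return m


@dataclass
class CorrelationImage:
    """Per-pixel Pearson correlation with a pinprick series; NaN = undefined."""

    r: np.ndarray  # (n1, n2)


@dataclass
class CandidateROI:
    """A candidate mask plus where it came from and how it scored."""

    mask: np.ndarray
    provenance: dict
    oc1: Optional[OC1Result] = None
    oc2: Optional[OC2Result] = None
    score: Optional[float] = None

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def default_thresholds() -> np.ndarray:
    """tau in {0.05, 0.10, ..., 0.95} (m = 19)."""
    return np.round(np.arange(0.05, 0.951, 0.05), 2)


def default_min_size(n_pixels: int) -> int:
    """Smallest admissible ROI: max(25 px, 0.05% of the image)."""
    return max(25, math.ceil(5e-4 * n_pixels))


def _pearson_rows(matrix: np.ndarray, y: np.ndarray, min_obs: int = 3) -> np.ndarray:
    """Pearson correlation of every row of ``matrix`` (n, 365) with ``y``
    (365,), NaN-aware: each row uses the DOYs observed in both."""
    valid = ~np.isnan(matrix) & ~np.isnan(y)[None, :]
    m = valid.sum(axis=1).astype(np.float64)
    x0 = np.where(valid, matrix, 0.0)
    y0 = np.where(valid, y[None, :], 0.0)
    sx = x0.sum(axis=1)
    sy = y0.sum(axis=1)
    sxx = (x0 * x0).sum(axis=1)
    syy = (y0 * y0).sum(axis=1)
    sxy = (x0 * y0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = np.where(m > 0, m, 1.0)
        cov = sxy - sx * sy / mm
        vx = sxx - sx * sx / mm
        vy = syy - sy * sy / mm
        r = cov / np.sqrt(vx * vy)
    bad = (m < min_obs) | (vx <= 0) | (vy <= 0)
    return np.where(bad, np.nan, np.clip(r, -1.0, 1.0))


def correlation_image(
    stack: ImageStack,
    pinprick: Pinprick,
    matrix: Optional[np.ndarray] = None,
) -> CorrelationImage:
    """Correlate every pixel's daily gcc series with the pinprick's.

    ``matrix`` may pass a precomputed :func:`pixel_series_matrix` to avoid
    recomputation across pinpricks.
    """
    if matrix is None:
        matrix = pixel_series_matrix(stack)
    pin_mask = pinprick.mask(stack.n1, stack.n2)
    pin_series = series_from_matrix(matrix, pin_mask)
    y = pin_series.values
    obs = ~np.isnan(y)
    if obs.sum() < 3 or np.nanmax(y) - np.nanmin(y) <= 0.0:
        raise ValueError("degenerate pinprick: series has <3 observed DOYs or zero variance")
    r = _pearson_rows(matrix, y).reshape(stack.n1, stack.n2)
    return CorrelationImage(r=r)


def threshold_candidates(
    cimg: CorrelationImage,
    thresholds: Sequence[float],
    min_size: int = 0,
) -> List[CandidateROI]:
    """One candidate mask per threshold: pixels with r >= tau.

    Masks are nested (higher tau, smaller mask).  Candidates below
    ``min_size`` are dropped with a log note.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any((thresholds < 0.0) | (thresholds >= 1.0)):
        raise ValueError("thresholds must lie in [0, 1)")
    out = []
    with np.errstate(invalid="ignore"):
        for tau in thresholds:
            mask = cimg.r >= tau  # NaN compares False
            size = int(mask.sum())
            if size < max(min_size, 1):  # empty masks are never candidates
                log.info("dropping threshold tau=%.2f: mask size %d < min_size %d", tau, size, min_size)
                continue
            out.append(CandidateROI(mask=mask, provenance={"tau": float(tau)}))
    return out


def _score_candidates(
    candidates: List[CandidateROI],
    matrix: np.ndarray,
    criterion: str,
    bank: Optional[TemplateBank],
) -> List[CandidateROI]:
    """Attach the chosen criterion score to each candidate; unscoreable
    candidates (degenerate series) are dropped with a log note."""
    if criterion not in ("oc1", "oc2"):
        raise ValueError(f"criterion must be 'oc1' or 'oc2', got {criterion!r}")
    if criterion == "oc2" and bank is None:
        bank = criteria.default_bank()
    kept = []
    for cand in candidates:
        series = series_from_matrix(matrix, cand.mask)
        try:
            if criterion == "oc1":
                cand.oc1 = criteria.oc1(series)
                cand.score = cand.oc1.f_max
            else:
                cand.oc2 = criteria.oc2(series, bank)
                cand.score = cand.oc2.rho_max
        except ValueError as exc:
            log.info("skipping candidate %s: %s", cand.provenance, exc)
            continue
        kept.append(cand)
    return kept


def _best_candidate(candidates: List[CandidateROI]) -> CandidateROI:
    # tie-break: larger mask, then smaller tau
    return max(
        candidates,
        key=lambda c: (c.score, c.size, -c.provenance.get("tau", 0.0)),
    )


def sroi_semi(
    stack: ImageStack,
    pinprick: Pinprick,
    thresholds: Optional[Sequence[float]] = None,
    criterion: str = "oc2",
    min_size: Optional[int] = None,
    bank: Optional[TemplateBank] = None,
    matrix: Optional[np.ndarray] = None,
) -> CandidateROI:
    """Semi-automated sROI: one expert pinprick, optimise the threshold."""
    if thresholds is None:
        thresholds = default_thresholds()
    if min_size is None:
        min_size = default_min_size(stack.n)
    if matrix is None:
        matrix = pixel_series_matrix(stack)
    cimg = correlation_image(stack, pinprick, matrix=matrix)
    candidates = threshold_candidates(cimg, thresholds, min_size=min_size)
    if not candidates:
        raise ValueError(f"all thresholded candidates fall below min_size={min_size}; lower min_size")
    for cand in candidates:
        cand.provenance["pinprick"] = pinprick.center
    scored = _score_candidates(candidates, matrix, criterion, bank)
    if not scored:
        raise ValueError("no candidate produced a scoreable %greenness series")
    return _best_candidate(scored)


def _random_pinpricks(stack: ImageStack, q: int, side: int, rng: np.random.Generator) -> List[Pinprick]:
    """Draw q pinprick centres without replacement on a coarse grid
    (stride = side) so random seeds do not pile onto near-duplicates."""
    rows = np.arange(0, stack.n1 - side + 1, side)
    cols = np.arange(0, stack.n2 - side + 1, side)
    if rows.size == 0 or cols.size == 0:
        raise ValueError(f"image {stack.n1}x{stack.n2} too small for side-{side} pinpricks")
    cells = [(int(r + side // 2), int(c + side // 2)) for r in rows for c in cols]
    picks = rng.choice(len(cells), size=min(q, len(cells)), replace=False)
    return [Pinprick(center=cells[i], side=side) for i in picks]


def sroi_auto(
    stack: ImageStack,
    q: int,
    thresholds: Optional[Sequence[float]] = None,
    criterion: str = "oc2",
    min_size: Optional[int] = None,
    seed: int = 0,
    side: int = DEFAULT_SIDE,
    bank: Optional[TemplateBank] = None,
    full_output: bool = False,
):
    """Fully automated sROI: q random pinpricks x m thresholds, global best.

    Degenerate pinpricks (constant series) are skipped with a log note.
    With ``full_output=True`` also returns the list of scored candidates.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if thresholds is None:
        thresholds = default_thresholds()
    if min_size is None:
        min_size = default_min_size(stack.n)
    rng = np.random.default_rng(seed)
    matrix = pixel_series_matrix(stack)
    if criterion == "oc2" and bank is None:
        bank = criteria.default_bank()

    scored: List[CandidateROI] = []
    n_usable = 0
    for pin in _random_pinpricks(stack, q, side, rng):
        try:
            cimg = correlation_image(stack, pin, matrix=matrix)
        except ValueError as exc:
            log.info("skipping pinprick %s: %s", pin.center, exc)
            continue
        n_usable += 1
        candidates = threshold_candidates(cimg, thresholds, min_size=min_size)
        for cand in candidates:
            cand.provenance["pinprick"] = pin.center
        scored.extend(_score_candidates(candidates, matrix, criterion, bank))
    if n_usable == 0:
        raise ValueError("all random pinpricks were degenerate (constant series)")
    if not scored:
        raise ValueError(f"no (pinprick, threshold) candidate survived min_size={min_size}")
    best = _best_candidate(scored)
    if full_output:
        return best, scored
    return best
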