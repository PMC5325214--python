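"""Phenological onset dates from a selected ROI's %greenness series.

Two estimators are provided.  The template route reads rough start-of-season
(SOS) and end-of-season (EOS2) dates directly off the winning OC2 template:
its spring-onset knot a and autumn-end knot b.  The segmentation route fits
the full annual series with a multiple-change-point model — piecewise-linear
regimes whose intercept and slope change at each change day — solved exactly
by dynamic programming, and labels the change DOYs, in ascending order, SOS,
MAX (peak greenness), EOS1 (start of autumn colouring) and EOS2 (end of
colouring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .criteria import ZERO_RSS_RTOL, OC2Result, _segment_rss
from .greenness import GreennessSeries

__all__ = ["PhenoDates", "dates_from_template", "segment_dates"]

_LABELS = ("sos", "max", "eos1", "eos2")


@dataclass
class PhenoDates:
    """SOS/MAX/EOS1/EOS2 day-of-year estimates; absent dates are None."""

    sos: Optional[int]
    max: Optional[int]
    eos1: Optional[int]
    eos2: Optional[int]
    method: str

    def __post_init__(self) -> None:
        present = [d for d in (self.sos, self.max, self.eos1, self.eos2) if d is not None]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError(f"dates must be ordered sos <= max <= eos1 <= eos2, got {present}")
        if self.sos is not None and self.eos2 is not None and self.sos >= self.eos2:
            raise ValueError("sos must precede eos2")


def dates_from_template(oc2_result: OC2Result) -> PhenoDates:
    """Rough SOS/EOS2 from the best-correlated template's (a, b) knots."""
    return PhenoDates(sos=oc2_result.a_hat, max=None, eos1=None, eos2=oc2_result.b_hat,
                      method="template")


def _segment_cost_matrix(t: np.ndarray, y: np.ndarray, min_seg: int) -> np.ndarray:
    """cost[i, j] = RSS of a least-squares line through observations i..j-1;
    +inf for segments shorter than ``min_seg``."""
    tc = t - t.mean()
    yc = y - y.mean()

    def cum(a):
        return np.concatenate([[0.0], np.cumsum(a)])

    st, sy = cum(tc), cum(yc)
    stt, sty, syy = cum(tc * tc), cum(tc * yc), cum(yc * yc)
    i = np.arange(t.size + 1)[:, None]
    j = np.arange(t.size + 1)[None, :]
    m = (j - i).astype(float)
    cost = _segment_rss(m, st[j] - st[i], sy[j] - sy[i], stt[j] - stt[i],
                        sty[j] - sty[i], syy[j] - syy[i])
    cost[m < min_seg] = np.inf
    return cost


def _optimal_partition(cost: np.ndarray, k_max: int, tol: float):
    """Dynamic-programming optimal partitioning into up to ``k_max`` + 1
    piecewise-linear segments.

    Returns (total_rss, splits) per number of change points K = 0..k_max,
    where splits are the observation indices starting each new regime.
    Ties in total RSS (within ``tol``) break toward the earliest splits.
    """
    n1 = cost.shape[0]
    d = np.full((k_max + 1, n1), np.inf)
    back = np.zeros((k_max + 1, n1), dtype=int)
    d[0] = cost[0]
    for k in range(1, k_max + 1):
        for j in range(n1):
            cand = d[k - 1, : j + 1] + cost[: j + 1, j]
            finite = np.isfinite(cand)
            if not np.any(finite):
                continue
            mn = np.min(cand[finite])
            i = int(np.argmax(cand <= mn + tol))  # first index within tol of the optimum
            d[k, j] = cand[i]
            back[k, j] = i

    totals = d[:, -1]
    splits_per_k: List[List[int]] = []
    for k in range(k_max + 1):
        splits: List[int] = []
        j = n1 - 1
        for kk in range(k, 0, -1):
            i = int(back[kk, j])
            splits.append(i)
            j = i
        splits_per_k.append(sorted(splits))
    return totals, splits_per_k


def segment_dates(
    series: GreennessSeries,
    max_changepoints: int = 4,
    f_floor: float = 20.0,
    min_side: int = 5,
) -> PhenoDates:
    """Multiple-change-point segmentation of the annual series.

    The observed series is partitioned into piecewise-linear regimes
    (intercept and slope free per regime, each regime at least ``min_side``
    observations) minimising the total residual sum of squares, solved
    exactly by dynamic programming for every change-point count up to
    ``max_changepoints``.  The count is chosen stepwise: the K-th change
    point is accepted when its supF-style statistic

        F_K = ((RSS_{K-1} - RSS_K) / 2) / (RSS_K / (n - 2(K+1)))

    exceeds ``f_floor`` (stops spurious splits in flat winter stretches);
    an exact fit (RSS_K ~ 0) counts as +inf unless the previous fit was
    already exact.  Each change DOY is the first observed day of its new
    regime; ties in RSS break toward the earliest days.  Fewer change
    points than labels leaves the trailing labels absent with a warning.
    """
    obs = np.nonzero(~np.isnan(series.values))[0]
    t = (obs + 1).astype(float)
    y = series.values[obs]
    n = t.size
    if n < 30:
        raise ValueError(f"segmentation needs at least 30 observed DOYs, got {n}")

    cost = _segment_cost_matrix(t, y, min_seg=min_side)
    yc = y - y.mean()
    tol = ZERO_RSS_RTOL * max(1.0, float((yc * yc).sum()))
    totals, splits_per_k = _optimal_partition(cost, max_changepoints, tol)

    chosen = 0
    for k in range(1, max_changepoints + 1):
        rss_prev, rss_k = totals[k - 1], totals[k]
        if not np.isfinite(rss_k):
            break
        dof = n - 2 * (k + 1)
        if dof <= 0:
            break
        if rss_k <= tol:
            f = 0.0 if rss_prev <= tol else np.inf
        else:
            f = ((rss_prev - rss_k) / 2.0) / (rss_k / dof)
        if f < f_floor:
            break
        chosen = k

    changepoints = [int(t[i]) for i in splits_per_k[chosen]]
    if len(changepoints) < len(_LABELS):
        warnings.warn(
            f"found {len(changepoints)} change points; labels "
            f"{_LABELS[len(changepoints):]} left absent"
        )
    dates = dict(zip(_LABELS, changepoints))
    return PhenoDates(
        sos=dates.get("sos"),
        max=dates.get("max"),
        eos1=dates.get("eos1"),
        eos2=dates.get("eos2"),
        method="segmentation",
    )
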