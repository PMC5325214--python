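"""Optimality criteria ranking %greenness series by phenological information.

Two scores decide which candidate ROI is "most phenological":

OC1 — supF change-point statistic.  A deciduous gcc series shows a sharp
structural change at spring leaf-out.  Restricting to the first 240 days of
the year (dropping autumn/winter), every DOY s in a candidate window
(default 30..210) is tried as a change point: a single straight line
(2 parameters, residual sum of squares RSS0) is compared with a segmented
fit whose intercept and slope both change at s (4 parameters, RSS1(s)) via

    F(s) = ((RSS0 - RSS1(s)) / k) / (RSS1(s) / (n - 2k)),   k = 2,

where n counts the observed DOYs used.  OC1 is max_s F(s); the argmax is
the estimated change DOY.  The F value is used purely as a ranking score,
not as a calibrated test statistic.

OC2 — template-bank correlation.  The expected deciduous annual curve is
encoded as a piecewise-linear template: winter floor, steep rise from
spring onset ``a`` to a peak, small dip onto a summer plateau, autumn
decline ending at ``b``.  A bank of templates over the grid
a ∈ {50..150}, b ∈ {265..365} is correlated (Pearson, observed DOYs only)
with the series; OC2 is the best correlation and the winning (a, b) double
as rough start/end-of-season dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .greenness import GreennessSeries, N_DOY

__all__ = [
    "OC1Result",
    "OC2Result",
    "Template",
    "TemplateBank",
    "oc1",
    "oc2",
    "make_template",
    "default_bank",
    "split_f_statistics",
]

# Residual sums below ZERO_RSS_RTOL * max(1, total sum of squares) count as
# an exact fit; keeps the +inf / 0 conventions robust to float cancellation.
ZERO_RSS_RTOL = 1e-9


@dataclass
class OC1Result:
    """Outcome of the supF scan: best F, its change DOY, and fit bookkeeping."""

    f_max: float
    change_doy: int
    rss0: float
    rss1: float
    n_used: int
    k_params: int = 2
    exact_fit: bool = False


@dataclass
class OC2Result:
    rho_max: float
    a_hat: int
    b_hat: int


# ---------------------------------------------------------------------------
# supF machinery (shared by OC1 and the greedy date segmentation)

def _segment_rss(m, st, sy, stt, sty, syy):
    """RSS of a least-squares line through segments summarised by moment sums.

    All arguments are arrays over segments: count, sum t, sum y, sum t^2,
    sum t*y, sum y^2.  Closed form: RSS = Syy_c - Sxy_c^2 / Sxx_c.
    Segments with fewer than two points fit exactly (RSS 0).
    """
    m = np.asarray(m, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = np.where(m > 0, m, 1.0)
        sxx = stt - st * st / mm
        sxy = sty - st * sy / mm
        syc = syy - sy * sy / mm
        rss = syc - np.where(sxx > 0, sxy * sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss = np.where(m >= 2, rss, 0.0)
    return np.clip(rss, 0.0, None)


def split_f_statistics(t: np.ndarray, y: np.ndarray, left_sizes: np.ndarray):
    """F statistics comparing one line against two lines split after
    ``left_sizes`` points, for observations (t, y) sorted by t.

    Returns ``(F, rss0, rss1)`` with F and rss1 arrays aligned to
    ``left_sizes``.  Exact-fit conventions: RSS1 ~ 0 with RSS0 > 0 gives
    F = +inf; RSS0 ~ 0 gives F = 0.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = t.size
    if np.any((left_sizes < 1) | (left_sizes > n - 1)):
        raise ValueError("left_sizes out of range")
    # centering improves the conditioning of the moment-sum closed form
    tc = t - t.mean()
    yc = y - y.mean()
    st = np.cumsum(tc)
    sy = np.cumsum(yc)
    stt = np.cumsum(tc * tc)
    sty = np.cumsum(tc * yc)
    syy = np.cumsum(yc * yc)

    rss0 = float(_segment_rss(np.array([n]), st[-1:], sy[-1:], stt[-1:], sty[-1:], syy[-1:])[0])

    i = np.asarray(left_sizes, dtype=int)
    left = _segment_rss(i, st[i - 1], sy[i - 1], stt[i - 1], sty[i - 1], syy[i - 1])
    right = _segment_rss(
        n - i, st[-1] - st[i - 1], sy[-1] - sy[i - 1], stt[-1] - stt[i - 1],
        sty[-1] - sty[i - 1], syy[-1] - syy[i - 1],
    )
    rss1 = np.minimum(left + right, rss0)

    tol = ZERO_RSS_RTOL * max(1.0, syy[-1])
    dof = n - 4
    if dof <= 0:
        raise ValueError(f"need more than 4 observations for the segmented fit, got {n}")
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((rss0 - rss1) / 2.0) / (rss1 / dof)
    f = np.where(rss1 <= tol, np.where(rss0 <= tol, 0.0, np.inf), f)
    return np.clip(f, 0.0, None), rss0, rss1


def oc1(
    series: GreennessSeries,
    window_end: int = 240,
    cand_lo: int = 30,
    cand_hi: int = 210,
    min_side: int = 5,
) -> OC1Result:
    """Optimality criterion 1: the supF structural-change scan.

    Only observed DOYs up to ``window_end`` enter; candidate change points
    run over ``cand_lo..cand_hi`` and need at least ``min_side`` observations
    strictly before and from the candidate onward (boundary candidates would
    make the segmented fit singular).  A change at s assigns days < s to the
    left regime and days >= s to the right one; ties in F break toward the
    earliest candidate.
    """
    vals = series.values[:window_end]
    obs = np.nonzero(~np.isnan(vals))[0]
    t = (obs + 1).astype(float)
    y = vals[obs]
    n = t.size
    if n < 2 * min_side:
        raise ValueError(f"need at least {2 * min_side} observed DOYs in 1..{window_end}, got {n}")

    cands = np.arange(cand_lo, cand_hi + 1)
    left_counts = np.searchsorted(t, cands)  # observations with DOY < s
    valid = (left_counts >= min_side) & (left_counts <= n - min_side)
    if not np.any(valid):
        raise ValueError("no candidate change point has enough observations on both sides")
    cands = cands[valid]
    left_counts = left_counts[valid]

    sizes, inverse = np.unique(left_counts, return_inverse=True)
    f_by_size, rss0, rss1_by_size = split_f_statistics(t, y, sizes)
    f = f_by_size[inverse]

    best = int(np.argmax(f))  # first occurrence wins -> earliest candidate DOY
    return OC1Result(
        f_max=float(f[best]),
        change_doy=int(cands[best]),
        rss0=rss0,
        rss1=float(rss1_by_size[inverse][best]),
        n_used=n,
        k_params=2,
        exact_fit=bool(np.isinf(f[best])),
    )


# ---------------------------------------------------------------------------
# OC2: template bank correlation

@dataclass(frozen=True)
class Template:
    """Piecewise-linear deciduous annual gcc shape on the DOY 1..365 axis.

    0 on [1, a]; rises 0 -> 1 on [a, c]; falls 1 -> plateau_level on [c, d];
    flat on [d, e]; falls back to 0 on [e, b]; 0 on [b, 365].  Only the
    relative geometry matters for OC2 (Pearson correlation is invariant to
    affine rescaling), so the winter floor is fixed at 0 and the peak at 1.
    """

    a: int
    b: int
    c: int
    d: int
    e: int
    plateau_level: float
    values: np.ndarray


def make_template(
    a: int,
    b: int,
    c: Optional[int] = None,
    d: Optional[int] = None,
    e: Optional[int] = None,
    plateau_level: float = 0.7,
) -> Template:
    """Build a deciduous template for spring onset ``a`` and autumn end ``b``.

    Defaults place the peak 20 days after onset (c = a + 20), the plateau a
    further 20 days on (d = c + 20) and the start of the autumn decline 60
    days before its end (e = b - 60).
    """
    c = a + 20 if c is None else c
    d = c + 20 if d is None else d
    e = b - 60 if e is None else e
    if not (1 <= a < c < d <= e < b <= N_DOY):
        raise ValueError(f"template knots must satisfy 1 <= a < c < d <= e < b <= {N_DOY}, got "
                         f"a={a} c={c} d={d} e={e} b={b}")
    if not (0.0 <= plateau_level <= 1.0):
        raise ValueError("plateau_level must lie in [0, 1]")
    doys = np.arange(1, N_DOY + 1, dtype=float)
    knots = np.array([1, a, c, d, e, b, N_DOY], dtype=float)
    levels = np.array([0.0, 0.0, 1.0, plateau_level, plateau_level, 0.0, 0.0])
    values = np.interp(doys, knots, levels)
    return Template(a=a, b=b, c=c, d=d, e=e, plateau_level=plateau_level, values=values)


@dataclass
class TemplateBank:
    """A template per (a, b) grid point, in lexicographic (a, b) order."""

    params: np.ndarray  # (N, 2) int array of (a, b)
    values: np.ndarray  # (N, 365)
    _std_cache: Dict[bytes, tuple] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.params)

    def standardized(self, observed_idx: np.ndarray):
        """Row-centred template values and norms on a set of observed DOY
        indices (0-based); cached because OC2 is evaluated for many series
        sharing one observation pattern."""
        key = observed_idx.astype(np.int64).tobytes()
        hit = self._std_cache.get(key)
        if hit is None:
            sub = self.values[:, observed_idx]
            centred = sub - sub.mean(axis=1, keepdims=True)
            norms = np.sqrt((centred * centred).sum(axis=1))
            hit = (centred, norms)
            if len(self._std_cache) >= 4:
                self._std_cache.pop(next(iter(self._std_cache)))
            self._std_cache[key] = hit
        return hit


def default_bank(
    a_values: Sequence[int] = range(50, 151),
    b_values: Sequence[int] = range(265, 366),
    **shape,
) -> TemplateBank:
    """The default bank: a ∈ {50..150} x b ∈ {265..365}, 10201 templates.

    ``shape`` forwards c/d/e/plateau_level overrides to every template.
    """
    params = []
    rows = []
    for a in a_values:
        for b in b_values:
            tpl = make_template(a, b, **shape)
            params.append((a, b))
            rows.append(tpl.values)
    return TemplateBank(params=np.array(params, dtype=int), values=np.array(rows))


def oc2(series: GreennessSeries, bank: Optional[TemplateBank] = None) -> OC2Result:
    """Optimality criterion 2: best Pearson correlation against the bank.

    Correlations are computed over the series' observed DOYs only.  The
    maximum and its (a, b) are returned; exact ties break toward the
    lexicographically smallest (a, b).  Templates that are constant on the
    observed window are excluded (their correlation is undefined).
    """
    if bank is None:
        bank = default_bank()
    idx = np.nonzero(~np.isnan(series.values))[0]
    if idx.size < 3:
        raise ValueError(f"OC2 needs at least 3 observed DOYs, got {idx.size}")
    y = series.values[idx]
    yc = y - y.mean()
    ny = float(np.sqrt((yc * yc).sum()))
    if ny <= 0.0:
        raise ValueError("OC2 undefined for a constant series (zero variance)")

    centred, norms = bank.standardized(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centred @ yc) / (norms * ny)
    rho = np.where(norms > 0, rho, -np.inf)
    if not np.any(np.isfinite(rho)):
        raise ValueError("every bank template is constant on the observed DOYs")
    best = int(np.argmax(rho))  # bank rows are lexicographic in (a, b)
    a_hat, b_hat = (int(v) for v in bank.params[best])
    return OC2Result(rho_max=float(rho[best]), a_hat=a_hat, b_hat=b_hat)
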