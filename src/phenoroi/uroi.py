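"""Unsupervised ROI extraction: SVD eigenimages + k-means pixel clustering.

Every colour channel of every pixel is treated as an observation unit and
every frame as a variable: the stack becomes a 3n x T data matrix

    X = (x_1, ..., x_T),   x_t = (r_1t..r_nt, g_1t..g_nt, b_1t..b_nt)',

row-centred over time.  A truncated SVD X = U D V' keeps the first p left
singular vectors (eigenimages); rearranging U gives the n x 3p feature
matrix U* whose row i holds pixel i's p loadings per colour channel.
k-means on the rows of U* segments the image into k clusters, each a
candidate ROI.  Scanning a (p, k) grid and scoring every cluster's
%greenness series with OC1/OC2 selects the most phenological cluster as
the final uROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import criteria
from .criteria import TemplateBank
from .greenness import pixel_series_matrix, series_from_matrix
from .image_stack import ImageStack
from .sroi import CandidateROI

__all__ = [
    "PixelFeatureMatrix",
    "Partition",
    "build_data_matrix",
    "svd_features",
    "kmeans_partition",
    "uroi_select",
    "DEFAULT_P_GRID",
    "DEFAULT_K_GRID",
]

log = logging.getLogger(__name__)

DEFAULT_P_GRID = (12, 24)
DEFAULT_K_GRID = (4, 5, 6, 7, 8, 9, 10)


@dataclass
class PixelFeatureMatrix:
    """Truncated-SVD pixel features.

    ``u`` is the 3n x p left-singular-vector block (orthonormal columns,
    sign-fixed); ``u_star`` the n x 3p per-pixel rearrangement with column
    order (r loadings 1..p, g loadings 1..p, b loadings 1..p); ``vt`` the
    p x T right factor, kept so the truncation can be checked by
    reconstruction.
    """

    u: np.ndarray
    u_star: np.ndarray
    singular_values: np.ndarray
    vt: np.ndarray
    p: int


@dataclass
class Partition:
    labels: np.ndarray  # cluster id per pixel, row-major
    k: int
    p: int
    seed: int

    def __post_init__(self) -> None:
        uniq = np.unique(self.labels)
        if uniq.size != self.k:
            raise ValueError(f"partition has {uniq.size} nonempty clusters, expected k={self.k}")

    def cluster_mask(self, cluster_id: int, n1: int, n2: int) -> np.ndarray:
        return (self.labels == cluster_id).reshape(n1, n2)


def build_data_matrix(stack: ImageStack) -> np.ndarray:
    """Row-centred 3n x T matrix, rows ordered r-block, g-block, b-block."""
    if stack.T < 2:
        raise ValueError(f"need at least 2 frames, got {stack.T}")
    arr = stack.pixel_array()  # (T, n1, n2, 3)
    T, n = stack.T, stack.n
    channels = [arr[..., ch].reshape(T, n).T for ch in range(3)]
    x = np.concatenate(channels, axis=0)
    return x - x.mean(axis=1, keepdims=True)


def _fix_signs(u: np.ndarray, vt: np.ndarray):
    """Flip each singular pair so u's largest-magnitude entry is positive
    (SVD signs are arbitrary; a fixed convention makes features
    reproducible).  The matching vt row flips too, preserving U D V'."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs, vt * signs[:, None]


def svd_features(stack: ImageStack, p: int) -> PixelFeatureMatrix:
    """First p left singular vectors of the centred data matrix, rearranged
    to per-pixel features.

    The decomposition is computed densely (LAPACK) and truncated by slicing,
    which is exact and deterministic at the stack sizes this package targets.
    """
    x = build_data_matrix(stack)
    rank_cap = min(x.shape)
    if not (1 <= p <= rank_cap):
        raise ValueError(f"p must lie in 1..min(3n, T) = {rank_cap}, got {p}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, vt = _fix_signs(u[:, :p], vt[:p])
    n = stack.n
    u_star = np.hstack([u[:n], u[n : 2 * n], u[2 * n :]])
    return PixelFeatureMatrix(u=u, u_star=u_star, singular_values=s[:p], vt=vt, p=p)


def kmeans_partition(
    features: PixelFeatureMatrix,
    k: int,
    seed: int = 0,
    restarts: int = 10,
) -> Partition:
    """Best-inertia k-means labelling of the U* rows (k-means++ seeding,
    squared-Euclidean, deterministic under a fixed seed)."""
    rows = features.u_star
    n = rows.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds pixel count {n}")
    if np.unique(rows, axis=0).shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of distinct feature rows")
    km = KMeans(n_clusters=k, n_init=restarts, max_iter=300, random_state=seed)
    labels = km.fit_predict(rows)
    return Partition(labels=labels, k=k, p=features.p, seed=seed)


def uroi_select(
    stack: ImageStack,
    p_grid: Sequence[int] = DEFAULT_P_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    criterion: str = "oc2",
    min_size: int = 0,
    seed: int = 0,
    restarts: int = 10,
    bank: Optional[TemplateBank] = None,
) -> Tuple[CandidateROI, pd.DataFrame]:
    """Grid-search uROI: one partition per (p, k), every cluster scored.

    Returns the best cluster under ``criterion`` (among clusters of at least
    ``min_size`` pixels; ``min_size=0`` scores everything) together with the
    full candidate table — columns (p, k, cluster_id, size, oc1, oc2, a_hat,
    b_hat, rank), ranked by the chosen criterion, one row per cluster before
    size filtering.
    """
    if criterion not in ("oc1", "oc2"):
        raise ValueError(f"criterion must be 'oc1' or 'oc2', got {criterion!r}")
    if len(p_grid) == 0 or len(k_grid) == 0:
        raise ValueError("p_grid and k_grid must be nonempty")
    if bank is None:
        bank = criteria.default_bank()
    matrix = pixel_series_matrix(stack)

    rows = []
    best: Optional[CandidateROI] = None
    best_key = None
    for p in p_grid:
        features = svd_features(stack, p)
        for k in k_grid:
            part = kmeans_partition(features, k, seed=seed, restarts=restarts)
            for cid in range(k):
                mask = part.cluster_mask(cid, stack.n1, stack.n2)
                size = int(mask.sum())
                series = series_from_matrix(matrix, mask)
                row = {"p": p, "k": k, "cluster_id": cid, "size": size,
                       "oc1": np.nan, "oc2": np.nan, "a_hat": np.nan, "b_hat": np.nan}
                oc1_res = oc2_res = None
                try:
                    oc1_res = criteria.oc1(series)
                    row["oc1"] = oc1_res.f_max
                except ValueError as exc:
                    log.info("OC1 unscoreable for (p=%d,k=%d,c=%d): %s", p, k, cid, exc)
                try:
                    oc2_res = criteria.oc2(series, bank)
                    row["oc2"] = oc2_res.rho_max
                    row["a_hat"] = oc2_res.a_hat
                    row["b_hat"] = oc2_res.b_hat
                except ValueError as exc:
                    log.info("OC2 unscoreable for (p=%d,k=%d,c=%d): %s", p, k, cid, exc)
                rows.append(row)

                score = row[criterion]
                if size < min_size or np.isnan(score):
                    continue
                key = (score, size)
                if best_key is None or key > best_key:
                    best_key = key
                    best = CandidateROI(
                        mask=mask,
                        provenance={"p": p, "k": k, "cluster_id": cid},
                        oc1=oc1_res,
                        oc2=oc2_res,
                        score=float(score),
                    )
    table = pd.DataFrame(rows)
    order = table[criterion].to_numpy(dtype=float)
    # rank 1 = best under the chosen criterion; NaN scores rank last
    rank_order = np.argsort(np.argsort(-np.nan_to_num(order, nan=-np.inf)))
    table["rank"] = rank_order + 1
    if best is None:
        raise ValueError(f"no cluster of at least min_size={min_size} pixels could be scored")
    return best, table
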