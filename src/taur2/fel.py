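"""Two-dimensional free-energy landscapes and conformational clusters.

The landscape over two reaction coordinates (here end-to-end distance
and radius of gyration) is ΔG(bin) = −k_B T·[ln P(bin) − ln P_max],
so the global minimum sits at ΔG = 0 and unvisited bins are undefined
(NaN), never zero.  Clusters in the same coordinate plane come from
k-means on z-score-normalized points, with populations and a
representative frame (the member closest to the cluster center).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .constants import BOLTZMANN_KCAL, DEFAULT_TEMPERATURE


class FelError(ValueError):
    pass


@dataclass(frozen=True)
class FELGrid:
    axis1_edges: np.ndarray     # x bin edges (e2e, nm)
    axis2_edges: np.ndarray     # y bin edges (Rg, nm)
    delta_g: np.ndarray         # (nx, ny) kcal/mol; NaN where unvisited
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.delta_g)


def build_fel(series_x, series_y, bins: int | tuple[int, int] = 50,
              temperature: float = DEFAULT_TEMPERATURE,
              ranges=None) -> FELGrid:
    """Bin two reaction-coordinate series into a free-energy grid."""
    x = np.asarray(series_x, dtype=float)
    y = np.asarray(series_y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise FelError("series must be equal-length and non-empty")
    if isinstance(bins, int):
        bins = (bins, bins)
    if min(bins) < 2:
        raise FelError("need at least 2 bins per axis")
    if ranges is not None:
        for (lo, hi) in ranges:
            if not hi > lo:
                raise FelError("zero-width axis range")
    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=ranges)
    p = counts / counts.sum()
    kbt = BOLTZMANN_KCAL * temperature
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
    delta_g = -kbt * (logp - logp.max())
    delta_g = np.where(np.isfinite(delta_g), delta_g, np.nan)
    return FELGrid(axis1_edges=xe, axis2_edges=ye, delta_g=delta_g,
                   temperature=temperature)


def suggest_k(grid: FELGrid, depth_kbt: float = 0.5,
              ceiling_kbt: float = 3.0) -> int:
    """Count local minima deeper than ``depth_kbt``·k_BT below their rim.

    Only bins within ``ceiling_kbt``·k_BT of the global minimum and
    with a fully sampled 8-neighbor rim are considered: sparsely
    sampled high-ΔG bins are statistical noise, not states.  The count
    is resolution-sensitive — for a few thousand frames a 20–30-bin
    grid is a sensible advisory resolution.  Advisory only: the
    cluster count is always a user decision, as it was chosen by eye
    from the landscape in the study this reproduces.
    """
    g = grid.delta_g
    kbt = BOLTZMANN_KCAL * grid.temperature
    nx, ny = g.shape
    count = 0
    for i in range(nx):
        for j in range(ny):
            if not np.isfinite(g[i, j]) or g[i, j] > ceiling_kbt * kbt:
                continue
            rim = []
            full_rim = True
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < ny and np.isfinite(g[a, b]):
                        rim.append(g[a, b])
                        if g[a, b] < g[i, j]:
                            is_min = False
                    else:
                        full_rim = False
            if is_min and full_rim \
                    and (np.median(rim) - g[i, j]) >= depth_kbt * kbt:
                count += 1
    return max(count, 1)


@dataclass(frozen=True)
class ClusterSet:
    k: int
    centers: np.ndarray              # (k, 2) in original coordinate units
    populations: np.ndarray          # fractions summing to 1
    representative_frames: np.ndarray  # frame indices, one per cluster
    labels: np.ndarray               # per-frame cluster assignment
    inertia: float


def _zscore(points: np.ndarray):
    mean = points.mean(axis=0)
    std = points.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (points - mean) / std, mean, std


def kmeans_cluster(points, k: int, seed: int) -> ClusterSet:
    """k-means on z-score-normalized (x, y) points.

    Standard Lloyd iterations with k-means++ seeding from ``seed`` and
    the best of 10 restarts by inertia (scikit-learn).  Deterministic
    given (points, k, seed).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FelError("points must be (n, 2)")
    n_distinct = np.unique(pts, axis=0).shape[0]
    if k < 1 or k > n_distinct:
        raise FelError(f"k={k} outside [1, {n_distinct} distinct points]")
    z, mean, std = _zscore(pts)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=int(seed))
    labels = km.fit_predict(z)
    centers = km.cluster_centers_ * std + mean
    populations = np.bincount(labels, minlength=k) / pts.shape[0]
    reps = np.array([
        representative_frame_for(z, labels, km.cluster_centers_, c)
        for c in range(k)
    ])
    return ClusterSet(
        k=k, centers=centers, populations=populations,
        representative_frames=reps, labels=labels,
        inertia=float(km.inertia_),
    )


def representative_frame_for(z_points: np.ndarray, labels: np.ndarray,
                             z_centers: np.ndarray, cluster_id: int) -> int:
    """Member frame closest (normalized Euclidean) to the cluster center.

    Ties break to the smallest frame index.
    """
    members = np.nonzero(labels == cluster_id)[0]
    if members.size == 0:
        raise FelError(f"cluster {cluster_id} is empty")
    d2 = ((z_points[members] - z_centers[cluster_id]) ** 2).sum(axis=1)
    return int(members[int(np.argmin(d2))])


def representative_frame(points, cluster_set: ClusterSet, cluster_id: int
                         ) -> int:
    """Representative frame of one cluster of an existing clustering."""
    pts = np.asarray(points, dtype=float)
    z, mean, std = _zscore(pts)
    z_centers = (cluster_set.centers - mean) / std
    return representative_frame_for(
        z, cluster_set.labels, z_centers, cluster_id
    )
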