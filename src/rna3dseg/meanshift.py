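"""Mean Shift clustering of 3D point traces with explicit outlier labeling.

Every point serves as a seed and is iteratively shifted to the (kernel-
weighted) centroid of its neighborhood until it moves by less than the
convergence tolerance.  Converged positions closer than one bandwidth are
merged into modes; points farther than one bandwidth from every mode are
labeled outliers — the raw material of linkers downstream.

The bandwidth is derived from a quantile of the data's nearest-neighbor
distance distribution rather than given in Å, so one setting transfers
across chains of very different size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .core import OUTLIER

logger = logging.getLogger(__name__)

KERNELS = ("uniform", "gaussian")


@dataclass(frozen=True)
class MeanShiftConfig:
    """Hyperparameters of the clustering stage.

    bandwidth_quantile : fraction in (0, 1] of the pairwise-distance
        distribution used to derive the bandwidth (default 0.2, the tuned
        optimum).
    kernel : ``uniform`` (equal weight to every neighbor inside the
        bandwidth) or ``gaussian`` (gaussian weights over the same
        neighborhood, truncated at one bandwidth).
    convergence_tol : stop shifting a point once it moves less than this
        many Å per iteration (default 0.001 Å).
    max_iterations : hard cap on shift iterations per seed.
    bandwidth : explicit bandwidth in Å, bypassing the quantile estimate
        (mainly for controlled experiments).
    """

    bandwidth_quantile: float = 0.2
    kernel: str = "uniform"
    convergence_tol: float = 0.001
    max_iterations: int = 300
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.bandwidth_quantile <= 1.0:
            raise ValueError("bandwidth_quantile must be in (0, 1]")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class ClusterLabeling:
    """Result of clustering: per-point labels, mode coordinates, bandwidth.

    ``labels[i]`` indexes a row of ``modes`` or equals :data:`OUTLIER`.
    """

    labels: np.ndarray
    modes: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        modes = np.asarray(self.modes, dtype=float).reshape(-1, 3)
        valid = labels[labels != OUTLIER]
        if valid.size and (valid.min() < 0 or valid.max() >= modes.shape[0]):
            raise ValueError("every non-outlier label must index a mode")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "modes", modes)

    @property
    def n_clusters(self) -> int:
        return int(self.modes.shape[0])

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == OUTLIER))


def estimate_bandwidth(points: np.ndarray, quantile: float = 0.2) -> float:
    """Bandwidth = mean distance to the k-th nearest neighbor, k = max(1, ⌊q·n⌋).

    The point itself counts as its own 0-th neighbor, so ``quantile=1.0``
    averages the distance to each point's farthest neighbor.  Returns 0 when
    all points coincide; callers must reject a zero bandwidth.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("bandwidth estimation needs at least 2 points")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    k = max(1, int(np.floor(quantile * n)))
    nbrs = NearestNeighbors(n_neighbors=k).fit(pts)
    dist, _ = nbrs.kneighbors(pts)
    return float(dist[:, -1].mean())


def shift_step(x: np.ndarray, points: np.ndarray, bandwidth: float,
               kernel: str = "uniform") -> np.ndarray:
    """One mean-shift update of query position ``x`` toward its local centroid."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    x = np.asarray(x, dtype=float)
    pts = np.asarray(points, dtype=float)
    d = np.linalg.norm(pts - x, axis=1)
    mask = d <= bandwidth
    if not mask.any():
        return x.copy()
    if kernel == "uniform":
        return pts[mask].mean(axis=0)
    w = np.where(mask, np.exp(-0.5 * (d / bandwidth) ** 2), 0.0)
    return (w[:, None] * pts).sum(axis=0) / w.sum()


def _shift_all(positions: np.ndarray, points: np.ndarray, bandwidth: float,
               kernel: str) -> np.ndarray:
    """Vectorized :func:`shift_step` for a batch of query positions."""
    d = cdist(positions, points)
    mask = d <= bandwidth
    new = positions.copy()
    if kernel == "uniform":
        counts = mask.sum(axis=1)
        nz = counts > 0
        new[nz] = (mask[nz].astype(float) @ points) / counts[nz, None]
        return new
    w = np.where(mask, np.exp(-0.5 * (d / bandwidth) ** 2), 0.0)
    s = w.sum(axis=1)
    nz = s > 0
    new[nz] = (w[nz] @ points) / s[nz, None]
    return new


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # lower root wins, keeping component ids deterministic
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def mean_shift_cluster(points: np.ndarray,
                       config: MeanShiftConfig | None = None) -> ClusterLabeling:
    """Cluster 3D points by Mean Shift with explicit outlier labeling.

    Every point is seeded and shifted until its displacement falls below
    ``config.convergence_tol`` (or ``max_iterations`` is reached).
    Converged positions within one bandwidth of each other are merged into a
    single mode by union-find; the mode coordinate is the converged position
    whose basin holds the most seeds (ties: lowest seed index).  Each point
    takes the label of its nearest mode if that mode lies within one
    bandwidth of the point, else :data:`OUTLIER`.

    Deterministic: no randomness anywhere in the procedure.
    """
    if config is None:
        config = MeanShiftConfig()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    n = pts.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 points")
    bandwidth = (config.bandwidth if config.bandwidth is not None
                 else estimate_bandwidth(pts, config.bandwidth_quantile))
    if bandwidth <= 0:
        raise ValueError("estimated bandwidth is 0 (all points coincide)")

    positions = pts.copy()
    active = np.ones(n, dtype=bool)
    for _ in range(config.max_iterations):
        moved = _shift_all(positions[active], pts, bandwidth, config.kernel)
        disp = np.linalg.norm(moved - positions[active], axis=1)
        positions[active] = moved
        still = disp >= config.convergence_tol
        active[np.flatnonzero(active)[~still]] = False
        if not active.any():
            break
    else:
        logger.warning("mean shift did not fully converge after %d iterations "
                       "(%d points still moving); using current positions",
                       config.max_iterations, int(active.sum()))

    # basins: seeds whose converged positions coincide (within tolerance)
    basin_rep = np.full(n, -1, dtype=int)     # representative seed per basin
    reps: list[int] = []
    for i in range(n):
        for r in reps:
            if np.linalg.norm(positions[i] - positions[r]) <= config.convergence_tol:
                basin_rep[i] = r
                break
        else:
            reps.append(i)
            basin_rep[i] = i
    basin_size = {r: int(np.sum(basin_rep == r)) for r in reps}

    # merge basins whose converged positions lie within one bandwidth
    uf = _UnionFind(len(reps))
    rep_pos = positions[reps]
    d = cdist(rep_pos, rep_pos)
    for a in range(len(reps)):
        for b in range(a + 1, len(reps)):
            if d[a, b] <= bandwidth:
                uf.union(a, b)
    components: dict[int, list[int]] = {}
    for a in range(len(reps)):
        components.setdefault(uf.find(a), []).append(a)

    # one mode per component: position of the largest basin (ties: lowest seed)
    mode_list: list[tuple[int, np.ndarray]] = []
    for members in components.values():
        best = max(members, key=lambda a: (basin_size[reps[a]], -reps[a]))
        first_seed = min(reps[a] for a in members)
        mode_list.append((first_seed, positions[reps[best]]))
    mode_list.sort(key=lambda t: t[0])
    modes = np.array([pos for _, pos in mode_list]).reshape(-1, 3)

    dist_to_modes = cdist(pts, modes)
    nearest = dist_to_modes.argmin(axis=1)
    labels = np.where(dist_to_modes[np.arange(n), nearest] <= bandwidth,
                      nearest, OUTLIER)
    return ClusterLabeling(labels, modes, bandwidth)
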