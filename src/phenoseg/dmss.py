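"""Dynamic multi-stage down-sampling (DMSS).

Fixed-ratio samplers treat every plant the same, but crop point clouds change
drastically over the growth cycle: a seedling is a sparse stick with two
leaves, a mature canopy is a dense, heavily self-occluded tangle. DMSS makes
the retained budget a function of the cloud's structural complexity:

1. Stage 1 thins the cloud by uniform random sampling (default: keep 10 %).
2. Two coefficient-of-variation statistics are computed on the *original*
   cloud: ``CV_v``, the CV of per-voxel point counts over occupied voxels of a
   5 cm grid (global occupancy unevenness), and ``CV_d``, the CV of per-point
   KNN densities ``rho_i = k / sum_j ||p_i - p_j||^2`` (local crowding).
3. They are turned into weights ``w_v = 1 / (1 + CV_v)`` and
   ``w_d = CV_d / (CV_v + CV_d)``, and the farthest-point-sampling ratio for
   stage 2 is ``r_FPS = r_base * (w_v + lambda * w_d)``.
4. Stage 2 runs farthest-point sampling on the stage-1 subset at that ratio,
   with the *overall* retained fraction (relative to the original cloud)
   clamped to [2 %, 8 %].

A weighted-sum diagnostic ``C_joint = lambda * CV_v + (1 - lambda) * CV_d``
summarizes joint complexity; it is reported but does not enter the ratio rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class DMSSParams:
    """Tunable knobs of the sampler. Distances are meters, ratios fractions."""

    voxel_edge: float = 0.05
    knn_k: int = 50
    r_base: float = 0.5
    lambda_weight: float = 0.5
    stage1_ratio: float = 0.10
    clamp_lo: float = 0.02
    clamp_hi: float = 0.08
    seed: int = 0
    reciprocal_density: bool = False  # rho = sum d^2 / k instead of k / sum d^2

    def __post_init__(self) -> None:
        if not (0.0 < self.stage1_ratio <= 1.0):
            raise ValueError("stage1_ratio must be in (0, 1]")
        if not (0.0 < self.clamp_lo < self.clamp_hi <= 1.0):
            raise ValueError("need 0 < clamp_lo < clamp_hi <= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.voxel_edge <= 0:
            raise ValueError("voxel_edge must be positive")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be nonnegative")


@dataclass
class VoxelStats:
    occupied_count: int
    mean_occupancy: float
    sd_occupancy: float
    cv_v: float
    w_v: float


@dataclass
class DensityStats:
    rho: np.ndarray
    mean_rho: float
    sd_rho: float
    cv_d: float
    w_d: float


@dataclass
class DMSSResult:
    stage1_indices: np.ndarray
    final_indices: np.ndarray
    voxel_stats: VoxelStats
    density_stats: DensityStats
    c_joint: float
    r_fps: float
    overall_ratio: float


def random_downsample(cloud, ratio: float, seed: int = 0) -> np.ndarray:
    """Uniform sampling without replacement of ``max(1, round(ratio*N))`` indices."""
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    n = cloud.n_points
    m = max(1, int(round(ratio * n)))
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=m, replace=False))


def farthest_point_sample(coords: np.ndarray, m: int, seed: int = 0,
                          start: int | None = None) -> np.ndarray:
    """Greedy farthest-point sampling.

    The first index is drawn uniformly from ``seed`` (or forced via
    ``start``); each subsequent index maximizes the minimum Euclidean distance
    to the already-selected set, ties broken toward the lowest index. Returns
    the ``m`` indices in selection order.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if not (1 <= m <= n):
        raise ValueError(f"m must satisfy 1 <= m <= {n}, got {m}")
    if start is None:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(n))
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start
    # min squared distance from each point to the selected set
    min_d2 = np.sum((coords - coords[start]) ** 2, axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(min_d2))  # argmax returns the lowest tying index
        selected[i] = nxt
        d2 = np.sum((coords - coords[nxt]) ** 2, axis=1)
        np.minimum(min_d2, d2, out=min_d2)
    return selected


def voxel_occupancy_stats(cloud, voxel_edge: float = 0.05) -> VoxelStats:
    """CV of per-voxel point counts over occupied voxels of a uniform grid.

    The grid is anchored at the bounding-box minimum corner with half-open
    cells; statistics use the population standard deviation and only voxels
    that contain at least one point.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be positive")
    coords = cloud.coords
    ijk = np.floor((coords - coords.min(axis=0)) / voxel_edge).astype(np.int64)
    _, counts = np.unique(ijk, axis=0, return_counts=True)
    mu = float(counts.mean())
    sigma = float(counts.std())  # population sd
    cv_v = sigma / mu if mu > 0 else 0.0
    return VoxelStats(occupied_count=len(counts), mean_occupancy=mu,
                      sd_occupancy=sigma, cv_v=cv_v, w_v=1.0 / (1.0 + cv_v))


def knn_density_stats(cloud, k: int = 50, cv_v: float = 0.0,
                      reciprocal: bool = False) -> DensityStats:
    """Per-point KNN density ``rho_i = k' / sum_{j in kNN(i)} ||p_i - p_j||^2``
    (self excluded, ``k' = min(k, N-1)``) and its coefficient of variation.

    ``w_d = CV_d / (cv_v + CV_d)`` pairs the density CV with the voxel CV of
    the same cloud; 0 when both CVs vanish.
    """
    n = cloud.n_points
    if n < 2:
        raise ValueError("KNN density needs at least 2 points")
    k_eff = min(k, n - 1)
    tree = cKDTree(cloud.coords)
    d, _ = tree.query(cloud.coords, k=k_eff + 1)  # includes self at distance 0
    sum_d2 = np.sum(d[:, 1:] ** 2, axis=1)
    sum_d2 = np.maximum(sum_d2, 1e-300)  # duplicated points
    rho = sum_d2 / k_eff if reciprocal else k_eff / sum_d2
    mu = float(rho.mean())
    sigma = float(rho.std())
    cv_d = sigma / mu if mu > 0 else 0.0
    w_d = cv_d / (cv_v + cv_d) if (cv_v + cv_d) > 0 else 0.0
    return DensityStats(rho=rho, mean_rho=mu, sd_rho=sigma, cv_d=cv_d, w_d=w_d)


def joint_complexity(cv_v: float, cv_d: float, lambda_weight: float) -> float:
    """Weighted-sum complexity diagnostic ``lambda*CV_v + (1-lambda)*CV_d``."""
    if not (0.0 <= lambda_weight <= 1.0):
        raise ValueError("lambda_weight must be in [0, 1]")
    if cv_v < 0 or cv_d < 0:
        raise ValueError("coefficients of variation must be nonnegative")
    return lambda_weight * cv_v + (1.0 - lambda_weight) * cv_d


def dmss_ratio(stats_v: VoxelStats, stats_d: DensityStats,
               params: DMSSParams) -> tuple[float, float]:
    """Adaptive FPS ratio and the clamped overall retained fraction.

    Raw ``r_FPS = r_base * (w_v + lambda * w_d)`` applies to the stage-1 set;
    the overall fraction ``stage1_ratio * r_FPS`` is clamped to
    ``[clamp_lo, clamp_hi]`` and the returned ``r_fps`` is the post-clamp
    overall fraction divided by ``stage1_ratio``.
    """
    raw_r_fps = params.r_base * (stats_v.w_v + params.lambda_weight * stats_d.w_d)
    overall = params.stage1_ratio * raw_r_fps
    overall = float(np.clip(overall, params.clamp_lo, params.clamp_hi))
    return overall / params.stage1_ratio, overall


def dmss_sample(cloud, params: DMSSParams | None = None) -> DMSSResult:
    """Run the full two-stage sampler; returned indices refer to the original cloud."""
    params = params or DMSSParams()
    n = cloud.n_points
    if int(round(params.stage1_ratio * n)) < 2:
        raise ValueError(
            f"stage 1 would retain fewer than 2 of {n} points at "
            f"ratio {params.stage1_ratio}")
    stage1 = random_downsample(cloud, params.stage1_ratio, seed=params.seed)
    vstats = voxel_occupancy_stats(cloud, params.voxel_edge)
    dstats = knn_density_stats(cloud, params.knn_k, cv_v=vstats.cv_v,
                               reciprocal=params.reciprocal_density)
    r_fps, overall = dmss_ratio(vstats, dstats, params)
    m = max(1, int(round(r_fps * stage1.size)))
    m = min(m, stage1.size)
    sub = farthest_point_sample(cloud.coords[stage1], m, seed=params.seed + 1)
    final = stage1[sub]
    return DMSSResult(
        stage1_indices=stage1,
        final_indices=final,
        voxel_stats=vstats,
        density_stats=dstats,
        c_joint=joint_complexity(vstats.cv_v, dstats.cv_d,
                                 min(params.lambda_weight, 1.0)),
        r_fps=r_fps,
        overall_ratio=final.size / n,
    )
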