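"""ISS keypoint detection and the keypoint-retention sampler benchmark.

Intrinsic Shape Signatures (ISS) flags points whose local neighborhood has a
distinctive shape: for each point the covariance matrix of its neighbors
within ``salient_radius`` is eigen-decomposed (eigenvalues
``l1 >= l2 >= l3``), points satisfying ``l2/l1 < gamma_21`` and
``l3/l2 < gamma_32`` are candidates, and non-maximum suppression on the
saliency ``l3`` within ``nms_radius`` keeps only local maxima. Corners and
edge/junction points survive; flat and cylindrical interiors do not.

The retention benchmark scores a down-sampler by the fraction of the cloud's
ISS keypoints that have a sampled point within a tolerance ``epsilon`` —
a sampler that keeps the structurally informative regions scores high even
at aggressive budgets.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .dmss import DMSSParams, dmss_sample, farthest_point_sample, random_downsample


@dataclass
class ISSParams:
    """ISS detector parameters; radii in meters."""

    salient_radius: float
    nms_radius: float
    gamma_21: float = 0.975
    gamma_32: float = 0.975
    min_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.salient_radius <= 0 or self.nms_radius <= 0:
            raise ValueError("radii must be positive")
        if not (0 < self.gamma_21 < 1 and 0 < self.gamma_32 < 1):
            raise ValueError("gamma thresholds must be in (0, 1)")
        if self.min_neighbors < 3:
            raise ValueError("min_neighbors must be >= 3")

    @classmethod
    def from_cloud(cls, cloud, salient_scale: float = 6.0,
                   nms_scale: float = 4.0, **kw) -> "ISSParams":
        """Radii as multiples of the cloud's mean nearest-neighbor spacing."""
        spacing = mean_nn_spacing(cloud)
        return cls(salient_radius=salient_scale * spacing,
                   nms_radius=nms_scale * spacing, **kw)


@dataclass
class KeypointSet:
    indices: np.ndarray
    params: ISSParams

    def __len__(self) -> int:
        return self.indices.size


def mean_nn_spacing(cloud) -> float:
    """Mean distance to the nearest neighbor (self excluded)."""
    tree = cKDTree(cloud.coords)
    d, _ = tree.query(cloud.coords, k=2)
    return float(d[:, 1].mean())


def iss_keypoints(cloud, params: ISSParams) -> KeypointSet:
    """Detect ISS keypoints; deterministic for a fixed cloud and parameters."""
    n = cloud.n_points
    if n < params.min_neighbors + 1:
        warnings.warn("too few points for ISS; returning empty keypoint set")
        return KeypointSet(indices=np.empty(0, dtype=np.int64), params=params)
    coords = cloud.coords
    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, r=params.salient_radius)
    saliency = np.full(n, -np.inf)
    candidate = np.zeros(n, dtype=bool)
    for i, nbrs in enumerate(neighbor_lists):
        nbrs = [j for j in nbrs if j != i]
        if len(nbrs) < params.min_neighbors:
            continue
        pts = coords[nbrs] - coords[i]
        cov = pts.T @ pts / len(nbrs)
        evals = np.linalg.eigvalsh(cov)[::-1]  # l1 >= l2 >= l3
        l1, l2, l3 = evals
        if l1 <= 0:
            continue
        if l2 / l1 < params.gamma_21 and (l2 > 0 and l3 / l2 < params.gamma_32):
            candidate[i] = True
            saliency[i] = l3
    cand_idx = np.where(candidate)[0]
    if cand_idx.size == 0:
        return KeypointSet(indices=cand_idx, params=params)
    # greedy non-maximum suppression on l3 within nms_radius
    # (descending saliency, ties broken toward the lower index)
    cand_tree = cKDTree(coords[cand_idx])
    suppressed = np.zeros(cand_idx.size, dtype=bool)
    kept = []
    for rank in np.argsort(-saliency[cand_idx], kind="stable"):
        if suppressed[rank]:
            continue
        kept.append(cand_idx[rank])
        nearby = cand_tree.query_ball_point(coords[cand_idx[rank]],
                                            r=params.nms_radius)
        suppressed[nearby] = True
    return KeypointSet(indices=np.sort(np.array(kept, dtype=np.int64)),
                       params=params)


def keypoint_retention(cloud, keys: KeypointSet, sampled: np.ndarray,
                       epsilon: float) -> float:
    """Fraction of keypoints with a sampled point within ``epsilon`` meters.

    Vacuously 1.0 when there are no keypoints; 0.0 when the sample is empty
    but keypoints exist.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if len(keys) == 0:
        return 1.0
    sampled = np.asarray(sampled, dtype=np.int64)
    if sampled.size == 0:
        return 0.0
    tree = cKDTree(cloud.coords[sampled])
    d, _ = tree.query(cloud.coords[keys.indices], k=1)
    return float(np.mean(d <= epsilon))


def benchmark_samplers(cloud, params: DMSSParams | None = None,
                       iss: ISSParams | None = None,
                       epsilon: float | None = None,
                       n_seeds: int = 20) -> dict:
    """Compare RS, plain FPS and DMSS at the budget DMSS realizes.

    Each method is run ``n_seeds`` times; the report carries mean and sd of
    the keypoint-retention ratio and the mean wall-clock seconds per method
    (timing is informational only). ``epsilon`` defaults to 1.5x the expected
    point spacing of the *sampled* subset (the original cloud's mean
    nearest-neighbor spacing divided by the square root of the retained
    fraction), i.e. a keypoint counts as retained when the sample represents
    it at the sample's own resolution.
    """
    from .dmss import dmss_ratio, knn_density_stats, voxel_occupancy_stats

    params = params or DMSSParams()
    iss = iss or ISSParams.from_cloud(cloud)
    if epsilon is None:
        vstats = voxel_occupancy_stats(cloud, params.voxel_edge)
        dstats = knn_density_stats(cloud, params.knn_k, cv_v=vstats.cv_v)
        _, overall = dmss_ratio(vstats, dstats, params)
        epsilon = 1.5 * mean_nn_spacing(cloud) / np.sqrt(overall)
    keys = iss_keypoints(cloud, iss)

    retention = {"rs": [], "fps": [], "dmss": []}
    seconds = {"rs": [], "fps": [], "dmss": []}
    budgets = []
    for s in range(n_seeds):
        p = DMSSParams(**{**params.__dict__, "seed": params.seed + s})
        t0 = time.perf_counter()
        res = dmss_sample(cloud, p)
        seconds["dmss"].append(time.perf_counter() - t0)
        budget = res.final_indices.size
        budgets.append(budget)
        retention["dmss"].append(keypoint_retention(cloud, keys,
                                                    res.final_indices, epsilon))

        t0 = time.perf_counter()
        rs_idx = random_downsample(cloud, budget / cloud.n_points, seed=p.seed)
        seconds["rs"].append(time.perf_counter() - t0)
        retention["rs"].append(keypoint_retention(cloud, keys, rs_idx, epsilon))

        t0 = time.perf_counter()
        fps_idx = farthest_point_sample(cloud.coords, budget, seed=p.seed)
        seconds["fps"].append(time.perf_counter() - t0)
        retention["fps"].append(keypoint_retention(cloud, keys, fps_idx, epsilon))

    report = {
        "n_keypoints": len(keys),
        "epsilon": float(epsilon),
        "n_seeds": n_seeds,
        "budget_mean": float(np.mean(budgets)),
        "methods": {},
    }
    for m in ("rs", "fps", "dmss"):
        report["methods"][m] = {
            "retention_mean": float(np.mean(retention[m])),
            "retention_sd": float(np.std(retention[m])),
            "seconds": float(np.mean(seconds[m])),
        }
    return report
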