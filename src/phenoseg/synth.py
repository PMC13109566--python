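"""Procedural labeled crop point clouds for desk-scale experiments.

The generator emulates the statistical structure of scanned crop plants that
the sampler and the segmentation network care about, without attempting
photorealism:

- two-class labels (0 = leaf, 1 = stem) with the stem a minority class;
- a growth-stage ordinal (1..12, a V1..R7 analogue for the soybean-like
  crop) that monotonically drives plant height (0.15 m at stage 1 to 1.20 m
  at stage 12), node/leaf count, and leaf size, hence canopy overlap;
- strongly non-uniform point density: leaf surfaces are sampled denser than
  stems and densify with stage, so the KNN-density CV grows over the cycle;
- viewpoint occlusion: points hidden behind nearer surface from a random
  single-side viewpoint are partially removed.

Geometry is deliberately simple: stems and branches are tubes around mildly
wandering vertical splines, leaves are quadratically bent ellipse patches
(grouped in trifoliate triples for the soybean-like crop, long arched blades
for maize-like, compound clusters of small leaflets for tomato-like).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pcio import LabeledPointCloud, write_point_cloud

_CROPS = ("soybean_like", "maize_like", "tomato_like")


@dataclass
class PlantSpec:
    """One synthetic plant. Unset ``height``/``n_leaves``/``n_branches`` are
    derived from ``stage``."""

    crop: str = "soybean_like"
    stage: int = 6
    height: float | None = None
    n_leaves: int | None = None
    n_branches: int | None = None
    points_per_area: float = 40_000.0   # points per square meter of surface
    noise_sd: float = 0.001             # meters
    occlusion_factor: float = 0.15
    cultivar_id: int = 0
    height_scale: float = 1.0           # cultivar-level systematic offset
    leaf_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop not in _CROPS:
            raise ValueError(f"crop must be one of {_CROPS}, got {self.crop!r}")
        if not (1 <= self.stage <= 12):
            raise ValueError(f"stage must be in 1..12, got {self.stage}")
        if not (0.0 <= self.occlusion_factor < 1.0):
            raise ValueError("occlusion_factor must be in [0, 1)")
        if self.points_per_area <= 0:
            raise ValueError("points_per_area must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.height is not None and not (0.10 <= self.height <= 1.30):
            raise ValueError("height must be within [0.10, 1.30] meters")
        if self.n_leaves is not None and self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")

    def derived_height(self) -> float:
        if self.height is not None:
            return self.height
        base = 0.15 + (self.stage - 1) / 11.0 * 1.05
        return float(np.clip(base * self.height_scale, 0.10, 1.30))

    def derived_n_leaves(self) -> int:
        if self.n_leaves is not None:
            return self.n_leaves
        n_nodes = 1 + self.stage
        per_node = {"soybean_like": 3, "maize_like": 1, "tomato_like": 5}[self.crop]
        return n_nodes * per_node


def _ellipse_patch(rng, n, a, b, bend):
    """Points on a quadratically bent ellipse patch in its local frame."""
    r = np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    x = a * r * np.cos(phi)
    y = b * r * np.sin(phi)
    z = bend * (x ** 2 + y ** 2) / max(a, 1e-9)
    return np.stack([x, y, z], axis=1)


def _rotation(azimuth, tilt):
    ca, sa = np.cos(azimuth), np.sin(azimuth)
    ct, st = np.cos(tilt), np.sin(tilt)
    rot_tilt = np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]])
    rot_az = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    return rot_az @ rot_tilt


def _tube(rng, p0, p1, radius, n):
    """Points on the lateral surface of a straight tube from p0 to p1."""
    t = rng.uniform(0, 1, n)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    axis = axis / max(length, 1e-9)
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    theta = rng.uniform(0, 2 * np.pi, n)
    return (p0 + t[:, None] * (p1 - p0)
            + radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v))


def _stem_axis(rng, height, n_ctrl=6):
    """A mildly wandering vertical polyline; returns a callable z-fraction -> xyz."""
    zs = np.linspace(0, 1, n_ctrl)
    amp = 0.02 * height
    xs = np.cumsum(rng.normal(0, amp / n_ctrl, n_ctrl))
    ys = np.cumsum(rng.normal(0, amp / n_ctrl, n_ctrl))

    def axis(t):
        t = np.atleast_1d(t)
        return np.stack([np.interp(t, zs, xs), np.interp(t, zs, ys),
                         t * height], axis=1)

    return axis


def _occlude(coords, rng, factor, height):
    """Viewpoint-based hidden-point thinning: bin directions from a random
    side viewpoint on a spherical grid and mark points behind the per-bin
    nearest surface as hidden; remove ``factor`` of the hidden points."""
    if factor <= 0:
        return np.ones(coords.shape[0], dtype=bool)
    center = coords.mean(axis=0)
    az = rng.uniform(0, 2 * np.pi)
    el = rng.uniform(np.deg2rad(10), np.deg2rad(45))
    view = center + 3.0 * height * np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    rel = coords - view
    dist = np.linalg.norm(rel, axis=1)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    phi = np.arcsin(np.clip(rel[:, 2] / dist, -1, 1))
    step = np.deg2rad(1.0)
    bins = (np.floor(theta / step).astype(np.int64) * 100_000
            + np.floor(phi / step).astype(np.int64))
    order = np.lexsort((dist, bins))
    sorted_bins = bins[order]
    first = np.ones(len(bins), dtype=bool)
    first[1:] = sorted_bins[1:] != sorted_bins[:-1]
    # nearest point per bin index
    nearest = np.empty(len(bins))
    nearest[order] = np.repeat(dist[order][first], np.diff(
        np.append(np.where(first)[0], len(bins))))
    hidden = dist > nearest + 0.02 * height
    drop = hidden & (rng.uniform(size=len(bins)) < factor)
    keep = ~drop
    if keep.sum() < 2:
        keep[:] = True
    return keep


def generate_plant(spec: PlantSpec) -> LabeledPointCloud:
    """Generate one labeled plant cloud; byte-identical for identical spec+seed."""
    rng = np.random.default_rng(spec.seed)
    height = spec.derived_height()
    stage_f = (spec.stage - 1) / 11.0
    axis = _stem_axis(rng, height)

    stem_radius = 0.003 + 0.009 * (height / 1.2)
    # close-range scans resolve small seedlings much finer than tall
    # canopies; stems lose effective density fastest (thin, self-occluded)
    stem_density = spec.points_per_area * (0.8 - 0.35 * stage_f)
    leaf_density = spec.points_per_area * (6.0 - 5.2 * stage_f)

    parts_xyz: list[np.ndarray] = []
    parts_lab: list[np.ndarray] = []

    # main stem
    stem_area = height * 2 * np.pi * stem_radius
    n_stem = max(60, int(stem_area * stem_density))
    t = rng.uniform(0, 1, n_stem)
    theta = rng.uniform(0, 2 * np.pi, n_stem)
    pts = axis(t)
    pts[:, 0] += stem_radius * np.cos(theta)
    pts[:, 1] += stem_radius * np.sin(theta)
    parts_xyz.append(pts)
    parts_lab.append(np.ones(n_stem, dtype=np.int64))

    # branches
    n_branches = spec.n_branches if spec.n_branches is not None else max(
        0, (spec.stage - 2) // 2)
    for _ in range(n_branches):
        t0 = rng.uniform(0.25, 0.85)
        p0 = axis(t0)[0]
        azb = rng.uniform(0, 2 * np.pi)
        blen = 0.18 * height * rng.uniform(0.7, 1.3)
        p1 = p0 + blen * np.array([np.cos(azb) * 0.8, np.sin(azb) * 0.8, 0.6])
        br = stem_radius * 0.6
        nb = max(25, int(blen * 2 * np.pi * br * stem_density))
        parts_xyz.append(_tube(rng, p0, p1, br, nb))
        parts_lab.append(np.ones(nb, dtype=np.int64))

    # leaves
    n_leaves = spec.derived_n_leaves()
    per_node = {"soybean_like": 3, "maize_like": 1, "tomato_like": 5}[spec.crop]
    n_nodes = max(1, n_leaves // per_node)
    # canopy closure: with growth the foliage concentrates toward the top,
    # so several leaves share each coarse voxel (overlap and occlusion)
    # seedlings carry their few leaves near the apex on short petioles;
    # with growth, foliage spreads down and outward along the stem
    node_lo = 0.55 - 0.37 * stage_f
    node_ts = np.linspace(node_lo, 0.98, n_nodes)
    petiole_scale = 0.35 + 1.0 * stage_f
    leaf_count = 0
    for node_i, tn in enumerate(node_ts):
        attach = axis(tn)[0]
        base_az = rng.uniform(0, 2 * np.pi)
        for k in range(per_node):
            if leaf_count >= n_leaves:
                break
            leaf_count += 1
            azimuth = base_az + k * 2 * np.pi / per_node + rng.normal(0, 0.3)
            if spec.crop == "maize_like":
                a = (0.16 + 0.22 * stage_f) * height * spec.leaf_scale
                b = 0.018 * height * spec.leaf_scale + 0.004
                bend = -rng.uniform(0.3, 0.6) * a
                tilt = np.deg2rad(rng.uniform(25, 60))
                petiole = 0.1 * a
            elif spec.crop == "tomato_like":
                a = (0.015 + 0.022 * stage_f + 0.008 * spec.stage / 12) * spec.leaf_scale * (
                    1 + 0.5 * height)
                b = 0.7 * a
                bend = rng.uniform(-0.4, 0.4) * a
                tilt = np.deg2rad(rng.uniform(10, 70))
                petiole = rng.uniform(1.0, 2.5) * a
            else:  # soybean_like trifoliate leaflets
                a = (0.020 + 0.045 * stage_f) * spec.leaf_scale * (1 + 0.3 * rng.uniform())
                b = 0.65 * a
                bend = rng.uniform(0.1, 0.5) * a
                tilt = np.deg2rad(rng.uniform(10, 50))
                petiole = rng.uniform(1.2, 2.2) * a * petiole_scale
            # canopy densification: per-leaf sampling density spreads out with
            # stage (upper canopy denser), driving the KNN-density CV upward
            # over the growth cycle as in real multi-view reconstructions
            sd = 0.4 * stage_f
            dens_mult = np.exp(rng.normal(0.0, sd) - sd ** 2 / 2)
            area = np.pi * a * b
            m = max(25, int(area * leaf_density * dens_mult))
            local = _ellipse_patch(rng, m, a, b, bend)
            rot = _rotation(azimuth, tilt)
            centre = attach + rot @ np.array([petiole + a, 0.0, 0.0])
            parts_xyz.append(local @ rot.T + centre)
            parts_lab.append(np.zeros(m, dtype=np.int64))

    # reproductive-stage pod clusters: tiny, geometrically tight structures
    # that scanners resolve at far higher local point density than foliage.
    # They sit at stem nodes (labeled stem) and dominate the upper tail of
    # the KNN-density distribution in late clouds.
    if spec.crop == "soybean_like" and spec.stage >= 7:
        n_pods = spec.stage - 6
        pod_density = 40.0 * spec.points_per_area
        for _ in range(n_pods):
            tp = rng.uniform(0.3, 0.95)
            azp = rng.uniform(0, 2 * np.pi)
            centre = axis(tp)[0] + np.array(
                [np.cos(azp), np.sin(azp), -0.4]) * 0.018
            ap, bp = 0.007, 0.0028
            area = 4 * np.pi * ((ap * bp + ap * bp + bp * bp) / 3)
            npod = max(40, int(area * pod_density))
            u = rng.normal(size=(npod, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pod = u * np.array([ap, bp, bp])
            rotp = _rotation(rng.uniform(0, 2 * np.pi),
                             np.deg2rad(rng.uniform(40, 80)))
            parts_xyz.append(pod @ rotp.T + centre)
            parts_lab.append(np.ones(npod, dtype=np.int64))

    coords = np.concatenate(parts_xyz)
    labels = np.concatenate(parts_lab)
    coords = coords + rng.normal(0, spec.noise_sd, coords.shape)
    keep = _occlude(coords, rng, spec.occlusion_factor, height)
    coords, labels = coords[keep], labels[keep]
    perm = rng.permutation(coords.shape[0])
    return LabeledPointCloud(
        coords=coords[perm], labels=labels[perm],
        name=f"{spec.crop}_c{spec.cultivar_id}_s{spec.stage:02d}_seed{spec.seed}")


def generate_dataset(crop: str = "soybean_like", n_cultivars: int = 5,
                     stages: int | list[int] = 12, plants_per_cell: int = 1,
                     seed: int = 0, out_dir: str | Path | None = None,
                     points_per_area: float = 40_000.0,
                     ) -> tuple[list[dict], list[LabeledPointCloud]]:
    """A cultivar x stage x replicate grid of plants.

    Cultivars differ by systematic height and leaf-size offsets. Returns the
    manifest (one JSON-serializable record per cloud) and the clouds in the
    same order; with ``out_dir`` given, clouds are also written as PLY and the
    manifest records their paths.
    """
    if n_cultivars < 1:
        raise ValueError("n_cultivars must be >= 1")
    stage_list = list(range(1, stages + 1)) if isinstance(stages, int) else list(stages)
    manifest: list[dict] = []
    clouds: list[LabeledPointCloud] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for cv in range(n_cultivars):
        height_scale = 1.0 + 0.07 * (cv - (n_cultivars - 1) / 2.0)
        leaf_scale = 1.0 + 0.10 * (cv - (n_cultivars - 1) / 2.0)
        for stage in stage_list:
            for rep in range(plants_per_cell):
                plant_seed = (seed * 1_000_003 + cv * 10_007
                              + stage * 101 + rep) % (2 ** 31)
                spec = PlantSpec(crop=crop, stage=stage,
                                 points_per_area=points_per_area,
                                 cultivar_id=cv, height_scale=height_scale,
                                 leaf_scale=leaf_scale, seed=plant_seed)
                cloud = generate_plant(spec)
                rec = {"crop": crop, "cultivar": cv, "stage": stage,
                       "plant_id": f"c{cv}r{rep}", "seed": plant_seed,
                       "n_points": cloud.n_points, "path": None}
                if out_dir is not None:
                    path = out_dir / f"{cloud.name}.ply"
                    write_point_cloud(cloud, path)
                    rec["path"] = str(path)
                manifest.append(rec)
                clouds.append(cloud)
    return manifest, clouds


def density_profile(cloud: LabeledPointCloud, n_bins: int = 10,
                    k: int = 16) -> dict:
    """KNN-density summary per vertical bin plus the overall density CV.

    Used to check generator realism: late-stage canopies should show a much
    larger density CV than seedlings.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    from .dmss import knn_density_stats

    stats = knn_density_stats(cloud, k=k)
    z = cloud.coords[:, 2]
    edges = np.linspace(z.min(), z.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        rho = stats.rho[mask]
        rows.append({
            "bin": b, "z_lo": float(edges[b]), "z_hi": float(edges[b + 1]),
            "n": int(mask.sum()),
            "median_rho": float(np.median(rho)) if mask.any() else np.nan,
            "q25_rho": float(np.quantile(rho, 0.25)) if mask.any() else np.nan,
            "q75_rho": float(np.quantile(rho, 0.75)) if mask.any() else np.nan,
        })
    return {"bins": rows, "cv_d": stats.cv_d}
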