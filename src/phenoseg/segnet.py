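"""Geometry-aware multi-scale point-transformer operators and model assembly.

The segmentation network is an encoder–decoder over an irregular point set:

- **Multi-scale neighborhood aggregation**: for each point, ball-query
  neighborhoods at three radii (fractions of the plant height, defaults
  0.05 / 0.10 / 0.15) are aggregated with per-scale shared MLPs ``phi_s``
  applied to ``[f_j - f_i; psi_ij]``, where ``psi_ij`` is a learned embedding
  of the relative position ``(p_j - p_i, ||p_j - p_i||)``. Aggregation is an
  attention-weighted sum whose weights are the distance kernel below; the
  three per-scale outputs are concatenated.
- **Geometry-aware attention**: neighbor weights ``a_ij = softmax_j(-d_ij /
  sigma)`` so nearer points receive larger prior weights; the attended
  feature is ``sum_j a_ij f_j``.
- **Fusion**: channel concatenation of the multi-scale and geometry branches
  followed by a linear map ``W_f``.
- **TransitionDown / TransitionUp**: farthest-point sampling with local
  max-pooling on the way down; inverse-square-distance interpolation on the
  way up, with skip connections fused by concatenation + geometry attention.
- A baseline scalar self-attention layer (``q.k`` softmax over neighbors)
  doubles as the ``baseline_pt`` ablation path.

FPS inside the network starts from the lexicographically smallest point so
inference is deterministic and stable under permutations of the input order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import autograd as ag
from .autograd import Tensor
from .dmss import farthest_point_sample

_ABLATIONS = ("full", "no_geometry_attention", "no_multiscale", "baseline_pt")


@dataclass
class SegNetConfig:
    """Architecture knobs. ``radii`` are fractions of the plant height."""

    radii: tuple[float, float, float] = (0.05, 0.10, 0.15)
    max_neighbors: int = 32
    knn_k_attention: int = 16
    channels: tuple[int, ...] = (32, 64, 128, 256)
    n_stages: int = 4
    down_ratio: float = 0.25
    sigma_mode: str = "radius"  # sigma tied to the scale's effective radius
    sigma_fixed: float = 0.1
    n_classes: int = 2
    ablation: str = "full"
    k_interp: int = 3
    psi_width: int = 8

    def __post_init__(self) -> None:
        if list(self.radii) != sorted(self.radii) or len(set(self.radii)) != len(self.radii):
            raise ValueError("radii must be strictly increasing")
        if not (0 < self.down_ratio <= 1):
            raise ValueError("down_ratio must be in (0, 1]")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.ablation not in _ABLATIONS:
            raise ValueError(f"ablation must be one of {_ABLATIONS}")
        if len(self.channels) < self.n_stages:
            raise ValueError(
                f"need at least n_stages={self.n_stages} channel widths, "
                f"got {len(self.channels)}")


@dataclass
class NeighborhoodIndex:
    """Ragged neighborhoods flattened to edge arrays.

    Edge ``e`` connects center ``center_ids[seg[e]]`` to point
    ``neighbors[e]``; ``offsets[e] = p_neighbor - p_center``.
    """

    center_ids: np.ndarray     # (n_centers,) point indices of the query points
    seg: np.ndarray            # (E,) segment id per edge, in [0, n_centers)
    neighbors: np.ndarray      # (E,) point indices
    offsets: np.ndarray        # (E, 3)
    dists: np.ndarray          # (E,)
    n_centers: int


@dataclass
class AttentionLayerParams:
    """Plain-array parameters for the operator-level API.

    MLPs are lists of ``(W, b)`` layer pairs applied with ReLU between
    layers (none after the last).
    """

    Wq: np.ndarray | None = None
    Wk: np.ndarray | None = None
    Wv: np.ndarray | None = None
    psi_mlp: list[tuple[np.ndarray, np.ndarray]] | None = None
    phi_mlps: list[list[tuple[np.ndarray, np.ndarray]]] | None = None
    Wf: np.ndarray | None = None
    bf: np.ndarray | None = None
    sigma: float = 0.1


@dataclass
class FeatureMap:
    """Per-level point set with features; ``provenance`` indexes the parent level."""

    level: int
    coords: np.ndarray
    features: np.ndarray
    provenance: np.ndarray | None = None


# ------------------------------------------------------------- neighborhoods

def ball_query(coords: np.ndarray, centers: np.ndarray, radius: float,
               max_neighbors: int = 32) -> NeighborhoodIndex:
    """Up to ``max_neighbors`` points within ``radius`` of each center,
    nearest-first; the center itself is always included (and is the sole
    neighbor when the ball is otherwise empty or the cap is 1)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(coords, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.int64)
    tree = cKDTree(coords)
    lists = tree.query_ball_point(coords[centers], r=radius)
    seg, nbr = [], []
    for c, raw in enumerate(lists):
        ci = centers[c]
        cand = np.asarray([j for j in raw if j != ci], dtype=np.int64)
        if cand.size:
            d = np.linalg.norm(coords[cand] - coords[ci], axis=1)
            order = np.lexsort((cand, d))  # nearest-first, ties by index
            cand = cand[order][:max(0, max_neighbors - 1)]
        chosen = np.concatenate(([ci], cand))
        seg.append(np.full(chosen.size, c, dtype=np.int64))
        nbr.append(chosen)
    seg = np.concatenate(seg)
    nbr = np.concatenate(nbr)
    offsets = coords[nbr] - coords[centers[seg]]
    return NeighborhoodIndex(center_ids=centers, seg=seg, neighbors=nbr,
                             offsets=offsets,
                             dists=np.linalg.norm(offsets, axis=1),
                             n_centers=centers.size)


def knn_query(coords: np.ndarray, centers: np.ndarray, k: int) -> NeighborhoodIndex:
    """K-nearest-neighbor neighborhoods (self included)."""
    coords = np.asarray(coords, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.int64)
    k_eff = min(k, coords.shape[0])
    tree = cKDTree(coords)
    d, idx = tree.query(coords[centers], k=k_eff)
    if k_eff == 1:
        d, idx = d[:, None], idx[:, None]
    seg = np.repeat(np.arange(centers.size), k_eff)
    nbr = idx.ravel()
    offsets = coords[nbr] - coords[centers[seg]]
    return NeighborhoodIndex(center_ids=centers, seg=seg, neighbors=nbr,
                             offsets=offsets, dists=d.ravel(),
                             n_centers=centers.size)


def geo_weights(neigh: NeighborhoodIndex, sigma: float) -> np.ndarray:
    """Per-edge attention weights ``softmax_j(-d_ij / sigma)`` within each
    neighborhood; rows (per center) sum to 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    scores = -neigh.dists / sigma
    seg_max = np.full(neigh.n_centers, -np.inf)
    np.maximum.at(seg_max, neigh.seg, scores)
    e = np.exp(scores - seg_max[neigh.seg])
    denom = np.zeros(neigh.n_centers)
    np.add.at(denom, neigh.seg, e)
    return e / denom[neigh.seg]


# --------------------------------------------------------------- operators

def _mlp_np(layers: list[tuple[np.ndarray, np.ndarray]], x: np.ndarray) -> np.ndarray:
    for i, (w, b) in enumerate(layers):
        x = x @ w + b
        if i < len(layers) - 1:
            x = np.maximum(x, 0.0)
    return x


def positional_embedding(offsets: np.ndarray,
                         params: AttentionLayerParams) -> np.ndarray:
    """``psi_ij = psi_mlp([dp_ij; ||dp_ij||])`` — depends only on relative
    positions, hence translation-invariant."""
    offsets = np.asarray(offsets, dtype=np.float64)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    norms = np.linalg.norm(offsets, axis=1, keepdims=True)
    return _mlp_np(params.psi_mlp, np.concatenate([offsets, norms], axis=1))


def geometry_attention(neigh: NeighborhoodIndex, features: np.ndarray,
                       sigma: float) -> np.ndarray:
    """Distance-kernel attention: ``x_geo(i) = sum_j softmax_j(-d_ij/sigma) f_j``."""
    w = geo_weights(neigh, sigma)
    out = np.zeros((neigh.n_centers, features.shape[1]))
    np.add.at(out, neigh.seg, w[:, None] * features[neigh.neighbors])
    return out


def baseline_self_attention(features: np.ndarray, neigh: NeighborhoodIndex,
                            params: AttentionLayerParams) -> np.ndarray:
    """Scalar dot-product self-attention over each neighborhood:
    ``q = Wq x``, ``k = Wk x``, ``v = Wv x``; weights = softmax_j(q_i . k_j);
    output = sum_j weight * v_j."""
    q = features @ params.Wq
    k = features @ params.Wk
    v = features @ params.Wv
    if q.shape[1] != k.shape[1]:
        raise ValueError("Wq and Wk output widths differ")
    scores = np.sum(q[neigh.center_ids[neigh.seg]] * k[neigh.neighbors], axis=1)
    seg_max = np.full(neigh.n_centers, -np.inf)
    np.maximum.at(seg_max, neigh.seg, scores)
    e = np.exp(scores - seg_max[neigh.seg])
    denom = np.zeros(neigh.n_centers)
    np.add.at(denom, neigh.seg, e)
    w = e / denom[neigh.seg]
    out = np.zeros((neigh.n_centers, v.shape[1]))
    np.add.at(out, neigh.seg, w[:, None] * v[neigh.neighbors])
    return out


def multiscale_aggregate(coords: np.ndarray, features: np.ndarray,
                         support: np.ndarray, params: AttentionLayerParams,
                         config: SegNetConfig,
                         plant_height: float) -> np.ndarray:
    """Per-scale message passing ``phi_s([f_j - f_i; psi_ij])`` aggregated by
    the distance-kernel attention weights, concatenated across scales."""
    radii = config.radii if config.ablation != "no_multiscale" else (config.radii[1],)
    outs = []
    for s, r in enumerate(radii):
        r_eff = r * plant_height
        neigh = ball_query(coords, support, r_eff, config.max_neighbors)
        psi = positional_embedding(neigh.offsets, params)
        msg_in = np.concatenate(
            [features[neigh.neighbors] - features[neigh.center_ids[neigh.seg]],
             psi], axis=1)
        phi = params.phi_mlps[s]
        if phi[0][0].shape[0] != msg_in.shape[1]:
            raise ValueError(
                f"phi_mlps[{s}] expects input width {phi[0][0].shape[0]}, "
                f"got {msg_in.shape[1]}")
        msg = _mlp_np(phi, msg_in)
        sigma = r_eff if config.sigma_mode == "radius" else config.sigma_fixed
        w = geo_weights(neigh, sigma)
        h = np.zeros((neigh.n_centers, msg.shape[1]))
        np.add.at(h, neigh.seg, w[:, None] * msg)
        outs.append(h)
    return np.concatenate(outs, axis=1)


def fuse_features(x_multi: np.ndarray, x_geo: np.ndarray,
                  params: AttentionLayerParams) -> np.ndarray:
    """Channel concatenation followed by the linear fusion map ``W_f``."""
    if x_multi.shape[0] != x_geo.shape[0]:
        raise ValueError("x_multi and x_geo must align point-for-point")
    cat = np.concatenate([x_multi, x_geo], axis=1)
    if params.Wf.shape[0] != cat.shape[1]:
        raise ValueError(
            f"Wf expects input width {params.Wf.shape[0]}, got {cat.shape[1]}")
    out = cat @ params.Wf
    if params.bf is not None:
        out = out + params.bf
    return out


def canonical_fps(coords: np.ndarray, m: int) -> np.ndarray:
    """FPS starting from the lexicographically smallest point — deterministic
    and invariant to the input point order (up to exact distance ties)."""
    start = int(np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))[0])
    return farthest_point_sample(coords, m, start=start)


def transition_down(fm: FeatureMap, config: SegNetConfig,
                    plant_height: float | None = None,
                    phi: list[tuple[np.ndarray, np.ndarray]] | None = None
                    ) -> FeatureMap:
    """Encoder down-sampling: FPS support at ``down_ratio``, features
    max-pooled over each support point's ball neighborhood after an optional
    pointwise map ``phi`` (identity when omitted)."""
    m = max(1, int(round(config.down_ratio * fm.coords.shape[0])))
    support = canonical_fps(fm.coords, m)
    h = plant_height if plant_height is not None else (
        fm.coords[:, 2].max() - fm.coords[:, 2].min() or 1.0)
    neigh = ball_query(fm.coords, support, config.radii[1] * h,
                       config.max_neighbors)
    feats = fm.features if phi is None else _mlp_np(phi, fm.features)
    pooled = np.full((neigh.n_centers, feats.shape[1]), -np.inf)
    np.maximum.at(pooled, neigh.seg, feats[neigh.neighbors])
    return FeatureMap(level=fm.level + 1, coords=fm.coords[support],
                      features=pooled, provenance=support)


def interp_weights(coarse_coords: np.ndarray, fine_coords: np.ndarray,
                   k: int = 3, eps: float = 1e-8
                   ) -> tuple[np.ndarray, np.ndarray]:
    """k-NN inverse-square-distance interpolation stencil: indices (M, k) into
    the coarse set and weights (M, k) summing to 1 per fine point."""
    if coarse_coords.shape[0] == 0:
        raise ValueError("coarse point set is empty")
    k_eff = min(k, coarse_coords.shape[0])
    tree = cKDTree(coarse_coords)
    d, idx = tree.query(fine_coords, k=k_eff)
    if k_eff == 1:
        d, idx = d[:, None], idx[:, None]
    w = 1.0 / (d ** 2 + eps)
    return idx, w / w.sum(axis=1, keepdims=True)


def transition_up(coarse: FeatureMap, fine_coords: np.ndarray,
                  k_interp: int = 3) -> np.ndarray:
    """Decoder up-sampling: distance-weighted interpolation of coarse features
    onto the fine point set (a fine point coincident with a coarse point
    recovers that coarse feature)."""
    if k_interp < 1:
        raise ValueError("k_interp must be >= 1")
    idx, w = interp_weights(coarse.coords, np.asarray(fine_coords), k_interp)
    return np.einsum("mk,mkc->mc", w, coarse.features[idx])


# ----------------------------------------------------------------- model

class _MLP:
    """Trainable MLP registered into a model's parameter dict."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 name: str, params: dict[str, Tensor]):
        self.layers: list[tuple[Tensor, Tensor]] = []
        for i, (win, wout) in enumerate(zip(widths[:-1], widths[1:])):
            w = ag.parameter((win, wout), rng=rng)
            b = ag.parameter(np.zeros(wout))
            params[f"{name}.W{i}"] = w
            params[f"{name}.b{i}"] = b
            self.layers.append((w, b))

    def __call__(self, x: Tensor) -> Tensor:
        for i, (w, b) in enumerate(self.layers):
            x = ag.add(ag.matmul(x, w), b)
            if i < len(self.layers) - 1:
                x = ag.relu(x)
        return x

    def as_np(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(w.value, b.value) for w, b in self.layers]


class SegModel:
    """Encoder–decoder point-segmentation model.

    Built by :func:`build_model`; call :meth:`forward` for a differentiable
    pass or :func:`forward_segment` for inference on a cloud.
    """

    def __init__(self, config: SegNetConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        c = config.channels
        n = config.n_stages
        if config.ablation == "baseline_pt":
            self.embed = _MLP([3, c[0]], rng, "embed", self.params)
            for layer in range(2):
                for nm, width in (("Wq", c[0]), ("Wk", c[0]), ("Wv", c[0])):
                    self.params[f"attn{layer}.{nm}"] = ag.parameter(
                        (c[0], width), rng=rng)
            self.head = _MLP([c[0], c[0], config.n_classes], rng, "head",
                             self.params)
            return
        n_scales = 1 if config.ablation == "no_multiscale" else len(config.radii)
        self.embed = _MLP([3, c[0]], rng, "embed", self.params)
        self.enc_psi: list[_MLP] = []
        self.enc_phi: list[list[_MLP]] = []
        self.enc_fuse: list[_MLP] = []
        self.enc_geo_proj: list[_MLP | None] = []
        self.enc_down: list[_MLP | None] = []
        self.dec_fuse: list[_MLP] = []
        self.dec_geo_proj: list[_MLP | None] = []
        geo = config.ablation != "no_geometry_attention"
        for l in range(n):
            cl = c[l]
            self.enc_psi.append(_MLP([4, config.psi_width, config.psi_width],
                                     rng, f"enc{l}.psi", self.params))
            self.enc_phi.append([
                _MLP([cl + config.psi_width, cl, cl], rng,
                     f"enc{l}.phi{s}", self.params)
                for s in range(n_scales)])
            self.enc_geo_proj.append(
                _MLP([cl, cl], rng, f"enc{l}.geo_proj", self.params)
                if geo else None)
            self.enc_fuse.append(_MLP([(n_scales + 1) * cl, cl], rng,
                                      f"enc{l}.fuse", self.params))
            self.enc_down.append(
                _MLP([cl, c[l + 1]], rng, f"enc{l}.down", self.params)
                if l < n - 1 else None)
        for l in range(n - 2, -1, -1):
            self.dec_fuse.append(_MLP([c[l + 1] + c[l], c[l]], rng,
                                      f"dec{l}.fuse", self.params))
            self.dec_geo_proj.append(
                _MLP([c[l], c[l]], rng, f"dec{l}.geo_proj", self.params)
                if geo else None)
        self.head = _MLP([c[0], c[0], config.n_classes], rng, "head",
                         self.params)

    # -- helpers ----------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params.values()))

    def _sigma(self, r_eff: float) -> float:
        return r_eff if self.config.sigma_mode == "radius" else self.config.sigma_fixed

    def _geo_block(self, coords: np.ndarray, feats: Tensor, level: int,
                   proj: _MLP | None, plant_height: float) -> Tensor:
        """Geometry attention (or plain mean in the ablation) over KNN
        neighborhoods, followed by the block's projection when present."""
        neigh = knn_query(coords, np.arange(coords.shape[0]),
                          self.config.knn_k_attention)
        if proj is None:  # no_geometry_attention: unweighted mean aggregation
            counts = np.bincount(neigh.seg, minlength=neigh.n_centers).astype(float)
            w = 1.0 / counts[neigh.seg]
            return ag.segment_sum(ag.gather(feats, neigh.neighbors), neigh.seg,
                                  neigh.n_centers, weights=w)
        sigma = self._sigma(self.config.radii[1] * plant_height)
        w = geo_weights(neigh, sigma)
        att = ag.segment_sum(ag.gather(feats, neigh.neighbors), neigh.seg,
                             neigh.n_centers, weights=w)
        return ag.relu(proj(att))

    def _multiscale(self, coords: np.ndarray, feats: Tensor, level: int,
                    plant_height: float) -> Tensor:
        cfg = self.config
        radii = cfg.radii if cfg.ablation != "no_multiscale" else (cfg.radii[1],)
        support = np.arange(coords.shape[0])
        outs = []
        for s, r in enumerate(radii):
            r_eff = r * plant_height
            neigh = ball_query(coords, support, r_eff, cfg.max_neighbors)
            # offsets are expressed in plant heights so the whole forward
            # pass, like the radii, is invariant to uniform rescaling
            rel = neigh.offsets / plant_height
            psi_in = np.concatenate(
                [rel, np.linalg.norm(rel, axis=1, keepdims=True)], axis=1)
            psi = self.enc_psi[level](ag.constant(psi_in))
            fdiff = ag.sub(ag.gather(feats, neigh.neighbors),
                           ag.gather(feats, neigh.center_ids[neigh.seg]))
            msg = self.enc_phi[level][s](ag.concat([fdiff, psi], axis=1))
            w = geo_weights(neigh, self._sigma(r_eff))
            outs.append(ag.segment_sum(msg, neigh.seg, neigh.n_centers,
                                       weights=w))
        return ag.concat(outs, axis=1)

    # -- forward ----------------------------------------------------------

    def forward(self, coords: np.ndarray) -> Tensor:
        """Per-point class logits (N, n_classes) as a graph-carrying Tensor."""
        coords = np.asarray(coords, dtype=np.float64)
        n = coords.shape[0]
        cfg = self.config
        height = float(coords[:, 2].max() - coords[:, 2].min()) or 1.0
        x0 = (coords - coords.mean(axis=0)) / height
        if cfg.ablation == "baseline_pt":
            f = ag.relu(self.embed(ag.constant(x0)))
            neigh = knn_query(coords, np.arange(n), cfg.knn_k_attention)
            for layer in range(2):
                q = ag.matmul(f, self.params[f"attn{layer}.Wq"])
                k = ag.matmul(f, self.params[f"attn{layer}.Wk"])
                v = ag.matmul(f, self.params[f"attn{layer}.Wv"])
                qk = ag.rowsum(ag.mul(ag.gather(q, neigh.center_ids[neigh.seg]),
                                      ag.gather(k, neigh.neighbors)))
                w = ag.segment_softmax(qk, neigh.seg, neigh.n_centers)
                wv = ag.mul(
                    ag.Tensor(w.value[:, None], parents=[(w, lambda g: g[:, 0])]),
                    ag.gather(v, neigh.neighbors))
                f = ag.relu(ag.segment_sum(wv, neigh.seg, neigh.n_centers))
            return self.head(f)

        min_n = int(np.ceil((1.0 / cfg.down_ratio) ** (cfg.n_stages - 1)))
        if n < min_n:
            raise ValueError(
                f"cloud of {n} points is too small for n_stages={cfg.n_stages} "
                f"at down_ratio={cfg.down_ratio}; use fewer stages")
        # encoder
        level_coords = [coords]
        skips: list[Tensor] = []
        feats = ag.relu(self.embed(ag.constant(x0)))
        for l in range(cfg.n_stages):
            cur = level_coords[-1]
            x_multi = self._multiscale(cur, feats, l, height)
            x_geo = self._geo_block(cur, feats, l, self.enc_geo_proj[l], height)
            feats = ag.relu(self.enc_fuse[l](ag.concat([x_multi, x_geo], axis=1)))
            skips.append(feats)
            if l < cfg.n_stages - 1:
                m = max(1, int(round(cfg.down_ratio * cur.shape[0])))
                support = canonical_fps(cur, m)
                neigh = ball_query(cur, support, cfg.radii[1] * height,
                                   cfg.max_neighbors)
                td = ag.relu(self.enc_down[l](feats))
                feats = ag.segment_max(ag.gather(td, neigh.neighbors),
                                       neigh.seg, neigh.n_centers)
                level_coords.append(cur[support])
        # decoder
        for i, l in enumerate(range(cfg.n_stages - 2, -1, -1)):
            fine, coarse = level_coords[l], level_coords[l + 1]
            idx, w = interp_weights(coarse, fine, cfg.k_interp)
            flat = ag.gather(feats, idx.ravel())
            up = ag.segment_sum(flat, np.repeat(np.arange(fine.shape[0]),
                                                idx.shape[1]),
                                fine.shape[0], weights=w.ravel())
            feats = ag.relu(self.dec_fuse[i](ag.concat([up, skips[l]], axis=1)))
            feats = self._geo_block(fine, feats, l, self.dec_geo_proj[i], height)
        return self.head(feats)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.config.__dict__.items()}
        arrays = {f"param/{k}": p.value for k, p in self.params.items()}
        np.savez(path, __config__=np.str_(json.dumps(cfg)),
                 __seed__=np.int64(self.seed), **arrays)

    @classmethod
    def load(cls, path) -> "SegModel":
        with np.load(path) as data:
            cfg = json.loads(str(data["__config__"]))
            cfg = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in cfg.items()}
            model = cls(SegNetConfig(**cfg), seed=int(data["__seed__"]))
            for k, p in model.params.items():
                p.value = data[f"param/{k}"].copy()
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.value = state[k].copy()


def build_model(config: SegNetConfig | None = None, seed: int = 0) -> SegModel:
    """Assemble the encoder–decoder model for the given configuration."""
    return SegModel(config or SegNetConfig(), seed=seed)


def forward_segment(model: SegModel, cloud) -> tuple[np.ndarray, np.ndarray]:
    """Inference: per-point class scores (N, n_classes) and argmax labels."""
    logits = model.forward(cloud.coords).value
    return logits, np.argmax(logits, axis=1)
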