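import numpy as np
import pytest

import phenoseg.autograd as ag
from phenoseg import LabeledPointCloud, SegNetConfig, build_model, forward_segment
from phenoseg.segnet import (
    AttentionLayerParams,
    FeatureMap,
    NeighborhoodIndex,
    ball_query,
    baseline_self_attention,
    fuse_features,
    geo_weights,
    geometry_attention,
    knn_query,
    positional_embedding,
    transition_down,
    transition_up,
)

SMALL_CFG = dict(channels=(12, 16), n_stages=2, max_neighbors=12,
                 knn_k_attention=8)


def manual_neigh(center_ids, seg, neighbors, coords):
    center_ids = np.asarray(center_ids)
    seg = np.asarray(seg)
    neighbors = np.asarray(neighbors)
    offsets = coords[neighbors] - coords[center_ids[seg]]
    return NeighborhoodIndex(center_ids=center_ids, seg=seg,
                             neighbors=neighbors, offsets=offsets,
                             dists=np.linalg.norm(offsets, axis=1),
                             n_centers=len(center_ids))


class TestBallQuery:
    def test_hand_case_one_dimensional(self):
        coords = np.array([[0, 0, 0], [0.04, 0, 0], [0.2, 0, 0]])
        n = ball_query(coords, np.array([0]), radius=0.05)
        assert set(n.neighbors) == {0, 1}
        assert n.neighbors[0] == 0  # self first

    def test_tiny_radius_gives_self_only(self):
        coords = np.random.default_rng(0).normal(size=(20, 3))
        n = ball_query(coords, np.arange(20), radius=1e-9)
        assert n.seg.size == 20
        np.testing.assert_array_equal(n.neighbors, np.arange(20))

    def test_max_neighbors_one_caps_to_self(self):
        coords = np.random.default_rng(1).uniform(size=(15, 3))
        n = ball_query(coords, np.arange(15), radius=10.0, max_neighbors=1)
        np.testing.assert_array_equal(n.neighbors, np.arange(15))

    def test_all_neighbors_within_radius(self):
        coords = np.random.default_rng(2).uniform(size=(50, 3))
        n = ball_query(coords, np.arange(50), radius=0.3, max_neighbors=64)
        assert np.all(n.dists <= 0.3 + 1e-12)


class TestPositionalEmbedding:
    def test_zero_offset_zero_bias_is_zero(self):
        rng = np.random.default_rng(0)
        params = AttentionLayerParams(psi_mlp=[(rng.normal(size=(4, 6)),
                                                np.zeros(6))])
        out = positional_embedding(np.zeros((3, 3)), params)
        np.testing.assert_allclose(out, 0.0)

    def test_identity_layer_hand_case(self):
        """Single identity layer: offset (1,2,2) maps to (1,2,2,3)."""
        params = AttentionLayerParams(psi_mlp=[(np.eye(4), np.zeros(4))])
        out = positional_embedding(np.array([[1.0, 2.0, 2.0]]), params)
        np.testing.assert_allclose(out[0], [1, 2, 2, 3])

    def test_depends_only_on_offsets(self):
        # offsets are relative, so translating a cloud leaves them unchanged
        rng = np.random.default_rng(1)
        params = AttentionLayerParams(
            psi_mlp=[(rng.normal(size=(4, 8)), rng.normal(size=8)),
                     (rng.normal(size=(8, 8)), rng.normal(size=8))])
        coords = rng.normal(size=(30, 3))
        n1 = ball_query(coords, np.arange(30), 0.8)
        n2 = ball_query(coords + 5.0, np.arange(30), 0.8)
        np.testing.assert_allclose(positional_embedding(n1.offsets, params),
                                   positional_embedding(n2.offsets, params),
                                   atol=1e-10)


class TestGeometryAttention:
    def test_single_neighbor_passthrough(self):
        coords = np.array([[0, 0, 0], [1.0, 0, 0]])
        n = manual_neigh([0], [0], [1], coords)
        f = np.array([[3.0, -1.0], [10.0, 20.0]])
        np.testing.assert_allclose(geometry_attention(n, f, sigma=1.0),
                                   [[10.0, 20.0]])

    def test_equidistant_neighbors_average(self):
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0]])
        n = manual_neigh([0], [0, 0], [1, 2], coords)
        f = np.array([[0.0], [4.0], [8.0]])
        np.testing.assert_allclose(geometry_attention(n, f, 1.0), [[6.0]])

    def test_hand_softmax_case(self):
        """d = {1, 2}, sigma = 1: weights e^-1 : e^-2 = {0.7311, 0.2689};
        with scalar features {10, 20} the output is 12.689."""
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        n = manual_neigh([0], [0, 0], [1, 2], coords)
        w = geo_weights(n, sigma=1.0)
        np.testing.assert_allclose(w, [0.73105857863, 0.26894142137],
                                   atol=1e-10)
        f = np.array([[0.0], [10.0], [20.0]])
        out = geometry_attention(n, f, 1.0)
        np.testing.assert_allclose(out, [[12.6894142137]], atol=1e-9)

    def test_weights_sum_to_one_and_monotone(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(100, 3))
        n = knn_query(coords, np.arange(100), 10)
        w = geo_weights(n, sigma=0.5)
        sums = np.zeros(100)
        np.add.at(sums, n.seg, w)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
        for c in range(100):
            mask = n.seg == c
            order = np.argsort(n.dists[mask])
            assert np.all(np.diff(w[mask][order]) <= 1e-12)

    def test_huge_sigma_limit_is_uniform_mean(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(50, 3))
        f = rng.normal(size=(50, 4))
        n = knn_query(coords, np.arange(50), 8)
        out = geometry_attention(n, f, sigma=1e6)
        means = np.zeros((50, 4))
        np.add.at(means, n.seg, f[n.neighbors] / 8)
        np.testing.assert_allclose(out, means, atol=1e-4)

    def test_bad_sigma(self):
        coords = np.zeros((2, 3))
        n = manual_neigh([0], [0], [1], coords)
        with pytest.raises(ValueError):
            geometry_attention(n, np.zeros((2, 1)), sigma=0.0)


class TestBaselineAttention:
    def test_singleton_neighborhood_reduces_to_wv(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 5))
        params = AttentionLayerParams(Wq=rng.normal(size=(5, 5)),
                                      Wk=rng.normal(size=(5, 5)),
                                      Wv=rng.normal(size=(5, 5)))
        coords = rng.normal(size=(6, 3)) * 100
        n = manual_neigh(np.arange(6), np.arange(6), np.arange(6), coords)
        np.testing.assert_allclose(baseline_self_attention(x, n, params),
                                   x @ params.Wv, atol=1e-10)

    def test_identical_neighbor_features_convexity(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(size=5)
        x = np.vstack([rng.normal(size=5), shared, shared, shared])
        params = AttentionLayerParams(Wq=rng.normal(size=(5, 5)),
                                      Wk=rng.normal(size=(5, 5)),
                                      Wv=rng.normal(size=(5, 5)))
        coords = rng.normal(size=(4, 3))
        n = manual_neigh([0], [0, 0, 0], [1, 2, 3], coords)
        np.testing.assert_allclose(baseline_self_attention(x, n, params)[0],
                                   shared @ params.Wv, atol=1e-10)

    def test_hand_softmax_weights(self):
        """q.k scores {0, ln 3} give softmax weights {0.25, 0.75}."""
        x = np.array([[1.0], [0.0], [np.log(3.0)]])
        params = AttentionLayerParams(Wq=np.eye(1), Wk=np.eye(1), Wv=np.eye(1))
        coords = np.zeros((3, 3))
        n = manual_neigh([0], [0, 0], [1, 2], coords)
        out = baseline_self_attention(x, n, params)
        expected = 0.25 * 0.0 + 0.75 * np.log(3.0)
        np.testing.assert_allclose(out, [[expected]], atol=1e-12)


class TestFusion:
    def test_identity_padded_wf_is_concatenation(self):
        xm = np.arange(6.0).reshape(2, 3)
        xg = np.arange(4.0).reshape(2, 2)
        params = AttentionLayerParams(Wf=np.eye(5))
        np.testing.assert_allclose(fuse_features(xm, xg, params),
                                   np.concatenate([xm, xg], axis=1))

    def test_matches_dense_algebra_oracle(self):
        rng = np.random.default_rng(2)
        xm, xg = rng.normal(size=(7, 4)), rng.normal(size=(7, 3))
        wf = rng.normal(size=(7, 5))
        params = AttentionLayerParams(Wf=wf)
        np.testing.assert_allclose(
            fuse_features(xm, xg, params),
            np.concatenate([xm, xg], axis=1) @ wf, atol=1e-6)

    def test_mismatched_points_error(self):
        params = AttentionLayerParams(Wf=np.eye(2))
        with pytest.raises(ValueError):
            fuse_features(np.zeros((3, 1)), np.zeros((2, 1)), params)


class TestTransitions:
    def test_down_shapes_and_subset(self):
        rng = np.random.default_rng(3)
        fm = FeatureMap(level=0, coords=rng.uniform(size=(64, 3)),
                        features=rng.normal(size=(64, 6)))
        out = transition_down(fm, SegNetConfig(**SMALL_CFG, down_ratio=0.25))
        assert out.coords.shape == (16, 3)
        assert {tuple(c) for c in out.coords} <= {tuple(c) for c in fm.coords}

    def test_down_maxpool_dominates_neighbors(self):
        rng = np.random.default_rng(4)
        cfg = SegNetConfig(**SMALL_CFG, down_ratio=0.5)
        fm = FeatureMap(level=0, coords=rng.uniform(size=(40, 3)),
                        features=rng.normal(size=(40, 5)))
        out = transition_down(fm, cfg)
        # each pooled feature >= the feature of the support point itself
        for i, src in enumerate(out.provenance):
            assert np.all(out.features[i] >= fm.features[src] - 1e-12)

    def test_up_equidistant_midpoint(self):
        coarse = FeatureMap(level=1, coords=np.array([[0.0, 0, 0], [1, 0, 0]]),
                            features=np.array([[0.0], [10.0]]))
        out = transition_up(coarse, np.array([[0.5, 0, 0]]), k_interp=2)
        np.testing.assert_allclose(out, [[5.0]], atol=1e-6)

    def test_up_coincident_point_recovers_feature(self):
        coarse = FeatureMap(level=1,
                            coords=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
                            features=np.array([[1.0], [2.0], [3.0]]))
        out = transition_up(coarse, np.array([[1.0, 0, 0]]), k_interp=3)
        np.testing.assert_allclose(out, [[2.0]], atol=1e-6)

    def test_up_hand_inverse_square_case(self):
        """Coarse at x=0 (f=0) and x=1 (f=10); fine at 0.25: weights
        1/0.0625 : 1/0.5625 give a feature of 1.0."""
        coarse = FeatureMap(level=1, coords=np.array([[0.0, 0, 0], [1, 0, 0]]),
                            features=np.array([[0.0], [10.0]]))
        out = transition_up(coarse, np.array([[0.25, 0, 0]]), k_interp=2)
        np.testing.assert_allclose(out, [[1.0]], atol=1e-6)

    def test_up_then_down_on_coincident_supports(self):
        """Interpolating coarse features onto their own coordinates is the
        identity (within the 1e-8 regularizer)."""
        rng = np.random.default_rng(5)
        coarse = FeatureMap(level=1, coords=rng.uniform(size=(20, 3)),
                            features=rng.normal(size=(20, 4)))
        out = transition_up(coarse, coarse.coords, k_interp=3)
        np.testing.assert_allclose(out, coarse.features, atol=1e-5)


class TestModel:
    def test_single_stage_forward_shape(self):
        model = build_model(SegNetConfig(channels=(12,), n_stages=1,
                                         max_neighbors=8, knn_k_attention=6))
        cloud = LabeledPointCloud(
            coords=np.random.default_rng(0).uniform(size=(100, 3)))
        scores, labels = forward_segment(model, cloud)
        assert scores.shape == (100, 2) and labels.shape == (100,)

    def test_baseline_has_no_fusion_parameters(self):
        model = build_model(SegNetConfig(**SMALL_CFG, ablation="baseline_pt"))
        names = " ".join(model.params)
        for banned in ("psi", "phi", "fuse", "geo"):
            assert banned not in names
        cloud = LabeledPointCloud(
            coords=np.random.default_rng(1).uniform(size=(60, 3)))
        scores, _ = forward_segment(model, cloud)
        assert scores.shape == (60, 2)

    def test_ablations_reduce_parameter_count(self):
        base = build_model(SegNetConfig(**SMALL_CFG)).n_parameters()
        for abl in ("no_geometry_attention", "no_multiscale"):
            ablated = build_model(
                SegNetConfig(**SMALL_CFG, ablation=abl)).n_parameters()
            assert ablated < base

    def test_translation_invariance(self, seedling):
        from tests.conftest import subsample
        cloud = subsample(seedling, 150)
        model = build_model(SegNetConfig(**SMALL_CFG), seed=0)
        s1 = model.forward(cloud.coords).value
        s2 = model.forward(cloud.coords + np.array([3.0, -2.0, 7.0])).value
        np.testing.assert_allclose(s1, s2, atol=1e-5)

    def test_uniform_scaling_invariance(self, seedling):
        """Radii are fractions of plant height, so scaling the cloud scales
        the neighborhoods with it and scores are unchanged."""
        from tests.conftest import subsample
        cloud = subsample(seedling, 150)
        model = build_model(SegNetConfig(**SMALL_CFG), seed=0)
        s1 = model.forward(cloud.coords).value
        s2 = model.forward(cloud.coords * 2.0).value
        np.testing.assert_allclose(s1, s2, atol=1e-5)

    def test_permutation_stability(self, seedling):
        from tests.conftest import subsample
        cloud = subsample(seedling, 150)
        model = build_model(SegNetConfig(**SMALL_CFG), seed=0)
        s1 = model.forward(cloud.coords).value
        perm = np.random.default_rng(2).permutation(150)
        s2 = model.forward(cloud.coords[perm]).value
        np.testing.assert_allclose(s1[perm], s2, atol=1e-5)

    def test_repeat_forward_deterministic(self, seedling):
        from tests.conftest import subsample
        cloud = subsample(seedling, 120)
        model = build_model(SegNetConfig(**SMALL_CFG), seed=0)
        np.testing.assert_array_equal(model.forward(cloud.coords).value,
                                      model.forward(cloud.coords).value)

    def test_too_small_cloud_suggests_fewer_stages(self):
        model = build_model(SegNetConfig(channels=(8, 8, 8, 8), n_stages=4))
        cloud = np.random.default_rng(0).uniform(size=(10, 3))
        with pytest.raises(ValueError, match="fewer stages"):
            model.forward(cloud)

    def test_checkpoint_roundtrip(self, tmp_path, seedling):
        from tests.conftest import subsample
        cloud = subsample(seedling, 120)
        model = build_model(SegNetConfig(**SMALL_CFG), seed=3)
        path = tmp_path / "m.npz"
        model.save(path)
        loaded = type(model).load(path)
        np.testing.assert_allclose(model.forward(cloud.coords).value,
                                   loaded.forward(cloud.coords).value,
                                   atol=1e-12)


class TestAutogradCore:
    def test_gradients_match_finite_differences(self):
        """End-to-end gradient check of the model loss on a tiny cloud."""
        rng = np.random.default_rng(0)
        coords = rng.uniform(size=(30, 3))
        labels = rng.integers(0, 2, size=30)
        model = build_model(SegNetConfig(channels=(6, 8), n_stages=2,
                                         max_neighbors=6, knn_k_attention=4),
                            seed=1)

        def loss_value():
            logits = model.forward(coords)
            loss, _ = ag.softmax_cross_entropy(logits, labels)
            return loss

        logits = model.forward(coords)
        loss, grad = ag.softmax_cross_entropy(logits, labels)
        logits.backward(grad)
        eps = 1e-6
        checked = 0
        for name in ("embed.W0", "enc0.phi0.W0", "enc1.geo_proj.W0",
                     "dec0.fuse.W0", "head.W1", "enc0.psi.W0"):
            p = model.params[name]
            assert p.grad is not None, name
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + eps
            up = loss_value()
            p.value[idx] = orig - eps
            down = loss_value()
            p.value[idx] = orig
            fd = (up - down) / (2 * eps)
            assert fd == pytest.approx(p.grad[idx], rel=1e-4, abs=1e-7), name
            checked += 1
        assert checked == 6

    def test_baseline_attention_gradient(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(size=(25, 3))
        labels = rng.integers(0, 2, size=25)
        model = build_model(SegNetConfig(channels=(6,), n_stages=1,
                                         knn_k_attention=5,
                                         ablation="baseline_pt"), seed=2)
        logits = model.forward(coords)
        loss, grad = ag.softmax_cross_entropy(logits, labels)
        logits.backward(grad)
        p = model.params["attn0.Wq"]
        idx = (2, 3)
        eps = 1e-6
        orig = p.value[idx]
        p.value[idx] = orig + eps
        up, _ = ag.softmax_cross_entropy(model.forward(coords), labels)
        p.value[idx] = orig - eps
        down, _ = ag.softmax_cross_entropy(model.forward(coords), labels)
        p.value[idx] = orig
        assert (up - down) / (2 * eps) == pytest.approx(p.grad[idx],
                                                        rel=1e-4, abs=1e-7)
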