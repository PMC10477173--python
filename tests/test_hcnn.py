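import numpy as np
import pytest

from meningiodet import (
    HCNNConfig,
    PhantomSpec,
    ValidationError,
    classify,
    conv_forward,
    generate_dataset,
    load_image,
    pool_forward,
    sfcm_cluster,
    train,
)
from meningiodet.hcnn import DegenerateDataError, NotTrainedError, _fcm_memberships
from meningiodet.image_io import DatasetManifest, ManifestRecord, MENINGIOMA


class TestConfigValidation:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            HCNNConfig(conv1_kernel=4)

    def test_fuzzifier_must_exceed_one(self):
        with pytest.raises(ValidationError):
            HCNNConfig(fuzzifier_m=1.0)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValidationError):
            HCNNConfig(features=("pif", "glcm"))


class TestConvForward:
    def test_delta_kernel_is_identity_crop(self, rng):
        x = rng.integers(0, 50, size=(1, 6, 6)).astype(float)
        k = np.zeros((1, 1, 3, 3))
        k[0, 0, 1, 1] = 1.0
        out = conv_forward(x, k, np.zeros(1))
        assert np.allclose(out[0], x[0, 1:5, 1:5])

    def test_zero_input_zero_output(self):
        out = conv_forward(np.zeros((2, 5, 5)), np.ones((3, 2, 3, 3)), np.zeros(3))
        assert out.shape == (3, 3, 3) and (out == 0).all()

    def test_matches_sliding_window_oracle(self, rng):
        x = rng.normal(size=(1, 6, 6))
        w = rng.normal(size=(1, 1, 3, 3))
        b = rng.normal(size=1)
        out = conv_forward(x, w, b)
        for i in range(4):
            for j in range(4):
                acc = (x[0, i : i + 3, j : j + 3] * w[0, 0]).sum() + b[0]
                assert out[0, i, j] == pytest.approx(max(acc, 0.0), abs=1e-10)

    def test_input_smaller_than_kernel_rejected(self):
        with pytest.raises(ValidationError, match="smaller"):
            conv_forward(np.zeros((1, 2, 2)), np.ones((1, 1, 3, 3)), np.zeros(1))


class TestPoolForward:
    def test_constant_input(self):
        out = pool_forward(np.full((1, 6, 6), 2.5), size=2, mode="max")
        assert out.shape == (1, 3, 3) and (out == 2.5).all()

    def test_two_by_two_max(self):
        out = pool_forward(np.array([[[1.0, 2.0], [3.0, 4.0]]]), size=2, mode="max")
        assert out.shape == (1, 1, 1) and out[0, 0, 0] == 4.0

    def test_mean_matches_window_average_oracle(self, rng):
        x = rng.normal(size=(1, 8, 8))
        out = pool_forward(x, size=2, mode="mean")
        for i in range(4):
            for j in range(4):
                assert out[0, i, j] == pytest.approx(
                    x[0, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].mean()
                )

    def test_trailing_remainder_dropped(self, rng):
        out = pool_forward(rng.normal(size=(1, 7, 5)), size=2, mode="max")
        assert out.shape == (1, 3, 2)

    @pytest.mark.parametrize("h,w,k1,k2,s", [(40, 40, 3, 5, 2), (33, 47, 5, 7, 2), (25, 30, 3, 3, 3)])
    def test_stack_output_shape_closed_form(self, h, w, k1, k2, s, rng):
        x = rng.normal(size=(2, h, w))
        w1 = rng.normal(size=(3, 2, k1, k1))
        w2 = rng.normal(size=(4, 3, k2, k2))
        a1 = conv_forward(x, w1, np.zeros(3))
        p1 = pool_forward(a1, size=s)
        a2 = conv_forward(p1, w2, np.zeros(4))
        p2 = pool_forward(a2, size=s)
        h1, w1_ = (h - k1 + 1) // s, (w - k1 + 1) // s
        assert p2.shape == (4, (h1 - k2 + 1) // s, (w1_ - k2 + 1) // s)


class TestSFCM:
    def _two_clouds(self, rng, n=40, spread=0.3, dist=3.0):
        a = rng.normal(size=(n, 2)) * spread + [0, 0]
        b = rng.normal(size=(n, 2)) * spread + [dist, dist]
        return np.vstack([a, b]), a.mean(0), b.mean(0)

    def test_two_cloud_centroid_recovery(self, rng):
        X, mu_a, mu_b = self._two_clouds(rng)
        state = sfcm_cluster(X, config=HCNNConfig(seed=3))
        dists = [
            min(np.linalg.norm(c - mu_a), np.linalg.norm(c - mu_b))
            for c in state.centroids
        ]
        assert max(dists) < 0.5
        assert state.memberships.max(axis=1).mean() > 0.9

    def test_membership_rows_sum_to_one(self, rng):
        X, _, _ = self._two_clouds(rng)
        state = sfcm_cluster(X, config=HCNNConfig(seed=0))
        assert np.allclose(state.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert (state.memberships >= 0).all() and (state.memberships <= 1).all()

    def test_objective_trace_non_increasing(self, rng):
        X, _, _ = self._two_clouds(rng)
        state = sfcm_cluster(X, config=HCNNConfig(seed=1))
        trace = np.array(state.objective_trace)
        assert (np.diff(trace) <= 1e-9 * np.maximum(1.0, trace[:-1])).all()

    def test_spatial_q_zero_equals_plain_fcm(self, rng):
        X, _, _ = self._two_clouds(rng, n=32)
        positions = np.stack(np.unravel_index(np.arange(64), (8, 8)), axis=1)
        plain = sfcm_cluster(X, config=HCNNConfig(seed=5))
        spatial_off = sfcm_cluster(
            X, grid_positions=positions, config=HCNNConfig(seed=5, spatial_p=1.0, spatial_q=0.0)
        )
        assert np.allclose(plain.memberships, spatial_off.memberships, atol=1e-9)
        assert np.allclose(plain.centroids, spatial_off.centroids, atol=1e-9)

    def test_spatial_weighting_smooths_an_isolated_flip(self, rng):
        # one aberrant sample inside a homogeneous grid patch gets pulled
        # toward its neighbours' cluster when q > 0
        grid = np.stack(np.unravel_index(np.arange(49), (7, 7)), axis=1)
        X = np.where((grid[:, 0] < 3)[:, None], 0.0, 4.0) + rng.normal(
            scale=0.1, size=(49, 2)
        )
        flip = 10  # row 1, col 3: deep inside the low cluster
        X[flip] = [4.0, 4.0]
        plain = sfcm_cluster(X, config=HCNNConfig(seed=2))
        spatial = sfcm_cluster(X, grid_positions=grid, config=HCNNConfig(seed=2))
        lo_plain = plain.centroids.sum(axis=1).argmin()
        lo_spat = spatial.centroids.sum(axis=1).argmin()
        assert plain.memberships[flip].argmax() != lo_plain
        # neighbourhood weighting must raise the flipped sample's membership
        # in its neighbours' (low) cluster relative to plain FCM
        assert (
            spatial.memberships[flip][lo_spat]
            > plain.memberships[flip][lo_plain] * 2
        )

    def test_degenerate_identical_points_rejected(self):
        with pytest.raises(DegenerateDataError):
            sfcm_cluster(np.ones((10, 3)), config=HCNNConfig(seed=0))


def _manifest_from(manifest, label=None):
    records = manifest.records if label is None else tuple(
        r for r in manifest.records if r.label == label
    )
    return DatasetManifest(records)


class TestTrainClassify:
    def test_single_class_training_rejected(self, tiny_dataset):
        manifest, _ = tiny_dataset
        with pytest.raises(ValidationError, match="both classes"):
            train(_manifest_from(manifest, MENINGIOMA), HCNNConfig(conv1_filters=4, conv2_filters=4, epochs=1))

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            train(DatasetManifest(()), HCNNConfig(conv1_filters=4, conv2_filters=4))

    def test_untrained_model_rejected(self, tiny_dataset):
        manifest, _ = tiny_dataset
        with pytest.raises(NotTrainedError):
            classify(load_image(manifest.records[0].image_path), object())

    def test_training_is_deterministic(self, tiny_dataset):
        manifest, _ = tiny_dataset
        cfg = HCNNConfig(conv1_filters=4, conv2_filters=8, seed=7, epochs=2, embed_dim=4)
        preds = []
        for _ in range(2):
            model = train(manifest, cfg)
            preds.append(
                tuple(
                    classify(load_image(r.image_path), model).label
                    for r in manifest.subset("test").records
                )
            )
        assert preds[0] == preds[1]

    def test_membership_edge_cases_against_frozen_centroids(self, tiny_dataset):
        manifest, _ = tiny_dataset
        cfg = HCNNConfig(conv1_filters=4, conv2_filters=8, seed=7, epochs=2, embed_dim=4)
        model = train(manifest, cfg)
        from meningiodet.hcnn import embed

        e = embed(load_image(manifest.records[0].image_path), model)
        # exactly at a centroid -> that cluster dominates
        model.sfcm.centroids = np.stack([e, e + 5.0])
        res = classify(load_image(manifest.records[0].image_path), model)
        assert res.memberships[model.sfcm.cluster_to_label[0]] >= 0.5
        assert res.label == model.sfcm.cluster_to_label[0]
        # equidistant -> memberships (0.5, 0.5), tie toward lower index
        model.sfcm.centroids = np.stack([e + 3.0, e - 3.0])
        res = classify(load_image(manifest.records[0].image_path), model)
        assert res.memberships[model.sfcm.cluster_to_label[0]] == pytest.approx(0.5, abs=1e-9)
        assert res.label == model.sfcm.cluster_to_label[0]

    def test_random_filter_mode_trains_without_backprop(self, tiny_dataset):
        manifest, _ = tiny_dataset
        cfg = HCNNConfig(
            conv1_filters=4, conv2_filters=8, seed=7, train_filters="random", embed_dim=4
        )
        model = train(manifest, cfg)
        assert model.trained and model.training_loss == []

    def test_record_order_does_not_change_accuracy_much(self, tiny_dataset):
        manifest, _ = tiny_dataset
        cfg = HCNNConfig(conv1_filters=8, conv2_filters=16, seed=11, epochs=6)
        accs = []
        for order in (list(manifest.records), list(manifest.records)[::-1]):
            model = train(DatasetManifest(tuple(order)), cfg)
            test = manifest.subset("test").records
            accs.append(
                np.mean([classify(load_image(r.image_path), model).label == r.label for r in test])
            )
        assert abs(accs[0] - accs[1]) <= 0.02 + 1e-9
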