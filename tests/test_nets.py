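"""Network engine: architecture contracts, gradients, training behavior."""

import numpy as np
import pytest

from cvepkit import nets
from cvepkit.codes import build_code_bank
from cvepkit.nets import (
    PairBatch,
    TrainConfig,
    TrunkConfig,
    build_class_head,
    build_kbit_head,
    build_siamese,
    build_trunk,
    make_pairs,
    predict_classes,
    reconstruct,
    train_classifier,
    train_reconstruction,
    train_siamese,
    trunk_param_count,
)
from cvepkit.synth import EpochSet


def _epochs(data, labels):
    n = len(labels)
    return EpochSet(
        data=data, labels=np.asarray(labels),
        session_id=np.ones(n, dtype=int), subject_id=np.ones(n, dtype=int),
        fs=512.0, channel_names=tuple(f"c{i}" for i in range(data.shape[1])),
    )


class TestArchitecture:
    def test_trunk_feature_length_2016(self):
        trunk = build_trunk(n_channels=8, n_times=538)
        out = trunk.forward(np.zeros((2, 8, 538)))
        assert out.shape == (2, 2016)
        assert trunk.meta["feature_len"] == 2016  # 32 filters x 63 bins

    def test_trunk_param_counts(self):
        counts = trunk_param_count(build_trunk())
        assert counts["without_bias"] == 8640
        assert counts["with_bias"] == 8696

    def test_kbit_head_added_params(self):
        trunk = build_trunk()
        net = build_kbit_head(trunk)
        assert net.meta["head_params"] == 2016 * 63 + 63 == 127071

    def test_class_head_added_params_and_softmax(self):
        net = build_class_head(build_trunk())
        assert net.meta["head_params"] == 2016 * 6 + 6 == 12102
        probs = nets._softmax(net.forward(np.random.default_rng(0).standard_normal((3, 8, 538))))
        assert probs.shape == (3, 6)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_incompatible_resampling_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_trunk(TrunkConfig(samples_per_bit=2), K=63)

    def test_spatial_conv_collapses_channels(self):
        # the Ns x 1 spatial convolution collapses the electrode axis into
        # filter maps: with one spatial filter, 8 channels -> 1 map
        trunk = build_trunk(TrunkConfig(spatial_filters=1), n_channels=8, n_times=538)
        x = np.random.default_rng(1).standard_normal((1, 8, 538))
        h = x
        for layer in trunk.layers[:3]:  # standardize, resample, spatial conv
            h = layer.forward(h, False, np.random.default_rng(0))
        assert h.shape[1] == 1

    def test_inference_deterministic_and_permutation_equivariant(self):
        rng = np.random.default_rng(2)
        net = build_kbit_head(build_trunk(seed=5), seed=6)
        x = rng.standard_normal((6, 8, 538))
        a = net.forward(x)
        b = net.forward(x)
        assert np.array_equal(a, b)  # dropout disabled at inference
        perm = rng.permutation(6)
        assert np.allclose(net.forward(x[perm]), a[perm])

    def test_sigmoid_outputs_in_unit_interval(self, tiny_epochs):
        net = build_kbit_head(build_trunk(seed=0), seed=1)
        recon = reconstruct(net, tiny_epochs)
        assert recon.y_hat.min() >= 0.0 and recon.y_hat.max() <= 1.0
        assert recon.K == 63


class TestGradients:
    def _tiny_net(self):
        cfg = TrunkConfig(
            spatial_filters=2, temporal_kernel1=3, temporal_filters1=3,
            dropout1=0.0, temporal_kernel2=3, temporal_filters2=4,
            dropout2=0.0, samples_per_bit=4,
        )
        trunk = build_trunk(cfg, n_channels=3, n_times=20, K=4, seed=0)
        return build_kbit_head(trunk, seed=1)

    def test_backward_matches_finite_differences(self):
        """The hand-derived gradients agree with numerical differentiation."""
        net = self._tiny_net()
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 3, 20))
        t = rng.integers(0, 2, size=(2, 4)).astype(float)

        def loss():
            a = nets._sigmoid(net.forward(x))
            return float(np.mean((a - t) ** 2))

        # analytic gradients
        a = nets._sigmoid(net.forward(x))
        dz = 2.0 * (a - t) * a * (1.0 - a) / a.size
        net.backward(dz)
        eps = 1e-6
        for p, g in net.parameters():
            flat_p = p.ravel()
            flat_g = g.ravel()
            for idx in range(0, flat_p.size, max(1, flat_p.size // 5)):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                lp = loss()
                flat_p[idx] = orig - eps
                lm = loss()
                flat_p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(flat_g[idx], abs=1e-6, rel=1e-4)


class TestTrainingLoops:
    @pytest.fixture()
    def small_bank(self):
        return build_code_bank()

    def test_reconstruction_rmse_decreases(self, tiny_epochs, small_bank):
        net = build_kbit_head(build_trunk(seed=0), seed=1)
        recon0 = reconstruct(net, tiny_epochs)
        t = small_bank.codes[tiny_epochs.labels - 1]
        rmse0 = float(np.sqrt(np.mean((recon0.y_hat - t) ** 2)))
        _, hist = train_reconstruction(
            net, tiny_epochs, small_bank,
            cfg=TrainConfig(epochs=4, batch=6, seed=0),
        )
        assert len(hist) == 4  # one monitored value per epoch
        assert hist[-1] < rmse0

    def test_reconstruction_determinism(self, tiny_epochs, small_bank):
        def run():
            net = build_kbit_head(build_trunk(seed=0), seed=1)
            net, _ = train_reconstruction(
                net, tiny_epochs, small_bank,
                cfg=TrainConfig(epochs=2, batch=6, seed=9),
            )
            return np.concatenate([p.ravel() for p in net.state()])

        assert np.array_equal(run(), run())

    def test_label_outside_bank_rejected(self, small_bank):
        bad = _epochs(np.zeros((2, 8, 538)), [1, 7])
        net = build_kbit_head(build_trunk(seed=0), seed=1)
        with pytest.raises(ValueError):
            train_reconstruction(net, bad, small_bank,
                                 cfg=TrainConfig(epochs=1))

    def test_classifier_overfits_tiny_set(self, tiny_epochs):
        net = build_class_head(build_trunk(seed=0), seed=1)
        net, hist = train_classifier(
            net, tiny_epochs, cfg=TrainConfig(epochs=10, batch=6, seed=0)
        )
        labels, probs = predict_classes(net, tiny_epochs)
        assert probs.shape == (tiny_epochs.n_trials, 6)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(labels, np.argmax(probs, axis=1) + 1)
        assert np.mean(labels == tiny_epochs.labels) >= 0.95


class TestPairsAndSiamese:
    def test_balanced_pairs(self, tiny_epochs):
        pairs = make_pairs(tiny_epochs, 256, seed=0)
        assert pairs.same_class.sum() == 128
        assert pairs.same_class.size == 256

    def test_pair_seed_determinism(self, tiny_epochs):
        a = make_pairs(tiny_epochs, 64, seed=5)
        b = make_pairs(tiny_epochs, 64, seed=5)
        assert np.array_equal(a.left, b.left) and np.array_equal(a.right, b.right)

    def test_positive_pairs_share_class(self, tiny_epochs):
        pairs = make_pairs(tiny_epochs, 100, seed=1)
        same = pairs.same_class.astype(bool)
        assert np.array_equal(
            tiny_epochs.labels[pairs.left[same]],
            tiny_epochs.labels[pairs.right[same]],
        )
        assert not np.any(
            tiny_epochs.labels[pairs.left[~same]]
            == tiny_epochs.labels[pairs.right[~same]]
        )

    def test_per_class_pair_mode(self, tiny_epochs):
        pairs = make_pairs(tiny_epochs, 50, seed=2, class_k=3)
        same = pairs.same_class.astype(bool)
        assert (tiny_epochs.labels[pairs.left[same]] == 3).all()
        assert (tiny_epochs.labels[pairs.right[same]] == 3).all()
        assert (tiny_epochs.labels[pairs.left[~same]] == 3).all()
        assert (tiny_epochs.labels[pairs.right[~same]] != 3).all()

    def test_single_class_rejected(self):
        ep = _epochs(np.zeros((4, 2, 20)), [1, 1, 1, 1])
        with pytest.raises(ValueError):
            make_pairs(ep, 10, seed=0)

    def test_similarity_symmetry_and_identical_inputs(self):
        trunk = build_trunk(n_channels=3, n_times=40, K=4, seed=0)
        net = build_siamese(trunk, seed=1)
        rng = np.random.default_rng(4)
        a = rng.standard_normal((3, 3, 40))
        b = rng.standard_normal((3, 3, 40))
        s_ab = net.forward_pair(a, b)
        s_ba = net.forward_pair(b, a)
        assert np.allclose(s_ab, s_ba)
        s_aa = net.forward_pair(a, a)
        # |e - e| = 0 -> sigmoid(bias), identical for every self-pair
        assert np.allclose(s_aa, s_aa[0])

    def test_embedding_dimension_is_K(self):
        trunk = build_trunk(n_channels=8, n_times=538, K=63, seed=0)
        net = build_siamese(trunk, seed=1)
        e = net.embed.forward(np.zeros((1, 8, 538)))
        assert e.shape == (1, 63)

    def test_training_separates_high_snr_pairs(self, tiny_epochs):
        trunk = build_trunk(seed=0)
        net = build_siamese(trunk, seed=1)
        net = train_siamese(
            net, tiny_epochs,
            TrainConfig(epochs=6, batch=64, seed=0), iters_per_epoch=2,
        )
        pairs = make_pairs(tiny_epochs, 120, seed=99)
        sims = net.forward_pair(
            tiny_epochs.data[pairs.left], tiny_epochs.data[pairs.right]
        )
        acc = np.mean((sims >= 0.5) == pairs.same_class.astype(bool))
        assert acc >= 0.9


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        net = build_kbit_head(build_trunk(seed=0), seed=1)
        x = np.random.default_rng(5).standard_normal((2, 8, 538))
        before = net.forward(x)
        nets.save_model(net, tmp_path / "model")
        fresh = build_kbit_head(build_trunk(seed=42), seed=43)
        assert not np.allclose(fresh.forward(x), before)
        nets.load_model(fresh, tmp_path / "model")
        assert np.allclose(fresh.forward(x), before)
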