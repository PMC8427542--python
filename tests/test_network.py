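import numpy as np
import pytest

from phagelift.encoding import one_hot_encode
from phagelift.network import (
    BatchNormParams,
    NetworkConfig,
    batchnorm_inference,
    build_variant,
    conv1d_forward,
    dense_forward,
    dropout_train,
    forward,
    forward_batch,
    global_avg_pool,
    initialize_weights,
    load_weights,
    maxpool1d,
    relu,
    save_weights,
    sigmoid,
)

from _oracles import (
    batchnorm_ref,
    conv1d_ref,
    dense_ref,
    forward_ref,
    global_avg_pool_ref,
    maxpool1d_ref,
)
from conftest import random_onehot, random_weights


class TestScalarActivations:
    def test_relu_piecewise(self):
        assert relu(-1.0) == 0.0
        assert relu(0.0) == 0.0
        assert relu(2.5) == 2.5

    def test_sigmoid_values_and_symmetry(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(800.0) == pytest.approx(1.0)
        assert sigmoid(-800.0) == pytest.approx(0.0)
        for x in (-3.0, 0.7, 12.0):
            assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0)


class TestConv1d:
    def test_zero_weights_zero_output(self):
        X = one_hot_encode("ACGTACGT")
        out = conv1d_forward(X, np.zeros((3, 4, 4)), np.zeros(3))
        assert out.shape == (8, 3)
        assert np.all(out == 0)

    def test_motif_detector_peak(self):
        # kernel equal to the one-hot of the motif scores 6 at a perfect match
        motif = one_hot_encode("ACGTAC")
        X = one_hot_encode("ACGTACGT")
        out = conv1d_forward(X, motif[None, :, :], np.zeros(1))
        assert out[0, 0] == pytest.approx(6.0)
        assert out.max() == pytest.approx(6.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = random_onehot(40, rng)
        W = rng.normal(size=(5, 6, 4))
        b = rng.normal(size=5)
        ref = np.array(conv1d_ref(X.tolist(), W.tolist(), b.tolist()))
        np.testing.assert_allclose(conv1d_forward(X, W, b), ref, atol=1e-6)

    def test_output_length_equals_input_length(self):
        X = random_onehot(33, np.random.default_rng(1))
        out = conv1d_forward(X, np.random.default_rng(2).normal(size=(2, 6, 4)), np.zeros(2))
        assert out.shape == (33, 2)


class TestMaxpool:
    def test_worked_example(self):
        col = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])[:, None]
        np.testing.assert_array_equal(maxpool1d(col, 3, 3)[:, 0], [3.0, 6.0])

    def test_constant_channel(self):
        Y = np.full((9, 2), 7.0)
        assert np.all(maxpool1d(Y, 3, 3) == 7.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(17, 4))
        for S1, S2 in [(3, 3), (2, 3), (4, 2), (3, 1)]:
            ref = np.array(maxpool1d_ref(Y.tolist(), S1, S2))
            np.testing.assert_array_equal(maxpool1d(Y, S1, S2), ref)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            maxpool1d(np.zeros((2, 1)), 3, 3)


class TestBatchnormDropoutPoolDense:
    def test_bn_identity_params(self):
        x = np.random.default_rng(4).normal(size=(5, 3))
        bn = BatchNormParams(np.ones(3), np.zeros(3), np.zeros(3), np.ones(3))
        np.testing.assert_allclose(batchnorm_inference(x, bn, 0.0), x)

    def test_bn_centering_returns_shift(self):
        mean = np.array([1.0, -2.0])
        bn = BatchNormParams(np.ones(2), np.array([5.0, 6.0]), mean, np.ones(2))
        np.testing.assert_allclose(batchnorm_inference(mean, bn, 0.0), [5.0, 6.0])

    def test_bn_matches_formula_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 3))
        bn = BatchNormParams(rng.normal(size=3), rng.normal(size=3),
                             rng.normal(size=3), rng.random(3) + 0.1)
        ref = np.array(batchnorm_ref(x.tolist(), bn.gamma.tolist(), bn.beta.tolist(),
                                     bn.running_mean.tolist(), bn.running_var.tolist(), 1e-3))
        np.testing.assert_allclose(batchnorm_inference(x, bn, 1e-3), ref, atol=1e-10)

    def test_dropout_p0_identity(self):
        x = np.random.default_rng(6).normal(size=(10, 3))
        out, mask = dropout_train(x, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, x)
        assert np.all(mask == 1)

    def test_dropout_empirical_fraction(self):
        x = np.ones((300, 300))
        out, mask = dropout_train(x, 0.3, np.random.default_rng(7))
        assert abs(1 - mask.mean() - 0.3) < 0.02
        # kept entries rescaled by 1/(1-P)
        kept = out[mask == 1]
        np.testing.assert_allclose(kept, 1 / 0.7)

    def test_dropout_invalid_p(self):
        with pytest.raises(ValueError):
            dropout_train(np.ones(3), 1.0, np.random.default_rng(0))

    def test_global_pool_constant_and_oracle(self):
        assert global_avg_pool(np.full((7, 2), 2.0)).tolist() == [2.0, 2.0]
        Y = np.random.default_rng(8).normal(size=(6, 3))
        np.testing.assert_allclose(global_avg_pool(Y), global_avg_pool_ref(Y.tolist()))

    def test_dense_zero_weights(self):
        x = np.random.default_rng(9).normal(size=4)
        np.testing.assert_array_equal(dense_forward(x, np.zeros((3, 4)), np.zeros(3), "relu"), 0)
        assert dense_forward(x, np.zeros((1, 4)), np.zeros(1), "sigmoid")[0] == 0.5

    def test_dense_matches_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=5)
        W = rng.normal(size=(3, 5))
        b = rng.normal(size=3)
        for act in ("relu", "sigmoid", "linear"):
            ref = dense_ref(x.tolist(), W.tolist(), b.tolist(), act)
            np.testing.assert_allclose(dense_forward(x, W, b, act), ref, atol=1e-9)


class TestForward:
    def test_zero_weights_score_half(self):
        config = NetworkConfig(L=30, F=4, M=3, R=5)
        w = initialize_weights(config, np.random.default_rng(0))
        w.conv_W[:] = 0
        w.dense1_W[:] = 0
        w.dense2_W[:] = 0
        X = one_hot_encode("ACGTACGATT" * 3)
        assert forward(config, w, X) == pytest.approx(0.5)

    def test_inference_deterministic(self):
        config = NetworkConfig(L=50, F=6, M=4)
        rng = np.random.default_rng(1)
        w = random_weights(config, rng)
        X = random_onehot(50, rng)
        assert forward(config, w, X) == forward(config, w, X)

    def test_score_in_open_interval(self):
        config = NetworkConfig(L=40, F=3, M=5)
        rng = np.random.default_rng(2)
        for _ in range(10):
            w = random_weights(config, rng)
            s = forward(config, w, random_onehot(40, rng))
            assert 0.0 < s < 1.0

    def test_matches_monolithic_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            config = NetworkConfig(L=int(rng.integers(20, 60)), F=int(rng.integers(2, 6)),
                                   M=int(rng.integers(2, 7)))
            w = random_weights(config, rng)
            X = random_onehot(config.L, rng)
            assert forward(config, w, X) == pytest.approx(
                forward_ref(config, w, X.tolist()), abs=1e-8
            )

    def test_batch_forward_agrees_with_single(self):
        config = NetworkConfig(L=60, F=5, M=6)
        rng = np.random.default_rng(4)
        w = random_weights(config, rng)
        X = np.stack([random_onehot(60, rng) for _ in range(7)])
        batch = forward_batch(config, w, X)
        singles = [forward(config, w, X[i]) for i in range(7)]
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_train_mode_dropout_scales(self):
        config = NetworkConfig(L=30, F=4, M=3, P=0.5)
        rng = np.random.default_rng(5)
        w = random_weights(config, rng)
        X = random_onehot(30, rng)
        s1 = forward(config, w, X, mode="train", rng=np.random.default_rng(0))
        s2 = forward(config, w, X, mode="train", rng=np.random.default_rng(0))
        assert s1 == s2  # same rng seed, same mask
        assert 0.0 < s1 < 1.0


class TestVariants:
    def test_full_has_eight_layers_in_order(self):
        layers = build_variant(NetworkConfig(L=400))
        assert layers == ("conv1d", "maxpool", "bn1", "dropout",
                          "globalpool", "dense1", "bn2", "dense2")

    def test_no_dropout_matches_full_at_inference(self):
        rng = np.random.default_rng(6)
        full = NetworkConfig(L=40, F=4, M=3)
        nodrop = NetworkConfig(L=40, F=4, M=3, variant="no_dropout")
        w = random_weights(full, rng)
        X = random_onehot(40, rng)
        assert forward(full, w, X) == pytest.approx(forward(nodrop, w, X))

    def test_kmer4_input_dimension(self):
        config = NetworkConfig(L=400, variant="kmer4")
        assert config.dense1_input_dim == 256
        w = initialize_weights(config, np.random.default_rng(7))
        assert w.dense1_W.shape == (64, 256)
        assert w.conv_W is None

    def test_no_globalpool_flattens(self):
        config = NetworkConfig(L=30, F=3, M=4, variant="no_globalpool")
        assert config.dense1_input_dim == config.pooled_length * 3
        w = random_weights(config, np.random.default_rng(8))
        s = forward(config, w, random_onehot(30, np.random.default_rng(9)))
        assert 0.0 < s < 1.0

    def test_no_bn_has_no_bn_layers(self):
        config = NetworkConfig(L=30, F=3, M=4, variant="no_bn")
        assert "bn1" not in config.layers and "bn2" not in config.layers
        w = initialize_weights(config, np.random.default_rng(10))
        assert w.bn1 is None and w.bn2 is None

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(L=400, variant="no_conv")


class TestWeightArchive:
    def test_roundtrip_identity(self, tmp_path):
        config = NetworkConfig(L=40, F=3, M=5, R=7)
        w = random_weights(config, np.random.default_rng(11))
        path = tmp_path / "w.npz"
        save_weights(w, config, path)
        w2, config2 = load_weights(path)
        assert config2 == config
        np.testing.assert_array_equal(w.conv_W, w2.conv_W)
        np.testing.assert_array_equal(w.dense1_W, w2.dense1_W)
        np.testing.assert_array_equal(w.bn1.running_var, w2.bn1.running_var)
        assert w.dense2_b == w2.dense2_b

    def test_corrupted_file_errors(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"not an archive")
        with pytest.raises(ValueError):
            load_weights(path)

    def test_scores_survive_roundtrip(self, tmp_path):
        config = NetworkConfig(L=50, F=4, M=6)
        rng = np.random.default_rng(12)
        w = random_weights(config, rng)
        X = random_onehot(50, rng)
        path = tmp_path / "w.npz"
        save_weights(w, config, path)
        w2, config2 = load_weights(path)
        assert forward(config, w, X) == forward(config2, w2, X)
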