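"""Model family: shape arithmetic, layer semantics, freezing, determinism."""

import numpy as np
import pytest

from snnface.architectures import (
    LRN,
    MaxPool,
    ModelConfig,
    PRESETS,
    build_model,
    compute_layer_shapes,
    preset,
)
from snnface.filter_banks import enumerate_dog_bank, enumerate_gabor_bank
from snnface.training import initialize_weights


@pytest.fixture(scope="module")
def dog_bank():
    return enumerate_dog_bank()


@pytest.fixture(scope="module")
def small_snn(dog_bank):
    # reduced input keeps forward passes fast; all layer semantics identical
    m = build_model(preset("snn", input_size=63), dog_bank)
    initialize_weights(m, 0)
    return m


class TestLayerShapes:
    def test_snn_chain_matches_published_architecture(self):
        s = compute_layer_shapes(preset("snn"))
        assert s["conv1"] == (32, 55, 55)
        assert s.units("conv1") == 96_800
        assert s["pool1"] == (32, 14, 14)
        assert s.units("pool1") == 6_272
        assert s["pool2"] == (64, 4, 4)
        assert s["fc1"] == (32,)
        assert s["fc2"] == (7,)

    def test_narrow_pooling_resolution(self):
        # ceil((55-3)/2)+1 = 27, evaluated by hand
        s = compute_layer_shapes(preset("narrow-pooling"))
        assert s["pool1"] == (32, 27, 27)

    def test_all_presets_terminate_in_seven_classes(self):
        for name in PRESETS:
            s = compute_layer_shapes(preset(name))
            assert s["fc2"] == (7,)
            assert all(all(d > 0 for d in shape) for shape in s.shapes.values())

    def test_collapsing_config_rejected_with_layer_name(self):
        with pytest.raises(ValueError, match="pool2"):
            compute_layer_shapes(preset("snn", input_size=23))


class TestBuildModel:
    def test_conv1_holds_bank_and_is_frozen(self, small_snn, dog_bank):
        assert not small_snn.layer("conv1").trainable
        trainable_names = {l.name for l in small_snn.trainable_layers()}
        assert "conv1" not in trainable_names
        assert trainable_names == {"conv2", "fc1", "fc2"}

    def test_add_layer_has_two_extra_convolutions(self, dog_bank):
        shallow = build_model(preset("snn", input_size=63), dog_bank)
        deep = build_model(preset("add-layer", input_size=63), dog_bank)
        n_conv = lambda m: sum(l.name.startswith("conv") for l in m.layers)
        assert n_conv(deep) == n_conv(shallow) + 2
        assert {l.name for l in deep.trainable_layers()} == {
            "conv1b", "conv2", "conv2b", "fc1", "fc2",
        }

    def test_bank_family_mismatch_rejected(self):
        with pytest.raises(ValueError, match="famil"):
            build_model(preset("snn", input_size=63), enumerate_gabor_bank())

    def test_wrong_bank_size_rejected(self, dog_bank):
        with pytest.raises(ValueError):
            build_model(preset("snn", input_size=63), dog_bank[:16])


class TestForward:
    def test_probabilities_sum_to_one(self, small_snn):
        x = np.random.default_rng(0).random((3, 63, 63, 3)).astype(np.float32)
        probs, _ = small_snn.forward(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_wrong_input_shape_rejected(self, small_snn):
        with pytest.raises(ValueError, match="expected batch"):
            small_snn.forward(np.zeros((2, 64, 64, 3), np.float32))

    def test_on_off_pairs_are_negatives_pre_relu(self, small_snn):
        # constant-gray input: paired ON/OFF DoG channels mirror each other
        x = np.full((1, 63, 63, 3), 0.5, np.float32)
        conv1 = small_snn.layer("conv1")
        out = conv1.forward(small_snn._check_batch(x))
        # bank ordering alternates ON/OFF within each parameter combination
        np.testing.assert_allclose(out[0, 0], -out[0, 1], atol=1e-5)

    def test_evaluation_forward_is_deterministic(self, small_snn):
        x = np.random.default_rng(1).random((2, 63, 63, 3)).astype(np.float32)
        p1, _ = small_snn.forward(x)
        p2, _ = small_snn.forward(x)
        np.testing.assert_array_equal(p1, p2)

    def test_relu_records_are_non_negative(self, small_snn):
        x = np.random.default_rng(2).random((2, 63, 63, 3)).astype(np.float32)
        _, rec = small_snn.forward(x, record=["relu1", "relu_fc1"])
        assert (rec["relu1"] >= 0).all()
        assert (rec["relu_fc1"] >= 0).all()

    def test_fc_widths(self, small_snn):
        assert small_snn.layer("fc1").W.shape[1] == 32
        assert small_snn.layer("fc2").W.shape == (32, 7)


class TestMaxPool:
    def test_matches_brute_force_with_overhang(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        pool = MaxPool("p", window=5, stride=4)
        out = pool.forward(x)
        # brute force: ceil mode pads with -inf where windows overhang
        ho = wo = int(np.ceil((8 - 5) / 4)) + 1
        assert out.shape == (1, 2, ho, wo)
        for c in range(2):
            for i in range(ho):
                for j in range(wo):
                    window = x[0, c, 4 * i : 4 * i + 5, 4 * j : 4 * j + 5]
                    assert out[0, c, i, j] == window.max()

    @pytest.mark.parametrize("window,stride", [(5, 4), (3, 2), (5, 2)])
    def test_all_pooling_geometries_match_brute_force(self, window, stride):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 1, 11, 11)).astype(np.float32)
        out = MaxPool("p", window, stride).forward(x)
        expected_size = int(np.ceil((11 - window) / stride)) + 1
        assert out.shape[-1] == expected_size
        for i in range(expected_size):
            for j in range(expected_size):
                win = x[0, 0, stride * i : stride * i + window, stride * j : stride * j + window]
                assert out[0, 0, i, j] == win.max()


class TestLRN:
    def test_zero_input_gives_zero_output(self):
        lrn = LRN("l")
        x = np.zeros((1, 8, 3, 3), np.float32)
        np.testing.assert_array_equal(lrn.forward(x), x)

    def test_single_active_channel_scalar_value(self):
        # 1/(1 + 2e-5·1)^0.75, evaluated by hand
        lrn = LRN("l", k=1.0, n=5, alpha=2e-5, beta=0.75)
        x = np.zeros((1, 8, 1, 1), np.float32)
        x[0, 3] = 1.0
        out = lrn.forward(x)
        assert out[0, 3, 0, 0] == pytest.approx((1 + 2e-5) ** -0.75, rel=1e-6)

    def test_pure_cross_channel_operation(self):
        # spatial positions are normalized independently and identically
        rng = np.random.default_rng(5)
        col = rng.normal(size=(1, 8, 1, 1)).astype(np.float32)
        tiled = np.tile(col, (1, 1, 4, 4))
        out = LRN("l").forward(tiled)
        np.testing.assert_allclose(out, np.tile(out[:, :, :1, :1], (1, 1, 4, 4)), atol=1e-7)

    def test_window_truncated_at_boundaries(self):
        lrn = LRN("l", k=1.0, n=5, alpha=1.0, beta=1.0)
        x = np.ones((1, 8, 1, 1), np.float32)
        out = lrn.forward(x)[0, :, 0, 0]
        # edge channel sees 3 neighbors, center channels see 5
        assert out[0] == pytest.approx(1 / (1 + 3.0))
        assert out[4] == pytest.approx(1 / (1 + 5.0))


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, dog_bank):
        from snnface.training import cross_entropy

        cfg = ModelConfig(input_size=47, depth="deep", dropout_rate=0.0)
        m = build_model(cfg, dog_bank)
        initialize_weights(m, 1)
        rng = np.random.default_rng(2)
        x = rng.random((2, 47, 47, 3)).astype(np.float32)
        y = np.array([1, 4])

        def loss_fn():
            return cross_entropy(m.logits(x, train=True, rng=np.random.default_rng(0)), y)

        _, dl = loss_fn()
        m.backward(dl, start=m.first_trainable_index())
        for lyr in m.trainable_layers():
            idx = tuple(rng.integers(0, s) for s in lyr.W.shape)
            eps = 1e-3
            old = lyr.W[idx]
            lyr.W[idx] = old + eps
            lp, _ = loss_fn()
            lyr.W[idx] = old - eps
            lm, _ = loss_fn()
            lyr.W[idx] = old
            num = (lp - lm) / (2 * eps)
            assert lyr.dW[idx] == pytest.approx(num, rel=0.05, abs=2e-4), lyr.name


class TestSerialization:
    def test_weight_roundtrip_through_npz(self, dog_bank, tmp_path):
        a = build_model(preset("snn", input_size=63), dog_bank)
        initialize_weights(a, 3)
        path = tmp_path / "weights.npz"
        a.save_weights(path)
        b = build_model(preset("snn", input_size=63), dog_bank)
        initialize_weights(b, 4)
        b.load_weights(path)
        x = np.random.default_rng(0).random((2, 63, 63, 3)).astype(np.float32)
        np.testing.assert_array_equal(a.forward(x)[0], b.forward(x)[0])
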