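"""Network architecture contracts and the NumPy layer toolkit."""

import numpy as np
import pytest

from veinroi import nn
from veinroi.network import (NetworkConfig, build_model, forward, load_weights,
                             save_weights, summarize)


@pytest.fixture(scope="module")
def improved():
    return build_model(NetworkConfig(input_size=(64, 64), seed=3))


class TestLayers:
    """Adjoint/gradient correctness of the individual layers."""

    @pytest.mark.parametrize("stride,pad_mode", [(1, "zeros"), (2, "zeros"),
                                                 (1, "edge"), (2, "edge")])
    def test_conv_adjoint(self, stride, pad_mode, rng):
        c = nn.Conv2d(3, 5, 3, stride=stride, pad_mode=pad_mode,
                      rng=np.random.default_rng(0))
        c.b.v[...] = 0.0
        x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        y = c.forward(x, train=True)
        w = rng.standard_normal(y.shape).astype(np.float32)
        dx = c.backward(w)
        assert float((y * w).sum()) == pytest.approx(float((x * dx).sum()), rel=1e-4)

    def test_conv_weight_gradient(self, rng):
        c = nn.Conv2d(2, 3, 3, rng=np.random.default_rng(1))
        x = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
        y = c.forward(x, train=True)
        c.backward(np.ones_like(y))
        idx = (1, 0, 2, 2)
        eps = 1e-3
        old = c.W.v[idx]
        c.W.v[idx] = old + eps
        up = c.forward(x).sum()
        c.W.v[idx] = old - eps
        dn = c.forward(x).sum()
        c.W.v[idx] = old
        assert c.W.g[idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-2)

    def test_bilinear_up_shapes_and_adjoint(self, rng):
        up = nn.BilinearUp2()
        x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        y = up.forward(x, train=True)
        assert y.shape == (2, 3, 16, 16)
        w = rng.standard_normal(y.shape).astype(np.float32)
        dx = up.backward(w)
        assert float((y * w).sum()) == pytest.approx(float((x * dx).sum()), rel=1e-4)

    def test_bilinear_preserves_constants(self):
        up = nn.BilinearUp2()
        x = np.full((1, 1, 6, 6), 3.0, dtype=np.float32)
        assert np.allclose(up.forward(x), 3.0, atol=1e-6)

    def test_maxpool_backward_routes_to_argmax(self):
        mp = nn.MaxPool2()
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        y = mp.forward(x, train=True)
        assert np.array_equal(y[0, 0], [[5, 7], [13, 15]])
        dx = mp.backward(np.ones_like(y))
        assert dx.sum() == 4
        assert dx[0, 0, 1, 1] == 1 and dx[0, 0, 0, 0] == 0

    def test_transposed_conv_shapes(self, rng):
        tc = nn.ConvTranspose2d(4, 6, rng=np.random.default_rng(2))
        x = rng.standard_normal((2, 4, 5, 5)).astype(np.float32)
        y = tc.forward(x, train=True)
        assert y.shape == (2, 6, 10, 10)
        dx = tc.backward(np.ones_like(y))
        assert dx.shape == x.shape


class TestArchitecture:
    def test_output_shape_matches_input(self):
        for variant in ("improved", "vanilla_unet", "improved_no_shortcut",
                        "improved_transposed"):
            m = build_model(NetworkConfig(input_size=(64, 64), variant=variant))
            out = m.forward(np.zeros((1, 1, 64, 64), np.float32))
            assert out.shape == (1, 4, 64, 64)

    def test_bottleneck_is_one_sixteenth(self):
        m = build_model(NetworkConfig(input_size=(128, 128)))
        m.forward(np.zeros((1, 1, 128, 128), np.float32))
        assert m.bottleneck_hw == (8, 8)

    def test_input_size_must_be_divisible_by_16(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_size=(100, 100))

    def test_wrong_input_size_rejected(self, improved):
        with pytest.raises(ValueError):
            improved.forward(np.zeros((1, 1, 32, 32), np.float32))

    def test_forward_finite_and_deterministic(self, improved, rng):
        x = rng.random((2, 1, 64, 64)).astype(np.float32)
        y1 = improved.forward(x)
        y2 = improved.forward(x)
        assert np.isfinite(y1).all()
        assert np.array_equal(y1, y2)
        y0 = improved.forward(np.zeros_like(x))
        assert np.isfinite(y0).all()

    def test_forward_helper_single_image(self, improved, rng):
        img = rng.random((64, 64))
        out = forward(improved, img)
        assert out.shape == (4, 64, 64)

    def test_gradient_reaches_stem(self, improved, rng):
        x = rng.random((2, 1, 64, 64)).astype(np.float32)
        for p in improved.params():
            p.g[...] = 0.0
        y = improved.forward(x, train=True)
        improved.backward(np.ones_like(y))
        stem_grad = np.abs(improved.stem_params()[0].g).sum()
        assert stem_grad > 0


class TestSummary:
    def test_parameter_budget(self):
        s = summarize(build_model(NetworkConfig()))
        sv = summarize(build_model(NetworkConfig(variant="vanilla_unet")))
        assert s.parameter_count * 10 < sv.parameter_count
        assert 0.8e6 <= s.serialized_size_fp32 <= 1.6e6
        assert s.serialized_size_fp32 == 4 * s.parameter_count

    def test_no_shortcut_has_fewer_parameters(self):
        s = summarize(build_model(NetworkConfig()))
        sn = summarize(build_model(NetworkConfig(variant="improved_no_shortcut")))
        assert sn.parameter_count < s.parameter_count

    def test_stem_hand_count(self):
        # 3x3 convs 1->20->10 with biases: 20*(9+1) + 10*(20*9+1) = 2010
        s = summarize(build_model(NetworkConfig()))
        assert s.stem_parameter_count == 2010

    def test_flops_scale_with_area(self):
        f64 = summarize(build_model(NetworkConfig(input_size=(64, 64)))).flops_per_forward
        f128 = summarize(build_model(NetworkConfig(input_size=(128, 128)))).flops_per_forward
        assert f128 == pytest.approx(4 * f64, rel=0.01)


def test_save_load_round_trip(tmp_path, improved, rng):
    x = rng.random((1, 1, 64, 64)).astype(np.float32)
    y1 = improved.forward(x)
    save_weights(improved, tmp_path / "m.npz")
    other = build_model(NetworkConfig(input_size=(64, 64), seed=99))
    load_weights(other, tmp_path / "m.npz")
    assert np.array_equal(other.forward(x), y1)
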