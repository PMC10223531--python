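"""Divergence and coordinate losses, their bounds and gradients."""

import numpy as np
import pytest

from veinroi import heatmaps as hm
from veinroi import losses as L


def random_dist(rng, n=32):
    p = rng.random(n) + 1e-6
    return p / p.sum()


class TestKL:
    def test_self_divergence_zero(self, rng):
        for _ in range(10):
            p = random_dist(rng)
            assert L.kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_known_value(self):
        assert L.kl_divergence([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2))

    def test_nonnegative_and_asymmetric(self, rng):
        asym = False
        for _ in range(50):
            p, q = random_dist(rng), random_dist(rng)
            kpq, kqp = L.kl_divergence(p, q), L.kl_divergence(q, p)
            assert kpq >= 0 and kqp >= 0
            asym |= abs(kpq - kqp) > 1e-6
        assert asym

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            L.kl_divergence([0.5, 0.5], [0.2, 0.3, 0.5])


class TestJS:
    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            p, q = random_dist(rng), random_dist(rng)
            j1, j2 = L.js_divergence(p, q), L.js_divergence(q, p)
            assert abs(j1 - j2) < 1e-12
            assert 0.0 <= j1 <= np.log(2) + 1e-12

    def test_extremes(self):
        assert L.js_divergence([1, 0], [0, 1]) == pytest.approx(np.log(2), abs=1e-9)
        p = [0.3, 0.7]
        assert L.js_divergence(p, p) == pytest.approx(0.0, abs=1e-12)


class TestHeatmapLosses:
    def make_pair(self, rng):
        kps = rng.uniform(4, 27, (4, 2))
        label = hm.encode_gaussian(kps, (32, 32), 2.0)
        pred = label + rng.normal(0, 0.1, label.shape)
        return pred, label, kps

    def test_mse_basics(self, rng):
        pred, label, _ = self.make_pair(rng)
        assert L.mse_heatmap_loss(label, label) == 0.0
        assert L.mse_heatmap_loss(label + 1.0, label) == pytest.approx(1.0)
        # naive elementwise loop oracle
        acc = 0.0
        for a, b in zip(pred.ravel(), label.ravel()):
            acc += (a - b) ** 2
        assert L.mse_heatmap_loss(pred, label) == pytest.approx(acc / pred.size)

    def test_js_heatmap_zero_and_bound(self, rng):
        pred, label, _ = self.make_pair(rng)
        assert L.js_heatmap_loss(label, label) == pytest.approx(0.0, abs=1e-12)
        assert 0.0 <= L.js_heatmap_loss(pred, label) <= np.log(2)

    def test_js_penalizes_multi_peak(self):
        """A bimodal response has larger JS loss than a matched unimodal one."""
        kps = np.array([[8.0, 8.0], [20.0, 8.0], [8.0, 20.0], [20.0, 20.0]])
        label = hm.encode_gaussian(kps, (28, 28), 1.5)
        unimodal = label.copy()
        bimodal = label.copy()
        for k in range(4):
            ghost = hm.encode_gaussian(kps[::-1], (28, 28), 1.5)
            bimodal[k] = np.maximum(bimodal[k], 0.9 * ghost[k])
        assert L.js_heatmap_loss(bimodal, label) > L.js_heatmap_loss(unimodal, label)

    def test_euclidean_loss_345(self):
        kps = np.array([[10.0, 10.0], [5.0, 5.0], [20.0, 20.0], [25.0, 12.0]])
        pred = np.zeros((4, 32, 32), dtype=float)
        for k, (x, y) in enumerate(kps):
            pred[k, int(y) + 4, int(x) + 3] = 1.0  # offset by (3, 4): distance 5
        loss = L.euclidean_coord_loss(pred, kps, hm.DecoderConfig(beta=200.0))
        assert loss == pytest.approx(5.0, abs=1e-3)

    def test_euclidean_round_trip_small(self, rng):
        pred, label, kps = self.make_pair(rng)
        assert L.euclidean_coord_loss(label, kps) < 0.5

    def test_euclidean_equals_decode_then_distance(self, rng):
        pred, _, kps = self.make_pair(rng)
        cfg = hm.DecoderConfig(beta=7.0)
        dists = []
        for ch, kp in zip(pred, kps):
            xy = np.array(hm.soft_argmax(ch, cfg))
            dists.append(np.linalg.norm(xy - kp))
        assert L.euclidean_coord_loss(pred, kps, cfg) == pytest.approx(np.mean(dists))

    def test_shape_mismatch(self, rng):
        pred, label, kps = self.make_pair(rng)
        with pytest.raises(ValueError):
            L.mse_heatmap_loss(pred[:, :16], label)
        with pytest.raises(ValueError):
            L.euclidean_coord_loss(pred[:3], kps)


class TestCombined:
    def test_perfect_prediction_near_zero(self, rng):
        kps = rng.uniform(4, 27, (4, 2))
        label = hm.encode_gaussian(kps, (32, 32), 2.0)
        lb = L.combined_loss(label, label, kps)
        assert lb.mse == 0.0 and lb.js == pytest.approx(0.0, abs=1e-12)
        assert lb.combined < 0.2  # euclidean round-trip error / 3

    def test_toggle_reduces_to_single_loss(self, rng):
        kps = rng.uniform(4, 27, (4, 2))
        label = hm.encode_gaussian(kps, (32, 32), 2.0)
        pred = label + rng.normal(0, 0.2, label.shape)
        lb = L.combined_loss(pred, label, kps, use_js=False, use_euclidean=False)
        assert lb.combined == pytest.approx(L.mse_heatmap_loss(pred, label))

    def test_combined_is_mean_of_terms(self, rng):
        kps = rng.uniform(4, 27, (4, 2))
        label = hm.encode_gaussian(kps, (32, 32), 2.0)
        pred = rng.normal(0, 1, label.shape)
        lb = L.combined_loss(pred, label, kps)
        assert np.isfinite([lb.mse, lb.js, lb.euclidean]).all()
        assert lb.combined == pytest.approx((lb.mse + lb.js + lb.euclidean) / 3)


class TestGradients:
    """Analytic gradients agree with central finite differences."""

    @pytest.mark.parametrize("term", ["mse", "js", "euclidean", "combined"])
    def test_finite_difference(self, term, rng):
        kps = rng.uniform(3, 12, (4, 2))
        label = hm.encode_gaussian(kps, (16, 16), 1.5)
        pred = rng.normal(0, 1, label.shape)
        cfg = hm.DecoderConfig(beta=4.0)
        fns = {
            "mse": (lambda p: L.mse_heatmap_loss(p, label),
                    lambda p: L.mse_heatmap_grad(p, label)),
            "js": (lambda p: L.js_heatmap_loss(p, label),
                   lambda p: L.js_heatmap_grad(p, label)),
            "euclidean": (lambda p: L.euclidean_coord_loss(p, kps, cfg),
                          lambda p: L.euclidean_coord_grad(p, kps, cfg)),
            "combined": (lambda p: L.combined_loss(p, label, kps, cfg).combined,
                         lambda p: L.combined_grad(p, label, kps, cfg)),
        }
        f, g = fns[term]
        grad = g(pred)
        for _ in range(5):
            idx = (rng.integers(4), rng.integers(16), rng.integers(16))
            eps = 1e-6
            up, down = pred.copy(), pred.copy()
            up[idx] += eps
            down[idx] -= eps
            num = (f(up) - f(down)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)
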