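"""Supervision terms for heatmap keypoint regression, with gradients.

Three losses supervise complementary aspects of the 4-channel output:

* MSE on the raw heatmaps (value agreement with the Gaussian labels);
* Jensen-Shannon divergence between softmax-normalized prediction and label
  channels (shape agreement: pushes the output toward a unimodal Gaussian
  and suppresses spurious secondary peaks);
* Euclidean distance between the Soft-argmax decoded coordinates and the
  label coordinates (direct, end-to-end differentiable localization).

The combined training loss is their unweighted average.  Natural logarithms
are used throughout, so the JS divergence is bounded by ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heatmaps import DecoderConfig, softmax_normalize

_EPS = 1e-12


@dataclass
class LossBreakdown:
    mse: float
    js: float
    euclidean: float
    combined: float


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) in nats; terms with P = 0 contribute 0, Q floored at 1e-12."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    _check_same_shape(P, Q)
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], _EPS))))


def js_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Symmetric JS(P || Q) = KL(P||M)/2 + KL(Q||M)/2 with M = (P + Q)/2."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    _check_same_shape(P, Q)
    M = 0.5 * (P + Q)
    return 0.5 * kl_divergence(P, M) + 0.5 * kl_divergence(Q, M)


def mse_heatmap_loss(pred: np.ndarray, label: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    _check_same_shape(pred, label)
    return float(np.mean((pred - label) ** 2))


def js_heatmap_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean over channels of JS between softmax-normalized pred and label."""
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    _check_same_shape(pred, label)
    vals = [js_divergence(softmax_normalize(p), softmax_normalize(q))
            for p, q in zip(pred.reshape(pred.shape[0], -1),
                            label.reshape(label.shape[0], -1))]
    return float(np.mean(vals))


def _soft_coords(channel: np.ndarray, beta: float):
    """Soft-argmax internals shared by the loss and its gradient."""
    h, w = channel.shape
    z = beta * (channel - channel.max())
    p = np.exp(z)
    p /= p.sum()
    cx = float((p.sum(axis=0) * np.arange(w)).sum())
    cy = float((p.sum(axis=1) * np.arange(h)).sum())
    return p, cx, cy


def euclidean_coord_loss(pred: np.ndarray, label_keypoints: np.ndarray,
                         config: DecoderConfig | None = None) -> float:
    """Mean distance (px) between Soft-argmax decodes and label coordinates."""
    pred = np.asarray(pred, dtype=np.float64)
    if pred.ndim != 3 or pred.shape[0] != 4:
        raise ValueError(f"expected a (4, H, W) stack, got {pred.shape}")
    config = config or DecoderConfig()
    kps = np.asarray(label_keypoints, dtype=float)
    dists = []
    for ch, (lx, ly) in zip(pred, kps):
        beta = config.effective_beta(ch)
        _, cx, cy = _soft_coords(ch, beta)
        dists.append(np.hypot(cx - lx, cy - ly))
    return float(np.mean(dists))


def combined_loss(pred: np.ndarray, label: np.ndarray,
                  label_keypoints: np.ndarray,
                  config: DecoderConfig | None = None,
                  use_mse: bool = True, use_js: bool = True,
                  use_euclidean: bool = True) -> LossBreakdown:
    """All three supervision terms and the mean of the enabled ones."""
    terms = []
    mse = js = euc = 0.0
    if use_mse:
        mse = mse_heatmap_loss(pred, label)
        terms.append(mse)
    if use_js:
        js = js_heatmap_loss(pred, label)
        terms.append(js)
    if use_euclidean:
        euc = euclidean_coord_loss(pred, label_keypoints, config)
        terms.append(euc)
    if not terms:
        raise ValueError("at least one loss term must be enabled")
    return LossBreakdown(mse=mse, js=js, euclidean=euc,
                         combined=float(np.mean(terms)))


# ---------------------------------------------------------------------------
# gradients w.r.t. the predicted stack (for end-to-end training)


def mse_heatmap_grad(pred: np.ndarray, label: np.ndarray) -> np.ndarray:
    return (2.0 / pred.size) * (pred - label)


def js_heatmap_grad(pred: np.ndarray, label: np.ndarray) -> np.ndarray:
    """d js_heatmap_loss / d pred.

    Per channel, with p = softmax(pred), q = softmax(label), m = (p + q)/2:
    dJS/dp_i = log(p_i / m_i) / 2, pulled back through the softmax Jacobian.
    """
    out = np.empty_like(pred, dtype=np.float64)
    n_ch = pred.shape[0]
    for k in range(n_ch):
        p = softmax_normalize(pred[k])
        q = softmax_normalize(label[k])
        m = 0.5 * (p + q)
        g = 0.5 * np.log(np.maximum(p, _EPS) / np.maximum(m, _EPS))
        out[k] = p * (g - float((p * g).sum()))
    return out / n_ch


def euclidean_coord_grad(pred: np.ndarray, label_keypoints: np.ndarray,
                         config: DecoderConfig | None = None) -> np.ndarray:
    """d euclidean_coord_loss / d pred (beta treated as a constant scale)."""
    config = config or DecoderConfig()
    out = np.zeros_like(pred, dtype=np.float64)
    kps = np.asarray(label_keypoints, dtype=float)
    n_ch = pred.shape[0]
    h, w = pred.shape[1:]
    xs = np.arange(w)
    ys = np.arange(h)
    for k in range(n_ch):
        beta = config.effective_beta(pred[k])
        p, cx, cy = _soft_coords(pred[k], beta)
        dx, dy = cx - kps[k, 0], cy - kps[k, 1]
        d = max(np.hypot(dx, dy), 1e-9)
        # dL/dc = (c - t)/d;   dc/dx through the softmax Jacobian
        hfield = (dx * xs[None, :] + dy * ys[:, None]) / d
        out[k] = beta * p * (hfield - float((p * hfield).sum()))
    return out / n_ch


def combined_grad(pred: np.ndarray, label: np.ndarray,
                  label_keypoints: np.ndarray,
                  config: DecoderConfig | None = None,
                  use_mse: bool = True, use_js: bool = True,
                  use_euclidean: bool = True) -> np.ndarray:
    grads = []
    if use_mse:
        grads.append(mse_heatmap_grad(pred, label))
    if use_js:
        grads.append(js_heatmap_grad(pred, label))
    if use_euclidean:
        grads.append(euclidean_coord_grad(pred, label_keypoints, config))
    if not grads:
        raise ValueError("at least one loss term must be enabled")
    return np.mean(grads, axis=0)


# ---------------------------------------------------------------------------
# batched fast path used by the training loop (same math, flattened batch)


def batch_combined(pred: np.ndarray, label: np.ndarray, keypoints: np.ndarray,
                   beta: float, use_mse: bool = True, use_js: bool = True,
                   use_euclidean: bool = True):
    """Loss breakdown and gradient for a (N, 4, H, W) batch in one pass.

    Returns (LossBreakdown of batch means, grad w.r.t. pred).  The MSE and
    JS terms equal the batch mean of the per-sample functions; the Euclidean
    term decodes with the windowed Soft-argmax used at inference (beta <= 0
    selects the window-adaptive sharpening) rather than the global Eq.-style
    softmax, whose floor pins the expectation to the grid center on
    mostly-empty maps.
    """
    n, c, h, w = pred.shape
    p64 = pred.astype(np.float64).reshape(n * c, h * w)
    l64 = label.astype(np.float64).reshape(n * c, h * w)
    grad = np.zeros_like(p64)
    mse = js = euc = 0.0
    n_terms = 0
    if use_mse:
        diff = p64 - l64
        mse = float((diff * diff).mean())
        grad += (2.0 / (c * h * w)) * diff
        n_terms += 1
    if use_js or use_euclidean:
        z = p64 - p64.max(axis=1, keepdims=True)
        P = np.exp(z)
        P /= P.sum(axis=1, keepdims=True)
    if use_js:
        zq = l64 - l64.max(axis=1, keepdims=True)
        Q = np.exp(zq)
        Q /= Q.sum(axis=1, keepdims=True)
        M = 0.5 * (P + Q)
        logPM = np.log(np.maximum(P, _EPS) / np.maximum(M, _EPS))
        logQM = np.log(np.maximum(Q, _EPS) / np.maximum(M, _EPS))
        js = float(np.mean((0.5 * (P * logPM + Q * logQM)).sum(axis=1)))
        g = 0.5 * logPM
        gj = P * (g - (P * g).sum(axis=1, keepdims=True))
        grad += gj / c
        n_terms += 1
    if use_euclidean:
        # differentiable "distance to the argmax index": Soft-argmax refined
        # inside a window around each channel's maximum (a global softmax over
        # a mostly-empty map is pinned to the grid center by its floor)
        r = 4  # 9x9 window
        kf = keypoints.reshape(n * c, 2)
        euc_sum = 0.0
        ge = np.zeros_like(grad)
        maps = p64.reshape(n * c, h, w)
        for row in range(n * c):
            m = maps[row]
            flat = int(np.argmax(m))
            ay, ax = divmod(flat, w)
            y0, y1 = max(0, ay - r), min(h, ay + r + 1)
            x0, x1 = max(0, ax - r), min(w, ax + r + 1)
            sub = m[y0:y1, x0:x1]
            b_eff = beta if beta > 0 else 10.0 / max(float(np.ptp(sub)), 1e-8)
            z = b_eff * (sub - sub.max())
            S = np.exp(z)
            S /= S.sum()
            xs = np.arange(x0, x1, dtype=np.float64)
            ys = np.arange(y0, y1, dtype=np.float64)
            cx = float((S.sum(axis=0) * xs).sum())
            cy = float((S.sum(axis=1) * ys).sum())
            dx, dy = cx - kf[row, 0], cy - kf[row, 1]
            d = max(np.hypot(dx, dy), 1e-9)
            euc_sum += d
            hf = (dx * xs[None, :] + dy * ys[:, None]) / d
            gsub = b_eff * S * (hf - float((S * hf).sum()))
            ge.reshape(n * c, h, w)[row, y0:y1, x0:x1] = gsub
        euc = euc_sum / (n * c)
        grad += ge / c
        n_terms += 1
    if n_terms == 0:
        raise ValueError("at least one loss term must be enabled")
    terms = [v for v, on in ((mse, use_mse), (js, use_js), (euc, use_euclidean)) if on]
    breakdown = LossBreakdown(mse=mse, js=js, euclidean=euc,
                              combined=float(np.mean(terms)))
    return breakdown, (grad / (n * n_terms)).reshape(pred.shape).astype(np.float32)
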