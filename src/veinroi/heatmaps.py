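"""Gaussian heatmap encoding and argmax / Soft-argmax decoding.

Coordinates are 0-based pixel centers, (x = column, y = row).  Label heatmaps
are unnormalized Gaussians with peak value 1 at the pixel nearest each
keypoint; divergence losses turn them into probability fields with
:func:`softmax_normalize` first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DecoderConfig:
    """Soft-argmax settings.

    beta is the inverse temperature of the sharpened softmax; ``None`` selects
    an adaptive beta = 10 / std(channel), which keeps the sharpening
    scale-free across raw-output magnitudes.

    window controls stack decoding: the expectation is refined inside a
    window x window patch around the hard argmax (the uniform softmax floor
    of a large, mostly-empty map otherwise pulls the estimate toward the grid
    center).  ``None`` decodes over the full map.
    """

    beta: float | None = None
    window: int | None = 9

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.window is not None and (self.window < 3 or self.window % 2 == 0):
            raise ValueError("window must be an odd integer >= 3")

    def effective_beta(self, channel: np.ndarray) -> float:
        if self.beta is not None:
            return float(self.beta)
        s = float(np.std(channel))
        return 10.0 / max(s, 1e-8)


def default_sigma(width: int) -> float:
    """Label Gaussian sigma: 1/32 of the heatmap width."""
    return max(width / 32.0, 1.0)


def encode_gaussian(keypoints: np.ndarray, shape: tuple[int, int],
                    sigma: float) -> np.ndarray:
    """Encode 4 keypoints as a (4, H, W) stack of Gaussians with peak 1.

    Each channel decays as exp(-r^2 / (2 sigma^2)) around its keypoint and is
    rescaled so the maximum pixel is exactly 1.  Keypoints outside the grid
    raise (no silent clipping).
    """
    kps = np.asarray(keypoints, dtype=float)
    if kps.shape != (4, 2):
        raise ValueError(f"expected (4, 2) keypoints, got {kps.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    h, w = shape
    if (kps[:, 0] < 0).any() or (kps[:, 0] > w - 1).any() \
            or (kps[:, 1] < 0).any() or (kps[:, 1] > h - 1).any():
        raise ValueError("keypoint outside the heatmap grid")
    ys = np.arange(h, dtype=np.float64)
    xs = np.arange(w, dtype=np.float64)
    stack = np.empty((4, h, w), dtype=np.float32)
    for k, (x, y) in enumerate(kps):
        g = np.exp(-((ys[:, None] - y) ** 2 + (xs[None, :] - x) ** 2)
                   / (2.0 * sigma ** 2))
        stack[k] = g / g.max()
    return stack


def softmax_normalize(raw_channel: np.ndarray) -> np.ndarray:
    """Turn a raw response map into a probability field (sums to 1).

    Subtracts the maximum before exponentiating, so the result is invariant
    to adding a constant to all inputs.
    """
    x = np.asarray(raw_channel, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in response map")
    e = np.exp(x - x.max())
    return e / e.sum()


def soft_argmax(raw_channel: np.ndarray,
                config: DecoderConfig | None = None) -> tuple[float, float]:
    """Differentiable decoding: expectation of the grid coordinates under the
    beta-sharpened softmax.  Returns subpixel (x, y)."""
    config = config or DecoderConfig()
    x = np.asarray(raw_channel, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in response map")
    beta = config.effective_beta(x)
    p = softmax_normalize(beta * x)
    h, w = p.shape
    col = float((p.sum(axis=0) * np.arange(w)).sum())
    row = float((p.sum(axis=1) * np.arange(h)).sum())
    return col, row


def hard_argmax(raw_channel: np.ndarray) -> tuple[int, int]:
    """(x, y) of the maximum response; ties break to the smallest row, then
    the smallest column (C-order argmax)."""
    x = np.asarray(raw_channel)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in response map")
    r, c = np.unravel_index(int(np.argmax(x)), x.shape)
    return int(c), int(r)


def _windowed_soft_argmax(channel: np.ndarray,
                          config: DecoderConfig) -> tuple[float, float]:
    cx, cy = hard_argmax(channel)
    r = config.window // 2
    h, w = channel.shape
    x0, y0 = max(0, cx - r), max(0, cy - r)
    sub = channel[y0:min(h, cy + r + 1), x0:min(w, cx + r + 1)]
    beta = config.beta if config.beta is not None else 10.0 / max(float(np.ptp(sub)), 1e-8)
    lx, ly = soft_argmax(sub, DecoderConfig(beta=beta, window=None))
    return x0 + lx, y0 + ly


def decode_stack(stack: np.ndarray, config: DecoderConfig | None = None,
                 method: str = "soft") -> tuple[np.ndarray, np.ndarray]:
    """Decode a (4, H, W) stack to keypoints and per-point confidences.

    Confidence is the peak channel value.  Coordinates are in heatmap pixels;
    multiply by the image/heatmap scale factor to reach annotation pixels.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != 4:
        raise ValueError(f"expected a (4, H, W) stack, got {stack.shape}")
    config = config or DecoderConfig()
    if method == "hard":
        decode = hard_argmax
    elif config.window is not None:
        decode = lambda ch: _windowed_soft_argmax(ch, config)  # noqa: E731
    else:
        decode = lambda ch: soft_argmax(ch, config)  # noqa: E731
    kps = np.array([decode(ch) for ch in stack], dtype=float)
    conf = stack.reshape(4, -1).max(axis=1).astype(float)
    return kps, conf
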