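"""Keypoint-detection networks.

The *improved* model is a lightweight encoder-decoder for heatmap regression
on single-channel NIR hand images:

* stem: two 3x3 convolutions (1 -> 20 -> 10 channels) with edge padding so the
  spatial size is preserved;
* encoder: four residual downsampling blocks (first conv 3x3 stride 2; the
  shortcut is a 1x1 stride-2 convolution matching channels and size, added to
  the main path), halving the resolution each time down to 1/16;
* decoder: four 2x bilinear upsampling steps; at each step a 1x1 convolution
  reduces the decoder channels and the corresponding encoder output is fused
  through its own 1x1 convolution by elementwise addition;
* head: 1x1 convolution to 4 channels (one heatmap per finger-web keypoint)
  at full input resolution.

Variants reproduce the ablation axes: ``improved_no_shortcut`` drops the
residual shortcut convolutions; ``improved_transposed`` swaps bilinear
upsampling for 2x2 stride-2 transposed convolutions; ``vanilla_unet`` is a
classic U-Net (double-conv blocks, max pooling, transposed-conv upsampling,
concatenation skips) used as the heavyweight baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

VARIANTS = ("improved", "vanilla_unet", "improved_no_shortcut", "improved_transposed")


@dataclass
class NetworkConfig:
    input_size: tuple[int, int] = (128, 128)
    stem_channels: tuple[int, int] = (20, 10)
    stage_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    variant: str = "improved"
    vanilla_base: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(f"input_size {self.input_size} must be divisible by 16")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class ModelSummary:
    parameter_count: int
    serialized_size_fp32: int
    flops_per_forward: int
    input_size: tuple[int, int]
    output_shape: tuple[int, int, int]
    stem_parameter_count: int = 0
    per_layer: dict = field(default_factory=dict)


class _ResBlock:
    """3x3 stride-2 conv -> BN -> ReLU -> 3x3 conv -> BN, plus an optional
    1x1 stride-2 shortcut, added before the final ReLU."""

    def __init__(self, cin: int, cout: int, shortcut: bool,
                 rng: np.random.Generator, name: str) -> None:
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=2, rng=rng, name=f"{name}.conv1")
        self.bn1 = nn.BatchNorm2d(cout, name=f"{name}.bn1")
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, rng=rng, name=f"{name}.conv2")
        self.bn2 = nn.BatchNorm2d(cout, name=f"{name}.bn2")
        self.short = nn.Conv2d(cin, cout, 1, stride=2, rng=rng,
                               name=f"{name}.shortcut") if shortcut else None
        self.relu2 = nn.ReLU()

    def params(self):
        ps = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.short is not None:
            ps += self.short.params()
        return ps

    def forward(self, x, train=False):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.short is not None:
            y = y + self.short.forward(x, train)
        return self.relu2.forward(y, train)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dx = 0.0
        if self.short is not None:
            dx = self.short.backward(d)
        d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        return self.conv1.backward(d) + dx

    def convs(self):
        cs = [self.conv1, self.conv2]
        if self.short is not None:
            cs.append(self.short)
        return cs


class ImprovedUNet:
    """Residual-downsampling encoder-decoder emitting a 4-channel heatmap stack."""

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.stem_channels
        st = config.stage_channels
        shortcut = config.variant != "improved_no_shortcut"
        transposed = config.variant == "improved_transposed"

        self.stem1 = nn.Conv2d(1, c1, 3, pad_mode="edge", rng=rng, name="stem.conv1")
        self.stem_relu1 = nn.ReLU()
        self.stem2 = nn.Conv2d(c1, c2, 3, pad_mode="edge", rng=rng, name="stem.conv2")
        self.stem_relu2 = nn.ReLU()

        chans = [c2, *st]
        self.blocks = [
            _ResBlock(chans[i], chans[i + 1], shortcut, rng, f"enc{i + 1}")
            for i in range(4)
        ]

        # decoder: from st[3] at 1/16 back up to c2 at full resolution
        dec_out = [st[2], st[1], st[0], c2]
        skip_ch = [st[2], st[1], st[0], c2]
        self.ups, self.reduce, self.fuse = [], [], []
        self.dec_bn, self.dec_relu = [], []
        cur = st[3]
        for i in range(4):
            if transposed:
                self.ups.append(nn.ConvTranspose2d(cur, cur, rng=rng, name=f"dec{i}.up"))
            else:
                self.ups.append(nn.BilinearUp2())
            self.reduce.append(nn.Conv2d(cur, dec_out[i], 1, rng=rng, name=f"dec{i}.reduce"))
            self.fuse.append(nn.Conv2d(skip_ch[i], dec_out[i], 1, rng=rng, name=f"dec{i}.fuse"))
            self.dec_bn.append(nn.BatchNorm2d(dec_out[i], name=f"dec{i}.bn"))
            self.dec_relu.append(nn.ReLU())
            cur = dec_out[i]
        self.head = nn.Conv2d(cur, 4, 1, rng=rng, name="head")
        self._bottleneck_hw: tuple[int, int] | None = None

    # -- introspection ------------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = self.stem1.params() + self.stem2.params()
        for b in self.blocks:
            ps += b.params()
        for i in range(4):
            if isinstance(self.ups[i], nn.ConvTranspose2d):
                ps += self.ups[i].params()
            ps += self.reduce[i].params() + self.fuse[i].params() + self.dec_bn[i].params()
        ps += self.head.params()
        return ps

    def stem_params(self) -> list[nn.Param]:
        return self.stem1.params() + self.stem2.params()

    def convs(self):
        cs = [self.stem1, self.stem2]
        for b in self.blocks:
            cs += b.convs()
        for i in range(4):
            if isinstance(self.ups[i], nn.ConvTranspose2d):
                cs.append(self.ups[i])
            cs += [self.reduce[i], self.fuse[i]]
        cs.append(self.head)
        return cs

    @property
    def bottleneck_hw(self) -> tuple[int, int] | None:
        """Spatial size of the deepest encoder output in the last forward pass."""
        return self._bottleneck_hw

    # -- computation --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        _check_input(x, self.config)
        s0 = self.stem_relu1.forward(self.stem1.forward(x, train), train)
        s0 = self.stem_relu2.forward(self.stem2.forward(s0, train), train)
        skips = [s0]
        h = s0
        for b in self.blocks:
            h = b.forward(h, train)
            skips.append(h)
        self._bottleneck_hw = h.shape[2:]
        # skip order for the decoder: enc3, enc2, enc1, stem
        use = [skips[3], skips[2], skips[1], skips[0]]
        for i in range(4):
            h = self.ups[i].forward(h, train)
            h = self.reduce[i].forward(h, train) + self.fuse[i].forward(use[i], train)
            h = self.dec_relu[i].forward(self.dec_bn[i].forward(h, train), train)
        return self.head.forward(h, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head.backward(dout)
        dskips = [None, None, None, None]  # grads for enc3, enc2, enc1, stem
        for i in range(3, -1, -1):
            d = self.dec_bn[i].backward(self.dec_relu[i].backward(d))
            dskips[i] = self.fuse[i].backward(d)
            d = self.reduce[i].backward(d)
            d = self.ups[i].backward(d)
        for j, b in enumerate(reversed(self.blocks)):  # blocks 4,3,2,1
            if j > 0:
                d = d + dskips[j - 1]
            d = b.backward(d)
        d = d + dskips[3]
        d = self.stem2.backward(self.stem_relu2.backward(d))
        d = self.stem1.backward(self.stem_relu1.backward(d))
        return d


class _DoubleConv:
    def __init__(self, cin, cout, rng, name):
        self.c1 = nn.Conv2d(cin, cout, 3, rng=rng, name=f"{name}.c1")
        self.b1 = nn.BatchNorm2d(cout, name=f"{name}.b1")
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(cout, cout, 3, rng=rng, name=f"{name}.c2")
        self.b2 = nn.BatchNorm2d(cout, name=f"{name}.b2")
        self.r2 = nn.ReLU()

    def params(self):
        return (self.c1.params() + self.b1.params()
                + self.c2.params() + self.b2.params())

    def forward(self, x, train=False):
        y = self.r1.forward(self.b1.forward(self.c1.forward(x, train), train), train)
        return self.r2.forward(self.b2.forward(self.c2.forward(y, train), train), train)

    def backward(self, dout):
        d = self.c2.backward(self.b2.backward(self.r2.backward(dout)))
        return self.c1.backward(self.b1.backward(self.r1.backward(d)))

    def convs(self):
        return [self.c1, self.c2]


class VanillaUNet:
    """Classic U-Net: double-conv stages, max-pool downsampling, transposed-conv
    upsampling and concatenation skips."""

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.vanilla_base
        ch = [b, 2 * b, 4 * b, 8 * b, 16 * b]
        self.enc = []
        cin = 1
        for i, c in enumerate(ch[:4]):
            self.enc.append(_DoubleConv(cin, c, rng, f"enc{i}"))
            cin = c
        self.pools = [nn.MaxPool2() for _ in range(4)]
        self.bottom = _DoubleConv(ch[3], ch[4], rng, "bottom")
        self.upconvs, self.dec = [], []
        cur = ch[4]
        for i in range(3, -1, -1):
            self.upconvs.append(nn.ConvTranspose2d(cur, ch[i], rng=rng, name=f"up{i}"))
            self.dec.append(_DoubleConv(2 * ch[i], ch[i], rng, f"dec{i}"))
            cur = ch[i]
        self.head = nn.Conv2d(ch[0], 4, 1, rng=rng, name="head")
        self._bottleneck_hw: tuple[int, int] | None = None

    def params(self):
        ps = []
        for e in self.enc:
            ps += e.params()
        ps += self.bottom.params()
        for u, d in zip(self.upconvs, self.dec):
            ps += u.params() + d.params()
        return ps + self.head.params()

    def convs(self):
        cs = []
        for e in self.enc:
            cs += e.convs()
        cs += self.bottom.convs()
        for u, d in zip(self.upconvs, self.dec):
            cs += [u] + d.convs()
        return cs + [self.head]

    @property
    def bottleneck_hw(self):
        return self._bottleneck_hw

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        _check_input(x, self.config)
        skips = []
        h = x
        for e, p in zip(self.enc, self.pools):
            h = e.forward(h, train)
            skips.append(h)
            h = p.forward(h, train)
        h = self.bottom.forward(h, train)
        self._bottleneck_hw = h.shape[2:]
        self._split = []
        for i in range(4):
            h = self.upconvs[i].forward(h, train)
            skip = skips[3 - i]
            self._split.append(skip.shape[1])
            h = self.dec[i].forward(np.concatenate([skip, h], axis=1), train)
        return self.head.forward(h, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head.backward(dout)
        dskips = []
        for i in range(3, -1, -1):
            d = self.dec[i].backward(d)
            c = self._split[i]
            dskips.append(d[:, :c])
            d = self.upconvs[i].backward(d[:, c:])
        d = self.bottom.backward(d)
        for j in range(3, -1, -1):
            d = self.pools[j].backward(d)
            d = d + dskips[3 - j]
            d = self.enc[j].backward(d)
        return d


def build_model(config: NetworkConfig):
    """Instantiate the network variant named in ``config``."""
    if config.variant == "vanilla_unet":
        return VanillaUNet(config)
    return ImprovedUNet(config)


def _check_input(x: np.ndarray, config: NetworkConfig) -> None:
    if x.ndim != 4 or x.shape[1] != 1:
        raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
    if tuple(x.shape[2:]) != tuple(config.input_size):
        raise ValueError(
            f"input spatial size {x.shape[2:]} != configured {config.input_size}")


def forward(model, image: np.ndarray) -> np.ndarray:
    """Inference-mode forward pass on a single [0, 1] grayscale image.

    Returns the 4-channel heatmap stack at input resolution.
    """
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    return model.forward(x, train=False)[0]


def summarize(model, input_size: tuple[int, int] | None = None) -> ModelSummary:
    """Exact parameter count, fp32 payload, and conv MAC-based FLOPs per forward."""
    cfg = model.config
    size = tuple(input_size or cfg.input_size)
    x = np.zeros((1, 1, *size), dtype=np.float32)
    out = model.forward(x, train=False)
    n_params = sum(p.size for p in model.params())
    flops = sum(c.flops() for c in model.convs())
    per_layer = {}
    for p in model.params():
        key = p.name.rsplit(".", 1)[0]
        per_layer[key] = per_layer.get(key, 0) + p.size
    stem = sum(p.size for p in model.stem_params()) if hasattr(model, "stem_params") else 0
    return ModelSummary(
        parameter_count=n_params,
        serialized_size_fp32=4 * n_params,
        flops_per_forward=flops,
        input_size=size,
        output_shape=tuple(out.shape[1:]),
        stem_parameter_count=stem,
        per_layer=per_layer,
    )


def save_weights(model, path) -> None:
    np.savez_compressed(path, **{p.name: p.v for p in model.params()},
                        **{f"__rs__{i}": np.stack([l.rm, l.rv])
                           for i, l in enumerate(_bns(model))})


def load_weights(model, path) -> None:
    data = np.load(path)
    for p in model.params():
        p.v[...] = data[p.name]
    for i, l in enumerate(_bns(model)):
        rs = data[f"__rs__{i}"]
        l.rm, l.rv = rs[0].copy(), rs[1].copy()


def _bns(model):
    seen = []
    stack = list(vars(model).values())
    while stack:
        o = stack.pop()
        if isinstance(o, nn.BatchNorm2d):
            seen.append(o)
        elif isinstance(o, (list, tuple)):
            stack.extend(o)
        elif isinstance(o, (_ResBlock, _DoubleConv)):
            stack.extend(vars(o).values())
    return seen
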