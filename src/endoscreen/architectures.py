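"""Classifier architectures: baseline CNN, ResNet50, MobileNetV2, GhostNet.

All four are expressed in the package's own layer algebra, so one code path
serves three uses: forward inference, gradient-based training, and analytic
multiply-accumulate counting by the profiler. ResNet50, MobileNetV2 and
GhostNet follow their published stage layouts with the classification head
replaced by a binary head; the baseline is six 3x3 convolution blocks
(batch norm, max-pool after every second block, dropout on the last two)
with channel widths 32-32-64-64-128-128.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

ARCH_NAMES = ("baseline_cnn", "resnet50", "mobilenet_v2", "ghostnet")


@dataclass
class ArchSpec:
    name: str = "ghostnet"
    input_size: tuple[int, int] = (224, 224)
    n_classes: int = 2
    width_multiplier: float = 1.0
    ghost_ratio: int = 2
    dropout_rate: float = 0.5

    def __post_init__(self):
        if self.name not in ARCH_NAMES:
            raise ValueError(f"unknown architecture {self.name!r}; "
                             f"choose one of {ARCH_NAMES}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.ghost_ratio < 1:
            raise ValueError("ghost_ratio must be >= 1")


def _make_divisible(v, divisor, min_value=None):
    """Round channel counts the way the mobile architectures do."""
    if min_value is None:
        min_value = divisor
    new_v = max(min_value, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def ghost_module(in_channels: int, out_channels: int, ratio: int = 2,
                 primary_kernel: int = 1, cheap_kernel: int = 3,
                 relu: bool = True, rng=None) -> nn.GhostModule:
    """Ghost convolution: ``out_channels/ratio`` intrinsic maps from a
    primary convolution plus ``(ratio-1)`` cheap depthwise-derived ghost
    maps per intrinsic map; ratio 1 degenerates to a plain convolution."""
    return nn.GhostModule(in_channels, out_channels, ratio=ratio,
                          primary_kernel=primary_kernel,
                          cheap_kernel=cheap_kernel, relu=relu, rng=rng)


def _baseline_cnn(spec: ArchSpec, rng) -> nn.Sequential:
    widths = [32, 32, 64, 64, 128, 128]
    widths = [max(2, int(round(w * spec.width_multiplier))) for w in widths]
    layers = []
    cin = 3
    for i, w in enumerate(widths):
        layers += [nn.Conv2d(cin, w, 3, bias=False, rng=rng, name=f"conv{i+1}"),
                   nn.BatchNorm2d(w), nn.ReLU()]
        if i >= 4:  # dropout on the last two convolutional blocks
            layers.append(nn.Dropout(spec.dropout_rate))
        if i % 2 == 1:
            layers.append(nn.MaxPool2d(2))
        cin = w
    layers += [nn.GlobalAvgPool(), nn.Linear(cin, spec.n_classes, rng=rng)]
    return nn.Sequential(layers, name="baseline_cnn")


def _resnet_bottleneck(cin, width, stride, rng, name):
    cout = 4 * width
    main = nn.Sequential([
        nn.Conv2d(cin, width, 1, bias=False, rng=rng, name=name + ".c1"),
        nn.BatchNorm2d(width), nn.ReLU(),
        nn.Conv2d(width, width, 3, stride=stride, bias=False, rng=rng,
                  name=name + ".c2"),
        nn.BatchNorm2d(width), nn.ReLU(),
        nn.Conv2d(width, cout, 1, bias=False, rng=rng, name=name + ".c3"),
        nn.BatchNorm2d(cout),
    ], name=name)
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = nn.Sequential([
            nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng,
                      name=name + ".down"),
            nn.BatchNorm2d(cout),
        ], name=name + ".down")
    return nn.Residual(main, shortcut, activation=nn.ReLU(), name=name)


def _resnet50(spec: ArchSpec, rng) -> nn.Sequential:
    layers = [
        nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng, name="stem"),
        nn.BatchNorm2d(64), nn.ReLU(),
        nn.MaxPool2d(3, 2, padding=1),
    ]
    cin = 64
    for s, (blocks, width) in enumerate(zip([3, 4, 6, 3], [64, 128, 256, 512])):
        for b in range(blocks):
            stride = 2 if (b == 0 and s > 0) else 1
            layers.append(_resnet_bottleneck(cin, width, stride, rng,
                                             f"layer{s+1}.{b}"))
            cin = 4 * width
    layers += [nn.GlobalAvgPool(), nn.Linear(cin, spec.n_classes, rng=rng)]
    return nn.Sequential(layers, name="resnet50")


def _inverted_residual(cin, cout, stride, expand, rng, name):
    hidden = cin * expand
    seq = []
    if expand != 1:
        seq += [nn.Conv2d(cin, hidden, 1, bias=False, rng=rng, name=name + ".exp"),
                nn.BatchNorm2d(hidden), nn.ReLU6()]
    seq += [nn.Conv2d(hidden, hidden, 3, stride=stride, groups=hidden,
                      bias=False, rng=rng, name=name + ".dw"),
            nn.BatchNorm2d(hidden), nn.ReLU6(),
            nn.Conv2d(hidden, cout, 1, bias=False, rng=rng, name=name + ".proj"),
            nn.BatchNorm2d(cout)]
    main = nn.Sequential(seq, name=name)
    if stride == 1 and cin == cout:
        return nn.Residual(main, None, None, name=name)
    return main


def _mobilenet_v2(spec: ArchSpec, rng) -> nn.Sequential:
    wm = spec.width_multiplier
    cin = _make_divisible(32 * wm, 8)
    layers = [nn.Conv2d(3, cin, 3, stride=2, bias=False, rng=rng, name="stem"),
              nn.BatchNorm2d(cin), nn.ReLU6()]
    cfg = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
           (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]
    for t, c, n, s in cfg:
        cout = _make_divisible(c * wm, 8)
        for b in range(n):
            stride = s if b == 0 else 1
            layers.append(_inverted_residual(cin, cout, stride, t, rng,
                                             f"ir{c}.{b}"))
            cin = cout
    last = _make_divisible(1280 * max(1.0, wm), 8)
    layers += [nn.Conv2d(cin, last, 1, bias=False, rng=rng, name="head_conv"),
               nn.BatchNorm2d(last), nn.ReLU6(),
               nn.GlobalAvgPool(), nn.Linear(last, spec.n_classes, rng=rng)]
    return nn.Sequential(layers, name="mobilenet_v2")


# GhostNet-1.0 stage table: kernel, expansion, output, SE flag, stride
_GHOSTNET_CFG = [
    (3, 16, 16, 0, 1),
    (3, 48, 24, 0, 2),
    (3, 72, 24, 0, 1),
    (5, 72, 40, 1, 2),
    (5, 120, 40, 1, 1),
    (3, 240, 80, 0, 2),
    (3, 200, 80, 0, 1),
    (3, 184, 80, 0, 1),
    (3, 184, 80, 0, 1),
    (3, 480, 112, 1, 1),
    (3, 672, 112, 1, 1),
    (5, 672, 160, 1, 2),
    (5, 960, 160, 0, 1),
    (5, 960, 160, 1, 1),
    (5, 960, 160, 0, 1),
    (5, 960, 160, 1, 1),
]


def _ghost_bottleneck(cin, mid, cout, kernel, stride, use_se, ratio, rng, name):
    seq = [nn.GhostModule(cin, mid, ratio=ratio, relu=True, rng=rng,
                          name=name + ".g1")]
    if stride > 1:
        seq += [nn.Conv2d(mid, mid, kernel, stride=stride, groups=mid,
                          bias=False, rng=rng, name=name + ".dw"),
                nn.BatchNorm2d(mid)]
    if use_se:
        seq.append(nn.SEBlock(mid, rng=rng, name=name + ".se"))
    seq.append(nn.GhostModule(mid, cout, ratio=ratio, relu=False, rng=rng,
                              name=name + ".g2"))
    main = nn.Sequential(seq, name=name)
    if stride == 1 and cin == cout:
        return nn.Residual(main, None, None, name=name)
    shortcut = nn.Sequential([
        nn.Conv2d(cin, cin, kernel, stride=stride, groups=cin, bias=False,
                  rng=rng, name=name + ".sdw"),
        nn.BatchNorm2d(cin),
        nn.Conv2d(cin, cout, 1, bias=False, rng=rng, name=name + ".spw"),
        nn.BatchNorm2d(cout),
    ], name=name + ".short")
    return nn.Residual(main, shortcut, None, name=name)


def _round4(v):
    return _make_divisible(v, 4)


def _ghostnet(spec: ArchSpec, rng) -> nn.Sequential:
    wm = spec.width_multiplier
    ratio = spec.ghost_ratio
    cin = _round4(16 * wm)
    layers = [nn.Conv2d(3, cin, 3, stride=2, bias=False, rng=rng, name="stem"),
              nn.BatchNorm2d(cin), nn.ReLU()]
    for i, (k, exp, out, se, s) in enumerate(_GHOSTNET_CFG):
        mid = _round4(exp * wm)
        cout = _round4(out * wm)
        if mid % ratio:
            mid += ratio - mid % ratio
        if cout % ratio:
            cout += ratio - cout % ratio
        layers.append(_ghost_bottleneck(cin, mid, cout, k, s, se, ratio, rng,
                                        f"gb{i}"))
        cin = cout
    squeeze = _round4(960 * wm)
    layers += [nn.Conv2d(cin, squeeze, 1, bias=False, rng=rng, name="squeeze"),
               nn.BatchNorm2d(squeeze), nn.ReLU(),
               nn.GlobalAvgPool(),
               nn.Linear(squeeze, 1280, rng=rng, name="head_fc"), nn.ReLU(),
               nn.Linear(1280, spec.n_classes, rng=rng, name="fc")]
    return nn.Sequential(layers, name="ghostnet")


_BUILDERS = {
    "baseline_cnn": _baseline_cnn,
    "resnet50": _resnet50,
    "mobilenet_v2": _mobilenet_v2,
    "ghostnet": _ghostnet,
}


def build_classifier(spec: ArchSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate the named architecture with a seeded initialisation."""
    rng = np.random.default_rng(seed)
    return _BUILDERS[spec.name](spec, rng)


def count_params(model: nn.Layer) -> int:
    return int(sum(p.data.size for p in model.params()))
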