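"""Encoder-decoder segmentation network with skip connections.

The canonical U-shaped layout: ``depth`` encoder levels of two 3x3
conv+BN+ReLU blocks each, 2x2 max-pool downsampling, a bottleneck, then
mirror-image decoder levels that upsample (nearest-neighbour + 3x3 conv),
concatenate the encoder skip tensor and convolve again. A final 1x1
convolution emits one logit map; sigmoid gives per-pixel glottis
probability.
"""

from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Conv2d, Layer, MaxPool2d, ReLU, Sequential,
                     UpsampleNearest2)


def _double_conv(cin, cout, rng, name):
    return Sequential([
        Conv2d(cin, cout, 3, bias=False, rng=rng, name=name + ".c1"),
        BatchNorm2d(cout), ReLU(),
        Conv2d(cout, cout, 3, bias=False, rng=rng, name=name + ".c2"),
        BatchNorm2d(cout), ReLU(),
    ], name=name)


class UNet(Layer):
    def __init__(self, in_channels=3, base_channels=8, depth=3, rng=None,
                 name="unet"):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.enc = []
        self.pools = []
        c = in_channels
        ch = base_channels
        for d in range(depth):
            self.enc.append(_double_conv(c, ch, rng, f"{name}.enc{d}"))
            self.pools.append(MaxPool2d(2))
            c, ch = ch, ch * 2
        self.bottleneck = _double_conv(c, ch, rng, name + ".mid")
        self.up_convs = []
        self.dec = []
        c = ch
        for d in reversed(range(depth)):
            skip_c = base_channels * 2 ** d
            self.up_convs.append(Sequential([
                UpsampleNearest2(),
                Conv2d(c, skip_c, 3, bias=False, rng=rng, name=f"{name}.up{d}"),
                BatchNorm2d(skip_c), ReLU(),
            ], name=f"{name}.up{d}"))
            self.dec.append(_double_conv(2 * skip_c, skip_c, rng, f"{name}.dec{d}"))
            c = skip_c
        self.head = Conv2d(c, 1, 1, rng=rng, name=name + ".head")

    def params(self):
        ps = []
        for block in self.enc + [self.bottleneck] + self.up_convs + self.dec:
            ps += block.params()
        return ps + self.head.params()

    def forward(self, x, train=False):
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        self._skip_channels = []
        for up, dec, skip in zip(self.up_convs, self.dec, reversed(skips)):
            x = up.forward(x, train=train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, dy):
        dy = self.head.backward(dy)
        dskips = []
        for dec, up, sc in zip(reversed(self.dec), reversed(self.up_convs),
                               reversed(self._skip_channels)):
            d = dec.backward(dy)
            dskips.append(d[:, :sc])
            dy = up.backward(d[:, sc:])
        dy = self.bottleneck.backward(dy)
        for enc, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dy = pool.backward(dy)
            dy = enc.backward(dy + dskip)
        return dy

    def flop_walk(self, in_shape, prefix=""):
        entries = []
        shape = in_shape
        skips = []
        for d, (enc, pool) in enumerate(zip(self.enc, self.pools)):
            sub, shape = enc.flop_walk(shape, f"enc{d}")
            entries += sub
            skips.append(shape)
            shape = pool.out_shape(shape)
        sub, shape = self.bottleneck.flop_walk(shape, "mid")
        entries += sub
        for i, (up, dec) in enumerate(zip(self.up_convs, self.dec)):
            sub, shape = up.flop_walk(shape, f"up{i}")
            entries += sub
            skip = skips[-(i + 1)]
            shape = (skip[0] + shape[0], shape[1], shape[2])
            sub, shape = dec.flop_walk(shape, f"dec{i}")
            entries += sub
        sub, shape = self.head.flop_walk(shape, "head")
        return entries + sub, shape
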