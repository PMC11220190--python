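"""U-Net encoder and decoder halves with an exposed bottleneck.

The encoder produces skip features at every resolution plus the bottleneck
feature map FA (spatial size reduced 2^depth-fold, channel width
``base_width * 2^depth``).  A decoder consumes FA and the skips — bilinear
2x upsampling, skip concatenation, a DoubleConv per level — and ends in a
1x1 convolution to class logits.  Keeping the halves separate lets one
encoder feed several independently initialized decoders, with the bottleneck
optionally perturbed per decoder.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .layers import Conv2d, DoubleConv, Module

__all__ = ["UNetEncoder", "UNetDecoder"]


class UNetEncoder(Module):
    def __init__(self, in_channels: int, base_width: int, depth: int,
                 rng: np.random.Generator):
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        self.depth = depth
        self.inc = DoubleConv(in_channels, base_width, rng)
        self.downs = [
            DoubleConv(base_width * 2 ** (i - 1), base_width * 2**i, rng)
            for i in range(1, depth + 1)
        ]

    def forward(self, x, train: bool = True):
        """Returns (skips, bottleneck, cache); skips are shallow-to-deep."""
        h, w = x.shape[2:]
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {2**self.depth}"
            )
        y, c = self.inc.forward(x, train)
        skips, caches, pools = [], [c], []
        for block in self.downs:
            skips.append(y)
            y, pc = F.maxpool2_forward(y)
            y, c = block.forward(y, train)
            pools.append(pc)
            caches.append(c)
        return skips, y, (caches, pools)

    def backward(self, cache, gskips, gbottleneck):
        """Accumulate encoder gradients from skip and bottleneck gradients.

        ``gskips`` aligns with the returned skips (length ``depth``); entries
        may be None when a decoder contributed nothing at that level.
        """
        caches, pools = cache
        g = gbottleneck
        for level in range(self.depth - 1, -1, -1):
            g = self.downs[level].backward(caches[level + 1], g)
            g = F.maxpool2_backward(pools[level], g)
            gs = gskips[level]
            if gs is not None:
                g = g + gs
        return self.inc.backward(caches[0], g)


class UNetDecoder(Module):
    def __init__(self, n_classes: int, base_width: int, depth: int,
                 rng: np.random.Generator):
        self.depth = depth
        # level i consumes upsampled 2^(i+1)w + skip 2^i w -> 2^i w
        self.ups = [
            DoubleConv(base_width * 2 ** (i + 1) + base_width * 2**i,
                       base_width * 2**i, rng)
            for i in reversed(range(depth))
        ]
        self.head = Conv2d(base_width, n_classes, 1, rng)

    def forward(self, bottleneck, skips, train: bool = True):
        """Returns (logits, cache); ``skips`` shallow-to-deep from the encoder."""
        y = bottleneck
        caches = []
        for idx, block in enumerate(self.ups):
            level = self.depth - 1 - idx
            y, uc = F.upsample2_forward(y)
            skip = skips[level]
            y = np.concatenate([skip, y], axis=1)
            split = skip.shape[1]
            y, bc = block.forward(y, train)
            caches.append((uc, split, bc))
        logits, hc = self.head.forward(y, train)
        return logits, (caches, hc)

    def backward(self, cache, glogits):
        """Returns (gbottleneck, gskips) and accumulates parameter gradients."""
        caches, hc = cache
        g = self.head.backward(hc, glogits)
        gskips: list = [None] * self.depth
        for idx in range(self.depth - 1, -1, -1):
            level = self.depth - 1 - idx
            uc, split, bc = caches[idx]
            g = self.ups[idx].backward(bc, g)
            gskips[level] = g[:, :split]
            g = F.upsample2_backward(uc, g[:, split:])
        return g, gskips
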