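"""Instantiate a runnable detector from a declarative :class:`ArchSpec`.

The network is a direct execution of the spec's layer DAG on the autodiff
engine.  Each detect head is a tower of two 3x3 conv blocks followed by a
1x1 convolution emitting ``4 * reg_max`` box-distribution logits and
``num_classes`` class logits per cell.
"""

from __future__ import annotations

import numpy as np

from .arch import ArchSpec, ArchError, trace_shapes
from .autodiff import (Tensor, Module, Conv2d, ConvBlock, C2f, SPPF, concat)


class DetectHead(Module):
    """Two conv blocks + one plain 1x1 conv (box-dist and class logits)."""

    def __init__(self, cin, reg_max, num_classes, rng, dtype=np.float32):
        super().__init__()
        self.cv1 = self.add(ConvBlock(cin, cin, 3, rng=rng, dtype=dtype))
        self.cv2 = self.add(ConvBlock(cin, cin, 3, rng=rng, dtype=dtype))
        self.out = self.add(Conv2d(cin, 4 * reg_max + num_classes, 1,
                                   rng=rng, dtype=dtype))
        # near-zero logit init with a rare-positive class prior: the head
        # starts from calm predictions instead of Kaiming-scale noise
        self.out.weight.data = rng.normal(
            0.0, 0.01, self.out.weight.data.shape).astype(dtype)
        self.out.bias.data[4 * reg_max:] = -4.6

    def __call__(self, x):
        return self.out(self.cv2(self.cv1(x)))


class DetectorNet(Module):
    """The detector as an executable layer graph.

    ``forward`` takes an image batch (N, 3, H, W) in [0, 1] and returns one
    prediction map per head, each (N, 4*reg_max + nc, H/stride, W/stride).
    """

    def __init__(self, spec: ArchSpec, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        shapes = trace_shapes(spec)
        self.ops: list[tuple] = []          # (index, sources, op or None, kind)
        for l in spec.layers:
            srcs = l.source if isinstance(l.source, list) else [l.source]
            cin = sum(shapes[s].channels for s in srcs)
            if l.op_kind == "conv_block":
                m = self.add(ConvBlock(cin, l.out_channels, l.kernel, l.stride,
                                       l.padding, rng=rng, dtype=dtype))
            elif l.op_kind == "c2f":
                shortcut = "td" not in l.notes and "bu" not in l.notes
                m = self.add(C2f(cin, l.out_channels, l.repeats, shortcut,
                                 rng=rng, dtype=dtype))
            elif l.op_kind == "sppf":
                m = self.add(SPPF(cin, l.out_channels, l.kernel, rng=rng,
                                  dtype=dtype))
            elif l.op_kind == "detect_head":
                m = self.add(DetectHead(cin, spec.reg_max, spec.num_classes,
                                        rng=rng, dtype=dtype))
            else:
                m = None                     # upsample / concat
            self.ops.append((l.index, srcs, m, l.op_kind))
        self.head_strides = list(spec.detect_strides)

    def forward(self, images: np.ndarray | Tensor) -> list[Tensor]:
        x = images if isinstance(images, Tensor) else Tensor(
            np.asarray(images, dtype=self.dtype))
        if x.data.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        deepest = max(self.head_strides)
        if x.shape[2] < deepest or x.shape[3] < deepest:
            raise ValueError(f"input {x.shape[2]}x{x.shape[3]} smaller than "
                             f"deepest stride {deepest}")
        outputs = {0: x}
        heads = []
        for index, srcs, m, kind in self.ops:
            if kind == "upsample":
                out = outputs[srcs[0]].upsample_nearest(2)
            elif kind == "concat":
                out = concat([outputs[s] for s in srcs], axis=1)
            else:
                out = m(outputs[srcs[0]])
            outputs[index] = out
            if kind == "detect_head":
                heads.append(out)
        return heads

    __call__ = forward


def make_anchors(head_shapes, strides):
    """Cell-center anchor points and per-anchor stride for all heads.

    Returns (points (A, 2) in grid units of each level, strides (A,)),
    concatenated over heads in head order.
    """
    pts, strs = [], []
    for (h, w), s in zip(head_shapes, strides):
        yy, xx = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5,
                             indexing="ij")
        pts.append(np.stack([xx.ravel(), yy.ravel()], axis=-1))
        strs.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(pts, axis=0), np.concatenate(strs, axis=0)
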