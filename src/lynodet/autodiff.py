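"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape engine in the micrograd style, extended with the
dense-prediction primitives a convolutional detector needs: strided 2-D
convolution (im2col), batch normalization, SiLU, same-size max pooling,
nearest-neighbour upsampling, channel concatenation, softmax families and a
numerically stable binary cross-entropy.  Everything runs on plain numpy in
whatever float dtype the inputs carry, so the same graph can be trained in
float32 and gradient-checked in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "Conv2d", "BatchNorm2d", "ConvBlock",
    "Bottleneck", "C2f", "SPPF", "Adamax",
    "concat", "softmax", "log_softmax", "bce_with_logits", "stack",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        self.grad = g if self.grad is None else self.grad + g

    # -- elementwise arithmetic ------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                              other.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / out.data)
        return out

    def arctan(self):
        out = Tensor(np.arctan(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / (1.0 + self.data ** 2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 + self.data * (1.0 - s)))
        return out

    def maximum(self, other):
        other = Tensor._lift(other)
        out = Tensor(np.maximum(self.data, other.data), parents=(self, other))
        if out.requires_grad:
            mask = self.data >= other.data
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * mask, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * ~mask, other.shape))
            out._backward = bw
        return out

    def minimum(self, other):
        other = Tensor._lift(other)
        out = Tensor(np.minimum(self.data, other.data), parents=(self, other))
        if out.requires_grad:
            mask = self.data <= other.data
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * mask, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * ~mask, other.shape))
            out._backward = bw
        return out

    def clamp(self, lo=None, hi=None):
        out_data = np.clip(self.data, lo, hi)
        out = Tensor(out_data, parents=(self,))
        if out.requires_grad:
            mask = np.ones_like(self.data, dtype=bool)
            if lo is not None:
                mask &= self.data >= lo
            if hi is not None:
                mask &= self.data <= hi
            out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions and shape --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), parents=(self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    def matmul(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.shape))
            out._backward = bw
        return out

    __matmul__ = matmul

    # -- spatial primitives (NCHW) ---------------------------------------
    def conv2d(self, weight: "Tensor", bias=None, stride=1, padding=0):
        """2-D convolution (cross-correlation) via im2col.

        x: (N, Cin, H, W); weight: (Cout, Cin, k, k); bias: (Cout,) or None.
        """
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        O, _, k, _ = w.shape
        s, p = stride, padding
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        if Ho <= 0 or Wo <= 0:
            raise ValueError(f"conv2d: non-positive output size {Ho}x{Wo}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # N,C,Ho,Wo,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, C * k * k)
        wm = w.reshape(O, C * k * k)
        out_data = cols @ wm.T                          # N,HoWo,O
        if bias is not None:
            out_data = out_data + bias.data
        out_data = out_data.transpose(0, 2, 1).reshape(N, O, Ho, Wo)
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(out_data, parents=parents)
        if out.requires_grad:
            def bw(g):
                gm = g.reshape(N, O, Ho * Wo).transpose(0, 2, 1)   # N,HoWo,O
                if bias is not None and bias.requires_grad:
                    bias._accum(gm.sum(axis=(0, 1)))
                if weight.requires_grad:
                    gw = np.einsum("npo,npc->oc", gm, cols)
                    weight._accum(gw.reshape(w.shape))
                if self.requires_grad:
                    gcols = gm @ wm                                 # N,HoWo,Ckk
                    gcols = gcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
                    gxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=x.dtype)
                    for i in range(k):
                        for j in range(k):
                            gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += gcols[..., i, j]
                    self._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)
            out._backward = bw
        return out

    def maxpool2d(self, kernel: int, stride: int = 1, padding: int = 0):
        x = self.data
        N, C, H, W = x.shape
        k, s, p = kernel, stride, padding
        fill = -np.inf
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=fill) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        flat = win.reshape(N, C, Ho, Wo, k * k)
        arg = flat.argmax(axis=-1)
        out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0],
                     parents=(self,))
        if out.requires_grad:
            def bw(g):
                gxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=x.dtype)
                ii, jj = np.divmod(arg, k)
                n_i, c_i, y_i, x_i = np.indices(arg.shape)
                np.add.at(gxp, (n_i, c_i, y_i * s + ii, x_i * s + jj), g)
                self._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)
            out._backward = bw
        return out

    def upsample_nearest(self, scale: int = 2):
        out = Tensor(self.data.repeat(scale, axis=2).repeat(scale, axis=3),
                     parents=(self,))
        if out.requires_grad:
            def bw(g):
                N, C, H, W = self.shape
                self._accum(g.reshape(N, C, H, scale, W, scale).sum(axis=(3, 5)))
            out._backward = bw
        return out


def concat(tensors, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    if out.requires_grad:
        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = bw
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(t,))
    if out.requires_grad:
        def bw(g):
            t._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
        out._backward = bw
    return out


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = Tensor(z - lse, parents=(t,))
    if out.requires_grad:
        s = np.exp(out.data)
        def bw(g):
            t._accum(g - s * g.sum(axis=axis, keepdims=True))
        out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy from logits, numerically stable."""
    x, t = logits.data, np.asarray(targets)
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(loss, parents=(logits,))
    if out.requires_grad:
        sig = 1.0 / (1.0 + np.exp(-x))
        out._backward = lambda g: logits._accum(g * (sig - t))
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data, decay=True):
        super().__init__(np.asarray(data), requires_grad=True)
        self.decay = decay   # participates in weight decay

    __slots__ = ("decay",)


class Module:
    """Minimal module container: tracks parameters and train/eval mode."""

    def __init__(self):
        self._modules: list[Module] = []
        self._params: list[Parameter] = []
        self.training = True

    def add(self, m: "Module") -> "Module":
        self._modules.append(m)
        return m

    def register(self, p: Parameter) -> Parameter:
        self._params.append(p)
        return p

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def train(self, mode=True):
        self.training = mode
        for m in self._modules:
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state arrays (batch-norm running stats), in order."""
        out = []
        if isinstance(self, BatchNorm2d):
            out.extend([self.running_mean, self.running_var])
        for m in self._modules:
            out.extend(m.buffers())
        return out

    def load_buffers(self, arrays):
        own = self.buffers()
        if len(own) != len(arrays):
            raise ValueError(f"buffer count mismatch: {len(own)} vs {len(arrays)}")
        for dst, src in zip(own, arrays):
            dst[...] = src


class Conv2d(Module):
    """Bare convolution layer with Kaiming-normal init."""

    def __init__(self, cin, cout, k, stride=1, padding=None, bias=True,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = self.register(Parameter(
            rng.normal(0.0, std, (cout, cin, k, k)).astype(dtype)))
        self.bias = None
        if bias:
            self.bias = self.register(Parameter(np.zeros(cout, dtype=dtype),
                                                decay=False))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.register(Parameter(np.ones(c, dtype=dtype), decay=False))
        self.beta = self.register(Parameter(np.zeros(c, dtype=dtype), decay=False))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        gr = gamma.data.reshape(1, -1, 1, 1)
        br = beta.data.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
            var = x.data.var(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.ravel() - self.running_var)
            std = np.sqrt(var + self.eps)
            xhat = (x.data - mu) / std
            out = Tensor(gr * xhat + br, parents=(x, gamma, beta))
            if out.requires_grad:
                def bw(g):
                    if gamma.requires_grad:
                        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
                    if beta.requires_grad:
                        beta._accum(g.sum(axis=(0, 2, 3)))
                    if x.requires_grad:
                        gx = g * gr
                        mean_g = gx.mean(axis=(0, 2, 3), keepdims=True)
                        mean_gx = (gx * xhat).mean(axis=(0, 2, 3), keepdims=True)
                        x._accum((gx - mean_g - xhat * mean_gx) / std)
                out._backward = bw
            return out
        std = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
        mu = self.running_mean.reshape(1, -1, 1, 1)
        xhat = (x.data - mu) / std
        out = Tensor(gr * xhat + br, parents=(x, gamma, beta))
        if out.requires_grad:
            def bw(g):
                if gamma.requires_grad:
                    gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
                if beta.requires_grad:
                    beta._accum(g.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    x._accum(g * gr / std)
            out._backward = bw
        return out


class ConvBlock(Module):
    """Conv2d -> BatchNorm2d -> SiLU (the detector's basic block)."""

    def __init__(self, cin, cout, k=3, stride=1, padding=None, rng=None,
                 dtype=np.float32):
        super().__init__()
        self.conv = self.add(Conv2d(cin, cout, k, stride, padding, bias=False,
                                    rng=rng, dtype=dtype))
        self.bn = self.add(BatchNorm2d(cout, dtype=dtype))

    def __call__(self, x):
        return self.bn(self.conv(x)).silu()


class Bottleneck(Module):
    """Two 3x3 conv blocks with an optional residual shortcut."""

    def __init__(self, c, shortcut=True, rng=None, dtype=np.float32):
        super().__init__()
        self.cv1 = self.add(ConvBlock(c, c, 3, rng=rng, dtype=dtype))
        self.cv2 = self.add(ConvBlock(c, c, 3, rng=rng, dtype=dtype))
        self.shortcut = shortcut

    def __call__(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(Module):
    """Coarse-to-fine block: split, repeated bottlenecks, concat, fuse.

    Hidden width is half the output width; every intermediate stream is
    concatenated before the final 1x1 fusion convolution.
    """

    def __init__(self, cin, cout, n=1, shortcut=True, rng=None, dtype=np.float32):
        super().__init__()
        self.c = cout // 2
        self.cv1 = self.add(ConvBlock(cin, 2 * self.c, 1, rng=rng, dtype=dtype))
        self.blocks = [self.add(Bottleneck(self.c, shortcut, rng=rng, dtype=dtype))
                       for _ in range(n)]
        self.cv2 = self.add(ConvBlock((2 + n) * self.c, cout, 1, rng=rng, dtype=dtype))

    def __call__(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        streams = [a, b]
        for blk in self.blocks:
            streams.append(blk(streams[-1]))
        return self.cv2(concat(streams, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): chained same-size max-pools."""

    def __init__(self, cin, cout, k=5, rng=None, dtype=np.float32):
        super().__init__()
        c = cin // 2
        self.k = k
        self.cv1 = self.add(ConvBlock(cin, c, 1, rng=rng, dtype=dtype))
        self.cv2 = self.add(ConvBlock(4 * c, cout, 1, rng=rng, dtype=dtype))

    def __call__(self, x):
        y = self.cv1(x)
        p1 = y.maxpool2d(self.k, 1, self.k // 2)
        p2 = p1.maxpool2d(self.k, 1, self.k // 2)
        p3 = p2.maxpool2d(self.k, 1, self.k // 2)
        return self.cv2(concat([y, p1, p2, p3], axis=1))


class Adamax:
    """Adamax optimizer (Adam with an infinity-norm second moment).

    update: m <- b1*m + (1-b1)*g ; u <- max(b2*u, |g|)
            theta <- theta - lr/(1-b1^t) * m / (u + eps)
    Weight decay is L2 on parameters flagged `decay` (conv weights).
    """

    def __init__(self, params, lr=5e-3, betas=(0.937, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = [p for p in params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.u = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bias = 1.0 - self.b1 ** self.t
        for p, m, u in zip(self.params, self.m, self.u):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and getattr(p, "decay", True):
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            p.data -= (self.lr / bias) * m / (u + self.eps)
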