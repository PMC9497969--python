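"""Minimal reverse-mode autodiff and CNN layers on numpy.

Everything the frame-selection and segmentation networks need runs through
this module: tensors with a backward tape, strided/grouped 2-D convolution,
batch normalization, pooling, upsampling, and the Adam optimizer.  Arrays
are NCHW float32 throughout; all parameter initialization is driven by an
explicit ``numpy.random.Generator`` so training is bit-reproducible on one
device.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "add",
    "mul",
    "concat",
    "global_avg_pool",
    "broadcast_spatial",
    "upsample_nearest",
    "flatten",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "Sequential",
    "Adam",
    "bce_with_logits",
    "softmax_cross_entropy",
]


class Tensor:
    """A numpy array plus the tape machinery for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order by DFS
        order, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self):
        return Tensor(self.data.copy())


def _make(data, parents, backward, requires_grad=True):
    return Tensor(data, requires_grad=requires_grad, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def bwd(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bwd(g):
        x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        a._accumulate(g)
        b._accumulate(g)

    return _make(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise (broadcasting) product; used for attention gating."""
    out_data = a.data * b.data

    def bwd(g):
        ga = g * b.data
        gb = g * a.data
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), bwd)


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def concat(tensors, axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(out_data, tuple(tensors), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def bwd(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None], x.data.shape) / (h * w))

    return _make(out_data, (x,), bwd)


def broadcast_spatial(x: Tensor, h: int, w: int) -> Tensor:
    """(N,C) -> (N,C,h,w) by replication."""
    out_data = np.broadcast_to(x.data[:, :, None, None], (*x.data.shape, h, w)).copy()

    def bwd(g):
        x._accumulate(g.sum(axis=(2, 3)))

    return _make(out_data, (x,), bwd)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    f = factor

    def bwd(g):
        n, c, h, w = x.data.shape
        gx = g.reshape(n, c, h, f, w, f).sum(axis=(3, 5))
        x._accumulate(gx)

    return _make(out_data, (x,), bwd)


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    orig = x.data.shape
    out_data = x.data.reshape(n, -1)

    def bwd(g):
        x._accumulate(g.reshape(orig))

    return _make(out_data, (x,), bwd)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, flag: bool):
        for m in self.modules():
            if hasattr(m, "training"):
                m.training = flag

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self):
        """Flat list of all arrays (parameters + buffers) for checkpointing."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays):
        arrays = list(arrays)
        params = self.parameters()
        for p, a in zip(params, arrays[: len(params)]):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = a.astype(np.float32)
        rest = arrays[len(params):]
        i = 0
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = rest[i].astype(np.float32)
                m.running_var = rest[i + 1].astype(np.float32)
                i += 2


class Conv2d(Module):
    """2-D convolution, 'same' padding, optional stride and depthwise groups.

    Only groups == 1 (dense) or groups == in_channels (depthwise) are
    supported — all the backbone blocks in this package use one of the two.
    """

    def __init__(self, in_ch, out_ch, k, stride=1, groups=1, bias=True, rng=None):
        if groups != 1 and groups != in_ch:
            raise ValueError("only dense or depthwise convolutions supported")
        self.depthwise = groups > 1
        if self.depthwise and out_ch != in_ch:
            raise ValueError("depthwise conv requires out_ch == in_ch")
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride, self.groups = stride, groups
        fan_in = (in_ch // groups) * k * k
        scale = np.sqrt(2.0 / fan_in)
        shape = (out_ch, in_ch // groups, k, k)
        self.weight = Tensor(rng.normal(0.0, scale, shape), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        w, s, k = self.weight, self.stride, self.k
        pad = k // 2
        xd = x.data
        n, c, h, wd_ = xd.shape
        xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        oh = (h + 2 * pad - k) // s + 1
        ow = (wd_ + 2 * pad - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N,C,OH,OW,k,k)
        if not self.depthwise:
            out = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
        else:  # depthwise
            out = np.einsum("nchwij,cij->nchw", win, w.data[:, 0], optimize=True)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None]
        out = np.ascontiguousarray(out, dtype=np.float32)
        layer = self

        def bwd(g):
            if layer.bias is not None:
                layer.bias._accumulate(g.sum(axis=(0, 2, 3)))
            if not layer.depthwise:
                gw = np.einsum("nohw,nchwij->ocij", g, win, optimize=True)
            else:
                gw = np.einsum("nchw,nchwij->cij", g, win, optimize=True)[:, None]
            layer.weight._accumulate(gw)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    if not layer.depthwise:
                        contrib = np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j],
                                            optimize=True)
                    else:
                        contrib = g * w.data[:, 0, i, j][None, :, None, None]
                    gxp[:, :, i:i + oh * s:s, j:j + ow * s:s] += contrib
            gx = gxp[:, :, pad:pad + h, pad:pad + wd_] if pad else gxp
            x._accumulate(gx)

        return _make(out, (x,), bwd)


class BatchNorm2d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        xd = x.data
        if self.training:
            mean = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        layer, training = self, self.training
        m = xd.shape[0] * xd.shape[2] * xd.shape[3]

        def bwd(g):
            layer.gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            layer.beta._accumulate(g.sum(axis=(0, 2, 3)))
            gxh = g * layer.gamma.data[None, :, None, None]
            if training:
                # full batch-norm backward
                term1 = gxh
                term2 = gxh.mean(axis=(0, 2, 3), keepdims=True)
                term3 = xhat * (gxh * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = (term1 - term2 - term3) * inv[None, :, None, None]
            else:
                gx = gxh * inv[None, :, None, None]
            x._accumulate(gx.astype(np.float32))

        return _make(out.astype(np.float32), (x,), bwd)


class Linear(Module):
    def __init__(self, in_f, out_f, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, scale, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        out = x.data @ self.weight.data + self.bias.data
        layer = self

        def bwd(g):
            layer.weight._accumulate(x.data.T @ g)
            layer.bias._accumulate(g.sum(axis=0))
            x._accumulate(g @ layer.weight.data.T)

        return _make(out, (x,), bwd)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data.reshape(-1)
    y = np.asarray(targets, dtype=np.float32).reshape(-1)
    # softplus(z) - y*z  ==  -[y log s + (1-y) log(1-s)]
    loss = np.mean(np.logaddexp(0.0, z) - y * z)
    n = z.size
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def bwd(g):
        logits._accumulate((g * (s - y) / n).reshape(logits.data.shape))

    return _make(np.float32(loss), (logits,), bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Pixel-wise categorical cross-entropy with integer labels.

    logits: (N, K, H, W); labels: (N, H, W) ints in [0, K).
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n, k, h, w = z.shape
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    logp = np.log(np.clip(p[idx_n, labels, idx_h, idx_w], 1e-12, None))
    loss = -logp.mean()
    count = n * h * w

    def bwd(g):
        grad = p.copy()
        grad[idx_n, labels, idx_h, idx_w] -= 1.0
        logits._accumulate(g * grad / count)

    return _make(np.float32(loss), (logits,), bwd)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
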