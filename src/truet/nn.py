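"""Minimal NumPy neural-network engine for the segmentation model.

No deep-learning framework is assumed at runtime: convolution, batch
normalisation, pooling, transpose convolution, the residual U-Net wiring and
the Adam optimiser are implemented here on top of BLAS matmuls (im2col).
Everything is float64 and deterministic given a seeded ``numpy.random
.Generator``; layers cache their forward inputs, so one ``forward`` must
precede each ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "ConvTranspose2x2",
    "ResidualBlock",
    "ResUNet",
    "Adam",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base class: parameters and gradients are parallel name->array dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution via im2col; 'same'-style padding of k//2 by default."""

    def __init__(self, cin, cout, k, stride=1, pad=None, rng=None, bias=True):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k))
        if bias:
            self.params["b"] = np.zeros(cout)
        self._cache = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        wmat = self.params["W"].reshape(self.cout, -1)
        out = cols @ wmat.T
        if "b" in self.params:
            out += self.params["b"]
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, xpshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dout = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.grads["W"] = (dout.T @ cols).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dout.sum(axis=0)
        dcols = dout @ self.params["W"].reshape(self.cout, -1)
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c) + xpshape[2:])
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, dy):
        xhat, inv, train = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None] * inv[None, :, None, None]
        if not train:
            return dy * g
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * self.params["gamma"][None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) * inv[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties resolve to the first maximum."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class ConvTranspose2x2(Layer):
    """Transpose convolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout, 2, 2))
        self.params["b"] = np.zeros(cout)

    def forward(self, x, train=True):
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("nchw,cdij->ndhiwj", x, self.params["W"], optimize=True)
        y = y.reshape(n, -1, 2 * h, 2 * w)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        x = self._x
        n, c, h, w = x.shape
        d = dy.shape[1]
        dy6 = dy.reshape(n, d, h, 2, w, 2)
        self.grads["W"] = np.einsum("nchw,ndhiwj->cdij", x, dy6, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        return np.einsum("ndhiwj,cdij->nchw", dy6, self.params["W"], optimize=True)


class _ConvBNReLU(Layer):
    def __init__(self, cin, cout, k, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, rng=rng, bias=False)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()
        self.children = [self.conv, self.bn, self.relu]

    def forward(self, x, train=True):
        for layer in self.children:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.children):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Layer):
    """Basic two-conv residual block; 1x1 projection when shape changes."""

    def __init__(self, cin, cout, stride=1, rng=None):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride, rng=rng, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, rng=rng, bias=False)
        self.bn2 = BatchNorm2d(cout)
        self.relu_out = ReLU()
        if stride != 1 or cin != cout:
            self.proj_conv = Conv2d(cin, cout, 1, stride, pad=0, rng=rng, bias=False)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj_conv = None
        self.children = [
            layer
            for layer in (
                self.conv1,
                self.bn1,
                self.relu1,
                self.conv2,
                self.bn2,
                self.proj_conv,
                self.proj_bn if self.proj_conv else None,
                self.relu_out,
            )
            if layer is not None
        ]

    def forward(self, x, train=True):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train))
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.proj_conv is not None:
            skip = self.proj_bn.forward(self.proj_conv.forward(x, train), train)
        else:
            skip = x
        return self.relu_out.forward(y + skip, train)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(dsum))))
        )
        if self.proj_conv is not None:
            dskip = self.proj_conv.backward(self.proj_bn.backward(dsum))
        else:
            dskip = dsum
        return dmain + dskip


def _iter_layers(layer):
    """Depth-first iterator over primitive layers owning parameters."""
    if layer.params:
        yield layer
    for child in getattr(layer, "children", []):
        yield from _iter_layers(child)


class _Seq(Layer):
    def __init__(self, *children):
        super().__init__()
        self.children = list(children)

    def forward(self, x, train=True):
        for layer in self.children:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.children):
            dy = layer.backward(dy)
        return dy


class ResUNet:
    """Residual-encoder U-Net with a 7x7 stem and a /32 bottleneck.

    ``base_channels=64`` reproduces the full plan (64-feature-map stem,
    1024-feature-map bottleneck: 8x8 spatial for a 256x256 input); small
    ``base_channels`` give a CPU-sized model with the same topology. The
    forward pass rejects inputs whose height or width is not divisible by 32.
    """

    def __init__(self, base_channels=64, blocks_per_stage=(2, 2, 2, 2), seed=0):
        c = base_channels
        self.base_channels = c
        self.blocks_per_stage = tuple(blocks_per_stage)
        self.seed = seed
        rng = np.random.default_rng(seed)

        def stage(cin, cout, n_blocks, stride):
            blocks = [ResidualBlock(cin, cout, stride, rng=rng)]
            blocks += [ResidualBlock(cout, cout, 1, rng=rng) for _ in range(n_blocks - 1)]
            return _Seq(*blocks)

        b = self.blocks_per_stage
        self.stem = _ConvBNReLU(3, c, 7, stride=2, rng=rng)          # /2
        self.pool = MaxPool2()                                        # /4
        self.stage1 = stage(c, c, b[0], 1)                            # /4
        self.stage2 = stage(c, 2 * c, b[1], 2)                        # /8
        self.stage3 = stage(2 * c, 4 * c, b[2], 2)                    # /16
        self.stage4 = stage(4 * c, 8 * c, b[3], 2)                    # /32
        self.bottleneck = _ConvBNReLU(8 * c, 16 * c, 3, rng=rng)      # /32
        self.up4 = ConvTranspose2x2(16 * c, 8 * c, rng=rng)           # /16
        self.dec4 = _ConvBNReLU(12 * c, 4 * c, 3, rng=rng)
        self.up3 = ConvTranspose2x2(4 * c, 2 * c, rng=rng)            # /8
        self.dec3 = _ConvBNReLU(4 * c, 2 * c, 3, rng=rng)
        self.up2 = ConvTranspose2x2(2 * c, c, rng=rng)                # /4
        self.dec2 = _ConvBNReLU(2 * c, c, 3, rng=rng)
        self.up1 = ConvTranspose2x2(c, c, rng=rng)                    # /2
        self.dec1 = _ConvBNReLU(2 * c, c, 3, rng=rng)
        self.up0 = ConvTranspose2x2(c, max(c // 2, 1), rng=rng)       # /1
        self.dec0 = _ConvBNReLU(max(c // 2, 1), max(c // 2, 1), 3, rng=rng)
        self.head = Conv2d(max(c // 2, 1), 1, 1, pad=0, rng=rng)

        self._modules = [
            self.stem, self.pool, self.stage1, self.stage2, self.stage3,
            self.stage4, self.bottleneck, self.up4, self.dec4, self.up3,
            self.dec3, self.up2, self.dec2, self.up1, self.dec1, self.up0,
            self.dec0, self.head,
        ]

    # -- graph ------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Input (N,3,H,W) in [0,1] -> logits (N,1,H,W)."""
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} not divisible by 32")
        s0 = self.stem.forward(x, train)                      # c,   /2
        f1 = self.stage1.forward(self.pool.forward(s0, train), train)  # c, /4
        f2 = self.stage2.forward(f1, train)                   # 2c,  /8
        f3 = self.stage3.forward(f2, train)                   # 4c,  /16
        f4 = self.stage4.forward(f3, train)                   # 8c,  /32
        bott = self.bottleneck.forward(f4, train)             # 16c, /32
        self._bottleneck_shape = bott.shape
        d4 = self.dec4.forward(
            np.concatenate([self.up4.forward(bott, train), f3], axis=1), train
        )
        d3 = self.dec3.forward(
            np.concatenate([self.up3.forward(d4, train), f2], axis=1), train
        )
        d2 = self.dec2.forward(
            np.concatenate([self.up2.forward(d3, train), f1], axis=1), train
        )
        d1 = self.dec1.forward(
            np.concatenate([self.up1.forward(d2, train), s0], axis=1), train
        )
        d0 = self.dec0.forward(self.up0.forward(d1, train), train)
        self._split = (8 * self.base_channels, 4 * self.base_channels,
                       2 * self.base_channels, self.base_channels,
                       self.base_channels)
        return self.head.forward(d0, train)

    def backward(self, dlogits: np.ndarray) -> None:
        c = self.base_channels
        dy = self.up0.backward(self.dec0.backward(self.head.backward(dlogits)))
        dcat1 = self.dec1.backward(dy)
        dd2 = self.up1.backward(dcat1[:, : c])
        ds0 = dcat1[:, c :]
        dcat2 = self.dec2.backward(dd2)
        dd3 = self.up2.backward(dcat2[:, : c])
        df1 = dcat2[:, c :]
        dcat3 = self.dec3.backward(dd3)
        dd4 = self.up3.backward(dcat3[:, : 2 * c])
        df2 = dcat3[:, 2 * c :]
        dcat4 = self.dec4.backward(dd4)
        dbott = self.up4.backward(dcat4[:, : 8 * c])
        df3 = dcat4[:, 8 * c :]
        df4 = self.bottleneck.backward(dbott)
        df3 = df3 + self.stage4.backward(df4)
        df2 = df2 + self.stage3.backward(df3)
        df1 = df1 + self.stage2.backward(df2)
        ds0 = ds0 + self.pool.backward(self.stage1.backward(df1))
        self.stem.backward(ds0)

    # -- parameter plumbing ----------------------------------------------
    def layers(self):
        for module in self._modules:
            yield from _iter_layers(module)

    def parameters(self):
        """Flat list of (layer, key) handles, stable across calls."""
        return [(layer, key) for layer in self.layers() for key in layer.params]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers()):
            for key, value in layer.params.items():
                state[f"{i}.{key}"] = value
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for key in layer.params:
                layer.params[key] = np.array(state[f"{i}.{key}"], dtype=np.float64)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.array(state[f"{i}.running_mean"], dtype=np.float64)
                layer.running_var = np.array(state[f"{i}.running_var"], dtype=np.float64)

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_dict().items()}


class Adam:
    """Adam with the usual defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, handles, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.handles = handles
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[key]) for layer, key in handles]
        self.v = [np.zeros_like(layer.params[key]) for layer, key in handles]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for i, (layer, key) in enumerate(self.handles):
            g = layer.grads.get(key)
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
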