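"""Minimal neural-network layers with explicit backprop on NumPy arrays.

Volumetric tensors are channels-last ``(N, D, H, W, C)`` float32; vector
tensors are ``(N, F)``.  Channels-last keeps the im2col matrix contiguous,
so stride-1 "same" convolution is 27 block copies plus one BLAS matmul;
the input gradient is a correlation with the spatially flipped kernel,
which avoids scatter-adds.  Each layer caches what its backward pass needs
during ``forward(training=True)``; inference caches nothing.

Parameters live in ``layer.params`` (name -> array) with gradients in
``layer.grads``; names listed in ``layer.decay`` receive the L2 penalty.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.decay: set[str] = set()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _vol_cols(x: np.ndarray, k: int) -> np.ndarray:
    """im2col for channels-last (N, D, H, W, C), stride 1, same padding.

    Returns a contiguous (N*D*H*W, k^3*C) matrix with patch layout
    (kd, kh, kw, C).
    """
    n, d, h, w, c = x.shape
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    if k == 1:
        return x.reshape(n * d * h * w, c)
    cols = np.empty((n, d, h, w, k * k * k, c), dtype=np.float32)
    o = 0
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                cols[:, :, :, :, o, :] = x[:, kd:kd + d, kh:kh + h, kw:kw + w, :]
                o += 1
    return cols.reshape(n * d * h * w, k ** 3 * c)


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))


def _offsets(k: int):
    return [(kd, kh, kw) for kd in range(k) for kh in range(k) for kw in range(k)]


class Conv3d(Layer):
    """3-D convolution, stride 1, same padding, odd kernel, He init.

    Two equivalent execution paths, chosen by channel count: a single
    im2col + GEMM when input channels are few (the gather is cheap and one
    large GEMM is efficient), or one GEMM per kernel offset on contiguous
    shifted slabs when channels are many (avoids materializing the k^3-fold
    column matrix).  The input gradient accumulates shifted GEMM results
    into a padded buffer, so no im2col of the output gradient is needed.
    ``input_grad=False`` (first layer) skips the dx computation entirely.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator, input_grad: bool = True):
        super().__init__()
        if ksize % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {ksize}")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        self.input_grad = input_grad
        fan_in = in_ch * ksize ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(out_ch, dtype=np.float32)}
        self.decay = {"W"}
        self._cache = None
        self._use_cols = in_ch < 8

    def forward(self, x, training=False):
        n, d, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        k = self.k
        if k == 1:
            flat = x.reshape(-1, c)
            out = flat @ self.params["W"] + self.params["b"]
            if training:
                self._cache = ("flat", flat, x.shape)
        elif self._use_cols:
            cols = _vol_cols(x, k)
            out = cols @ self.params["W"] + self.params["b"]
            if training:
                self._cache = ("cols", cols, x.shape)
        else:
            xp = _pad_same(x, k)
            w6 = self.params["W"].reshape(k ** 3, c, self.out_ch)
            out = np.empty((n * d * h * w, self.out_ch), dtype=np.float32)
            out[:] = self.params["b"]
            for o, (kd, kh, kw) in enumerate(_offsets(k)):
                slab = np.ascontiguousarray(
                    xp[:, kd:kd + d, kh:kh + h, kw:kw + w, :]).reshape(-1, c)
                out += slab @ w6[o]
            if training:
                self._cache = ("slab", xp, x.shape)
        return out.reshape(n, d, h, w, self.out_ch)

    def backward(self, dout):
        mode, cached, xshape = self._cache
        n, d, h, w, c = xshape
        k = self.k
        f = self.out_ch
        d2 = dout.reshape(-1, f)
        self.grads["b"] = d2.sum(axis=0)
        dx = None
        if mode == "flat":
            self.grads["W"] = cached.T @ d2
            if self.input_grad:
                dx = (d2 @ self.params["W"].T).reshape(xshape)
        elif mode == "cols":
            self.grads["W"] = cached.T @ d2
            if self.input_grad:
                dx = self._dx_scatter(dout, xshape)
        else:
            xp = cached
            dw = np.empty((k ** 3, c, f), dtype=np.float32)
            for o, (kd, kh, kw) in enumerate(_offsets(k)):
                slab = np.ascontiguousarray(
                    xp[:, kd:kd + d, kh:kh + h, kw:kw + w, :]).reshape(-1, c)
                dw[o] = slab.T @ d2
            self.grads["W"] = dw.reshape(k ** 3 * c, f)
            if self.input_grad:
                dx = self._dx_scatter(dout, xshape)
        self._cache = None
        return dx

    def _dx_scatter(self, dout, xshape):
        n, d, h, w, c = xshape
        k, f = self.k, self.out_ch
        p = k // 2
        w6 = self.params["W"].reshape(k ** 3, c, f)
        d2 = dout.reshape(-1, f)
        dxp = np.zeros((n, d + 2 * p, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for o, (kd, kh, kw) in enumerate(_offsets(k)):
            dxp[:, kd:kd + d, kh:kh + h, kw:kw + w, :] += \
                (d2 @ w6[o].T).reshape(n, d, h, w, c)
        return np.ascontiguousarray(dxp[:, p:p + d, p:p + h, p:p + w, :])


class BatchNorm(Layer):
    """Batch normalization per channel over batch (+ spatial) axes.

    Works on both (N, D, H, W, C) and (N, F) inputs.  Running statistics
    (momentum 0.9, eps 1e-3) are used at inference.
    """

    def __init__(self, num_ch: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(num_ch, dtype=np.float32),
                       "beta": np.zeros(num_ch, dtype=np.float32)}
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.ones(num_ch, dtype=np.float32)
        self._cache = None

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        out = self.params["gamma"] * xhat + self.params["beta"]
        if training:
            self._cache = (xhat, inv, axes)
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, inv, axes = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) * inv
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training=False):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2; input dims must be even."""

    def forward(self, x, training=False):
        n, d, h, w, c = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {(d, h, w)}")
        blk = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        blk = np.ascontiguousarray(blk.transpose(0, 1, 3, 5, 7, 2, 4, 6))
        blk = blk.reshape(n, d // 2, h // 2, w // 2, c, 8)
        idx = blk.argmax(axis=-1)
        out = np.take_along_axis(blk, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, xshape = self._cache
        n, d, h, w, c = xshape
        dblk = np.zeros((n, d // 2, h // 2, w // 2, c, 8), dtype=np.float32)
        np.put_along_axis(dblk, idx[..., None], dout[..., None].astype(np.float32),
                          axis=-1)
        dblk = dblk.reshape(n, d // 2, h // 2, w // 2, c, 2, 2, 2)
        dx = dblk.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(n, d, h, w, c)
        self._cache = None
        return np.ascontiguousarray(dx)


class GlobalAvgPool(Layer):
    """(N, D, H, W, C) -> (N, C) per-channel spatial mean."""

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dout):
        n, d, h, w, c = self._shape
        dx = np.broadcast_to(dout[:, None, None, None, :] / (d * h * w), self._shape)
        self._shape = None
        return np.ascontiguousarray(dx, dtype=np.float32)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(out_f, dtype=np.float32)}
        self.decay = {"W"}

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference. Draws from its own rng."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self.rate == 0:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, training=False):
        for lay in self.layers:
            x = lay.forward(x, training=training)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def iter_layers(self):
        for lay in self.layers:
            if isinstance(lay, (Sequential, DenseBlock)):
                yield from lay.iter_layers()
            else:
                yield lay


class DenseBlock(Layer):
    """Dense (concatenative) connectivity: each conv unit sees the block
    input concatenated with every previous unit's output; the block output
    is the concatenation of the input and all unit outputs."""

    def __init__(self, in_ch: int, growth: int, n_convs: int, ksize: int,
                 rng: np.random.Generator):
        super().__init__()
        self.units: list[Sequential] = []
        ch = in_ch
        for _ in range(n_convs):
            self.units.append(Sequential([
                Conv3d(ch, growth, ksize, rng), BatchNorm(growth), ReLU()]))
            ch += growth
        self.out_ch = ch
        self.growth = growth
        self._feat_chs = None

    def forward(self, x, training=False):
        feats = [x]
        for unit in self.units:
            xin = np.concatenate(feats, axis=-1) if len(feats) > 1 else feats[0]
            feats.append(unit.forward(xin, training=training))
        if training:
            self._feat_chs = [f.shape[-1] for f in feats]
        return np.concatenate(feats, axis=-1)

    def backward(self, dout):
        chs = self._feat_chs
        bounds = np.cumsum([0] + chs)
        dfeats = [np.ascontiguousarray(dout[..., bounds[i]:bounds[i + 1]])
                  for i in range(len(chs))]
        for i in reversed(range(len(self.units))):
            dxin = self.units[i].backward(dfeats[i + 1])
            b = np.cumsum([0] + chs[:i + 1])
            for j in range(i + 1):
                dfeats[j] = dfeats[j] + dxin[..., b[j]:b[j + 1]]
        self._feat_chs = None
        return dfeats[0]

    def iter_layers(self):
        for unit in self.units:
            yield from unit.iter_layers()


def iter_params(root: Layer):
    """Yield (layer, name) pairs for every parameter under root."""
    layers = root.iter_layers() if isinstance(root, (Sequential, DenseBlock)) else [root]
    for lay in layers:
        for name in lay.params:
            yield lay, name


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)
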