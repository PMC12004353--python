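"""Minimal dense/convolutional network engine (numpy, CPU).

Implements exactly the layer vocabulary the model specs need — 1D/3D
same-padding convolutions, batch normalization, leaky ReLU, spectral-axis max
pooling and upsampling, skip concatenation with spectral cropping, flatten,
dense, and a 1×1 2D head — with reverse-mode gradients and an Adam optimizer.

Tensor layout is channels-last throughout: spectra are (N, L, C), patches and
scans are (N, H, W, L, C), flattened features are (N, F). The spectral axis is
always axis −2, which is the only axis pooling and upsampling touch.

Convolutions are computed by im2col + GEMM, chunked over the batch axis to
bound the size of the materialized column matrix. All kernels used here have
odd extents, so the input gradient of a same-padding convolution is again a
same-padding convolution with the kernel flipped and its channel axes
swapped.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

class Layer:
    """Base layer: trainable ``params`` with aligned ``grads``, optional tag."""

    tag: str | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False, net=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, net=None) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _conv1d_cols(x: np.ndarray, k: int) -> np.ndarray:
    """im2col for (N, L, C) with same padding -> (N*L, k*C)."""
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    v = sliding_window_view(xp, k, axis=1)  # (N, L, C, k)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
        x.shape[0] * x.shape[1], k * x.shape[2]
    )


def _conv1d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    k, cin, cout = w.shape
    n, length, _ = x.shape
    cols = _conv1d_cols(x, k)
    return (cols @ w.reshape(k * cin, cout)).reshape(n, length, cout)


def _pad3d(x: np.ndarray, kshape: tuple[int, int, int]) -> np.ndarray:
    kh, kw, kl = kshape
    return np.pad(
        x,
        ((0, 0), ((kh - 1) // 2,) * 2, ((kw - 1) // 2,) * 2,
         ((kl - 1) // 2,) * 2, (0, 0)),
    )


def _conv3d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padding 3D convolution as a sum of per-offset GEMMs.

    Avoids materializing the full im2col matrix: for each kernel offset the
    shifted input slice is multiplied by that offset's (cin, cout) weight
    slab and accumulated.
    """
    kh, kw, kl, cin, cout = w.shape
    n, h, wd, length, _ = x.shape
    xp = _pad3d(x, (kh, kw, kl))
    out = np.zeros((n * h * wd * length, cout), dtype=np.result_type(x, w))
    for di in range(kh):
        for dj in range(kw):
            for dl in range(kl):
                s = xp[:, di : di + h, dj : dj + wd, dl : dl + length, :]
                out += s.reshape(-1, cin) @ w[di, dj, dl]
    return out.reshape(n, h, wd, length, cout)


def _conv3d_dw(x: np.ndarray, dy: np.ndarray, kshape: tuple[int, int, int]) -> np.ndarray:
    """Weight gradient of the same-padding 3D convolution."""
    kh, kw, kl = kshape
    n, h, wd, length, cin = x.shape
    cout = dy.shape[-1]
    xp = _pad3d(x, (kh, kw, kl))
    dyf = dy.reshape(-1, cout)
    gw = np.empty((kh, kw, kl, cin, cout), dtype=np.float64)
    for di in range(kh):
        for dj in range(kw):
            for dl in range(kl):
                s = xp[:, di : di + h, dj : dj + wd, dl : dl + length, :]
                gw[di, dj, dl] = s.reshape(-1, cin).T @ dyf
    return gw


class Conv1D(Layer):
    def __init__(self, k: int, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (k * cin))
        self.w = (rng.standard_normal((k, cin, cout)) * scale).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, training=False, net=None):
        self.x = x
        return _conv1d(x, self.w) + self.b

    def backward(self, dy, net=None):
        k, cin, cout = self.w.shape
        cols = _conv1d_cols(self.x, k)
        self.gw[...] = (cols.T @ dy.reshape(-1, cout)).reshape(k, cin, cout)
        self.gb[...] = dy.sum(axis=(0, 1))
        wf = np.ascontiguousarray(self.w[::-1].transpose(0, 2, 1))
        return _conv1d(dy, wf)


class Conv3D(Layer):
    def __init__(self, kernel_size: tuple[int, int, int], cin: int, cout: int,
                 rng: np.random.Generator, dtype=np.float32):
        kh, kw, kl = kernel_size
        scale = np.sqrt(2.0 / (kh * kw * kl * cin))
        self.w = (rng.standard_normal((kh, kw, kl, cin, cout)) * scale).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, training=False, net=None):
        self.x = x
        return _conv3d(x, self.w) + self.b

    def backward(self, dy, net=None):
        kh, kw, kl, _, _ = self.w.shape
        self.gw[...] = _conv3d_dw(self.x, dy, (kh, kw, kl))
        self.gb[...] = dy.sum(axis=(0, 1, 2, 3))
        wf = np.ascontiguousarray(
            self.w[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
        )
        return _conv3d(dy, wf)


class Conv2D1x1(Layer):
    """1×1 2D convolution head: a per-pixel dense map over channels."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / cin)
        self.w = (rng.standard_normal((cin, cout)) * scale).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, training=False, net=None):
        self.x = x
        return x @ self.w + self.b

    def backward(self, dy, net=None):
        cin, cout = self.w.shape
        self.gw[...] = self.x.reshape(-1, cin).T @ dy.reshape(-1, cout)
        self.gb[...] = dy.reshape(-1, cout).sum(axis=0)
        return dy @ self.w.T


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / nin)
        self.w = (rng.standard_normal((nin, nout)) * scale).astype(dtype)
        self.b = np.zeros(nout, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, training=False, net=None):
        self.x = x
        return x @ self.w + self.b

    def backward(self, dy, net=None):
        self.gw[...] = self.x.T @ dy
        self.gb[...] = dy.sum(axis=0)
        return dy @ self.w.T


class BatchNorm(Layer):
    """Per-channel batch normalization (channels-last); 2 trainable params
    per channel, running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x, training=False, net=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.m = int(np.prod([x.shape[a] for a in axes]))
            self.invstd = 1.0 / np.sqrt(var + self.eps)
            self.xhat = (x - mu) * self.invstd
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mu
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
            return (self.gamma * self.xhat + self.beta).astype(x.dtype)
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        return ((x - self.running_mean) * invstd * self.gamma + self.beta).astype(
            x.dtype
        )

    def backward(self, dy, net=None):
        axes = tuple(range(dy.ndim - 1))
        self.ggamma[...] = (dy * self.xhat).sum(axis=axes)
        self.gbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        m = self.m
        dx = (
            self.invstd
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)
                - self.xhat * (dxhat * self.xhat).sum(axis=axes)
            )
        )
        return dx.astype(dy.dtype)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3):
        self.alpha = alpha

    def forward(self, x, training=False, net=None):
        self.mask = x >= 0
        return np.where(self.mask, x, self.alpha * x)

    def backward(self, dy, net=None):
        return np.where(self.mask, dy, self.alpha * dy)


class MaxPoolSpectral(Layer):
    """Max pooling along the spectral axis (axis −2), floor division."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, training=False, net=None):
        f = self.factor
        length = x.shape[-2]
        l2 = length // f
        self.in_shape = x.shape
        xr = x[..., : l2 * f, :].reshape(x.shape[:-2] + (l2, f, x.shape[-1]))
        self.arg = xr.argmax(axis=-2)
        return np.take_along_axis(xr, self.arg[..., None, :], axis=-2).squeeze(-2)

    def backward(self, dy, net=None):
        f = self.factor
        l2 = dy.shape[-2]
        dxr = np.zeros(dy.shape[:-2] + (l2, f, dy.shape[-1]), dtype=dy.dtype)
        np.put_along_axis(dxr, self.arg[..., None, :], dy[..., None, :], axis=-2)
        dx = np.zeros(self.in_shape, dtype=dy.dtype)
        dx[..., : l2 * f, :] = dxr.reshape(dy.shape[:-2] + (l2 * f, dy.shape[-1]))
        return dx


class UpsampleSpectral(Layer):
    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, training=False, net=None):
        return np.repeat(x, self.factor, axis=-2)

    def backward(self, dy, net=None):
        f = self.factor
        l2 = dy.shape[-2] // f
        return dy.reshape(dy.shape[:-2] + (l2, f, dy.shape[-1])).sum(axis=-2)


class Flatten(Layer):
    def forward(self, x, training=False, net=None):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy, net=None):
        return dy.reshape(self.in_shape)


class ReshapeSpectralToChannels(Layer):
    """(N, H, W, L, C) -> (N, H, W, L·C): stack the spectral axis into
    channels ahead of the 1×1 head."""

    def forward(self, x, training=False, net=None):
        self.in_shape = x.shape
        return x.reshape(x.shape[:-2] + (x.shape[-2] * x.shape[-1],))

    def backward(self, dy, net=None):
        return dy.reshape(self.in_shape)


class CropSpectralOp(Layer):
    """Crop the saved skip tensor to the current spectral length (leading
    bins kept); the through-stream passes unchanged."""

    def __init__(self, source: str):
        self.source = source

    def forward(self, x, training=False, net=None):
        entry = net.saved[self.source]
        length = x.shape[-2]
        entry["cropped"] = entry["tensor"][..., :length, :]
        entry["pad"] = entry["tensor"].shape[-2] - length
        return x

    def backward(self, dy, net=None):
        return dy


class ConcatSkipOp(Layer):
    """Concatenate the (cropped) skip tensor onto the channel axis."""

    def __init__(self, source: str):
        self.source = source

    def forward(self, x, training=False, net=None):
        entry = net.saved[self.source]
        skip = entry.get("cropped", entry["tensor"])
        self.split = x.shape[-1]
        return np.concatenate([x, skip], axis=-1)

    def backward(self, dy, net=None):
        entry = net.saved[self.source]
        main = dy[..., : self.split]
        gskip = dy[..., self.split :]
        pad = entry.get("pad", 0)
        if pad:
            width = [(0, 0)] * gskip.ndim
            width[-2] = (0, pad)
            gskip = np.pad(gskip, width)
        entry["grad"] = gskip if entry.get("grad") is None else entry["grad"] + gskip
        return main


# ---------------------------------------------------------------------------
# network, loss, optimizer
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def cross_entropy_loss_grad(
    logits: np.ndarray,
    targets: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy (from logits) and its gradient.

    ``targets`` are integer class codes over all leading axes of ``logits``;
    the loss is the (optionally class-weighted) mean negative log-likelihood.
    """
    shp = logits.shape
    k = shp[-1]
    z = logits.reshape(-1, k).astype(np.float64)
    y = np.asarray(targets).reshape(-1)
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    idx = np.arange(len(y))
    nll = -np.log(np.maximum(p[idx, y], 1e-300))
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=np.float64)[y]
    else:
        w = np.ones(len(y))
    wsum = w.sum()
    loss = float((w * nll).sum() / wsum)
    g = p
    g[idx, y] -= 1.0
    g *= (w / wsum)[:, None]
    return loss, g.reshape(shp).astype(logits.dtype)


class Network:
    """Sequential network with optional tagged skip connections.

    ``forward`` returns logits; ``predict_proba`` applies the final softmax.
    """

    def __init__(self, layers: list[Layer], name: str = "net"):
        self.layers = layers
        self.name = name
        self.saved: dict[str, dict] = {}

    @property
    def n_params(self) -> int:
        return int(sum(p.size for ly in self.layers for p in ly.params))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self.saved = {}
        for ly in self.layers:
            x = ly.forward(x, training=training, net=self)
            if ly.tag:
                self.saved[ly.tag] = {"tensor": x, "grad": None, "pad": 0}
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for ly in reversed(self.layers):
            if ly.tag:
                # skip consumers contribute gradient at this layer's OUTPUT
                g = self.saved[ly.tag]["grad"]
                if g is not None:
                    dy = dy + g
                    self.saved[ly.tag]["grad"] = None
            dy = ly.backward(dy, net=self)
        return dy

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(softmax(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        return np.argmax(self.predict_proba(x, batch_size), axis=-1)


class Adam:
    """Adam with fixed learning rate (the training default is 3e-4)."""

    def __init__(self, network: Network, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p, dtype=np.float64)
                   for ly in network.layers for p in ly.params]
        self._v = [np.zeros_like(p, dtype=np.float64)
                   for ly in network.layers for p in ly.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        i = 0
        for ly in self.network.layers:
            for p, g in zip(ly.params, ly.grads):
                m, v = self._m[i], self._v[i]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * np.square(g, dtype=np.float64)
                p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)
                i += 1
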