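"""Minimal convolutional network implemented on numpy.

Just enough machinery for the soft sensor: stride-1 'same' 2-D
convolution (im2col + BLAS matmul), ReLU, non-overlapping max pooling,
dense layers, a softmax cross-entropy head and an Adam optimizer. All
tensors are NHWC float32. Gradients are exact analytic backprop; the
convolution input-gradient is computed as a same-convolution with the
spatially flipped kernel (in/out channels swapped), so forward and
backward are both single matmuls per layer.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, kh*kw*C) patch matrix for 'same' stride-1 conv."""
    n, h, w, c = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (N, H, W, C, kh, kw) -> (N, H, W, kh, kw, C)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(n * h * w, kh * kw * c)


class Conv2DSame:
    """Stride-1 'same' convolution + ReLU."""

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int,
                 rng: np.random.Generator) -> None:
        fan_in = kh * kw * c_in
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU
        self.w = (rng.standard_normal((kh, kw, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col(x, self.kh, self.kw)
        y = cols @ self.w.reshape(-1, self.c_out) + self.b
        y = y.reshape(n, h, w, self.c_out)
        self._x_shape = x.shape
        self._cols = cols
        self._mask = y > 0
        return np.maximum(y, 0.0)

    def backward(self, dy: np.ndarray):
        n, h, w, _ = self._x_shape
        dy = dy * self._mask
        dflat = dy.reshape(n * h * w, self.c_out)
        dw = (self._cols.T @ dflat).reshape(self.w.shape)
        db = dflat.sum(axis=0)
        # input gradient: same-conv of dy with flipped kernel, channels swapped
        w_flip = self.w[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh, kw, c_out, c_in)
        cols_dy = _im2col(dy, self.kh, self.kw)
        dx = (cols_dy @ w_flip.reshape(-1, self.c_in)).reshape(n, h, w, self.c_in)
        return dx, [dw, db]


class MaxPool:
    """Non-overlapping max pooling; pool size clipped to the input dims."""

    def __init__(self, ph: int, pw: int) -> None:
        self.ph, self.pw = ph, pw

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        # height is clipped (few montage rows by design); width must fit
        ph, pw = min(self.ph, h), self.pw
        if pw > w:
            raise ValueError("pooling window larger than spatial dimension")
        ho, wo = h // ph, w // pw
        xc = x[:, :ho * ph, :wo * pw]
        blocks = xc.reshape(n, ho, ph, wo, pw, c)
        y = blocks.max(axis=(2, 4))
        self._cache = (x.shape, ph, pw, blocks, y)
        return y

    def backward(self, dy: np.ndarray):
        x_shape, ph, pw, blocks, y = self._cache
        n, h, w, c = x_shape
        ho, wo = h // ph, w // pw
        mask = blocks == y[:, :, None, :, None, :]
        dx = np.zeros(x_shape, dtype=np.float32)
        grad = mask * dy[:, :, None, :, None, :]
        dx[:, :ho * ph, :wo * pw] = grad.reshape(n, ho * ph, wo * pw, c)
        return dx, []


class Dense:
    """Affine layer with optional ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 relu: bool = True) -> None:
        scale = np.sqrt((2.0 if relu else 1.0) / d_in)
        self.w = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.relu = relu

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x @ self.w + self.b
        self._x = x
        if self.relu:
            self._mask = y > 0
            y = np.maximum(y, 0.0)
        return y

    def backward(self, dy: np.ndarray):
        if self.relu:
            dy = dy * self._mask
        dw = self._x.T @ dy
        db = dy.sum(axis=0)
        dx = dy @ self.w.T
        return dx, [dw, db]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient wrt logits for integer labels ``y``."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class ConvNet:
    """Conv blocks -> flatten -> concat side features -> dense -> softmax.

    ``conv_blocks`` is a list of ``(filters, (kh, kw), (ph, pw))``; the
    flattened convolutional features are concatenated with an
    ``n_features``-long side (shallow) feature vector before the dense
    head.
    """

    def __init__(self, input_shape: tuple[int, int, int],
                 conv_blocks: list[tuple[int, tuple[int, int], tuple[int, int]]],
                 n_features: int, dense_units: int, n_classes: int,
                 seed: int, global_avg_pool: bool = True) -> None:
        if not conv_blocks:
            raise ValueError("need at least one convolutional block")
        rng = np.random.default_rng(seed)
        h, w, c = input_shape
        self.blocks: list = []
        for filters, (kh, kw), (ph, pw) in conv_blocks:
            conv = Conv2DSame(kh, kw, c, filters, rng)
            pool = MaxPool(ph, pw)
            if pw > w:
                raise ValueError("pooling window larger than spatial dimension")
            h, w, c = h // min(ph, h), w // pw, filters
            if h < 1 or w < 1:
                raise ValueError("feature map vanished; reduce pooling")
            self.blocks += [conv, pool]
        self.global_avg_pool = global_avg_pool
        self.flat_dim = c if global_avg_pool else h * w * c
        self.fc1 = Dense(self.flat_dim + n_features, dense_units, rng, relu=True)
        self.fc2 = Dense(dense_units, n_classes, rng, relu=False)
        self.n_features = n_features
        self.input_shape = input_shape

    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.blocks:
            out += layer.params
        return out + self.fc1.params + self.fc2.params

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, feats: np.ndarray) -> np.ndarray:
        """Logits for a batch of images + side features."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        feats = np.ascontiguousarray(feats, dtype=np.float32)
        if x.shape[1:] != self.input_shape:
            raise ValueError(f"expected images of shape {self.input_shape}")
        if feats.shape != (x.shape[0], self.n_features):
            raise ValueError(f"expected {self.n_features} side features per image")
        for layer in self.blocks:
            x = layer.forward(x)
        self._conv_out_shape = x.shape
        if self.global_avg_pool:
            flat = x.mean(axis=(1, 2))
        else:
            flat = x.reshape(x.shape[0], -1)
        self._split = flat.shape[1]
        z = np.concatenate([flat, feats], axis=1)
        return self.fc2.forward(self.fc1.forward(z))

    def predict_proba(self, x: np.ndarray, feats: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size],
                                            feats[i:i + batch_size])))
        return np.concatenate(out, axis=0)

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        dz, g2 = self.fc2.backward(dlogits)
        dz, g1 = self.fc1.backward(dz)
        dpool = dz[:, :self._split]
        if self.global_avg_pool:
            n, h, w, c = self._conv_out_shape
            dx = np.broadcast_to(
                dpool[:, None, None, :] / (h * w), self._conv_out_shape
            ).astype(np.float32)
        else:
            dx = dpool.reshape(self._conv_out_shape)
        for layer in reversed(self.blocks):
            dx, g = layer.backward(dx)
            grads = g + grads
        return grads + g1 + g2

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w
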