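"""Minimal numpy CNN framework for feature tapping and small-scale training.

Forward passes use im2col convolutions (BLAS matmuls) in float32, enough
to run the published AlexNet / ResNet-50 / DarkNet-19 / DenseNet-201
definitions on CPU with random weights.  Backward passes are implemented
for the layer subset the trainable ``tinycnn`` uses (conv, relu, 2x2 max
pool, global average pool, linear), so full SGDM fine-tuning works there;
composite forward-only blocks (bottlenecks, dense blocks) raise if asked
for gradients.

Tensor layout is NCHW throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Dropout",
    "Bottleneck",
    "DenseBlock",
    "Transition",
    "Sequential",
    "softmax_cross_entropy",
    "SGDM",
]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} has no backward pass")

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def supports_backward(self) -> bool:
        cls = type(self)
        return cls.backward is not Layer.backward

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad, self.kernel = stride, pad, kernel
        fan_in = in_ch * kernel * kernel
        self.W = _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.dW = self.db = None
        self._cache: tuple | None = None

    def _cols(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return np.ascontiguousarray(cols), ho, wo

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        cols, ho, wo = self._cols(x)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ wmat.T
        if self.b is not None:
            out += self.b
        out = out.reshape(x.shape[0], ho, wo, -1).transpose(0, 3, 1, 2)
        self._cache = (x.shape, cols)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n, _, h, w = x_shape
        o, c, k, _ = self.W.shape
        s, p = self.stride, self.pad
        _, _, ho, wo = grad.shape
        g2 = grad.transpose(0, 2, 3, 1).reshape(-1, o)
        self.dW = (g2.T @ cols).reshape(self.W.shape)
        if self.b is not None:
            self.db = g2.sum(axis=0)
        dcols = (g2 @ self.W.reshape(o, -1)).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self) -> dict[str, np.ndarray]:
        out = {"W": self.W}
        if self.b is not None:
            out["b"] = self.b
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {"W": self.dW}
        if self.b is not None:
            out["b"] = self.db
        return out


class BatchNorm2d(Layer):
    """Inference-mode batch normalisation (gamma=1, beta=0, running stats 0/1).

    With fresh statistics this is an identity up to eps; it exists so the
    published architectures keep their exact layer structure and can host
    real running statistics if pretrained weights are ever loaded.
    """

    def __init__(self, ch: int, eps: float = 1e-5) -> None:
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.mean = np.zeros(ch, dtype=np.float32)
        self.var = np.ones(ch, dtype=np.float32)
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        scale = (self.gamma / np.sqrt(self.var + self.eps)).reshape(1, -1, 1, 1)
        shift = (self.beta - self.mean * scale.ravel()).reshape(1, -1, 1, 1)
        return x * scale + shift


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1) -> None:
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, x, self.alpha * x).astype(np.float32, copy=False)


class MaxPool2d(Layer):
    """Max pooling; backward is implemented for the 2x2/stride-2 case."""

    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0) -> None:
        self.kernel = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        if k == 2 and s == 2 and p == 0 and x.shape[2] % 2 == 0 and x.shape[3] % 2 == 0:
            n, c, h, w = x.shape
            xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
            xr = xr.reshape(n, c, h // 2, w // 2, 4)
            self._argmax = xr.argmax(axis=-1)
            self._in_shape = x.shape
            self._fast = True
            return np.ascontiguousarray(xr.max(axis=-1))
        self._fast = False
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        return np.ascontiguousarray(win.max(axis=(4, 5)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if not self._fast:
            raise NotImplementedError("backward only for 2x2 stride-2 pooling")
        n, c, h, w = self._in_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dxr.reshape(n, c, h, w))


class AvgPool2d(Layer):
    def __init__(self, kernel: int, stride: int | None = None) -> None:
        self.kernel = kernel
        self.stride = stride or kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        return np.ascontiguousarray(win.mean(axis=(4, 5), dtype=np.float32))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3), dtype=np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], self._in_shape) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Linear(Layer):
    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (out_dim, in_dim), in_dim)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dW = self.db = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(np.float32, copy=False)
        return self._x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.W

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}


class Dropout(Layer):
    """Identity at inference; kept so AlexNet's published layer count holds."""

    def __init__(self, p: float = 0.5) -> None:
        self.p = p

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class Bottleneck(Layer):
    """ResNet bottleneck: 1x1 -> 3x3 -> 1x1 with identity/projection shortcut."""

    def __init__(
        self,
        in_ch: int,
        mid_ch: int,
        out_ch: int,
        stride: int,
        rng: np.random.Generator,
    ) -> None:
        self.conv1 = Conv2d(in_ch, mid_ch, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid_ch)
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid_ch)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        self.relu = LeakyReLU(0.0)
        self.down: Conv2d | None = None
        self.down_bn: BatchNorm2d | None = None
        if stride != 1 or in_ch != out_ch:
            self.down = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = BatchNorm2d(out_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.relu(self.bn1(self.conv1(x)))
        y = self.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        sc = x if self.down is None else self.down_bn(self.down(x))
        return self.relu(y + sc)


class DenseBlock(Layer):
    """DenseNet block: each layer sees the concat of all previous outputs."""

    def __init__(
        self, in_ch: int, n_layers: int, growth: int, rng: np.random.Generator
    ) -> None:
        self.layers = []
        ch = in_ch
        for _ in range(n_layers):
            self.layers.append(
                (
                    BatchNorm2d(ch),
                    Conv2d(ch, 4 * growth, 1, bias=False, rng=rng),
                    BatchNorm2d(4 * growth),
                    Conv2d(4 * growth, growth, 3, pad=1, bias=False, rng=rng),
                )
            )
            ch += growth
        self.out_ch = ch
        self.relu = LeakyReLU(0.0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for bn1, c1, bn2, c2 in self.layers:
            y = c1(self.relu(bn1(x)))
            y = c2(self.relu(bn2(y)))
            x = np.concatenate([x, y], axis=1)
        return x


class Transition(Layer):
    """DenseNet transition: BN-ReLU-1x1 conv (channel halving) + 2x2 avg pool."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        self.bn = BatchNorm2d(in_ch)
        self.conv = Conv2d(in_ch, out_ch, 1, bias=False, rng=rng)
        self.pool = AvgPool2d(2)
        self.relu = LeakyReLU(0.0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.pool(self.conv(self.relu(self.bn(x))))


class Sequential:
    """Ordered named layers with taps: forward can stop after any layer."""

    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        self.layers = layers
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")

    def layer_names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def __getitem__(self, name: str) -> Layer:
        for n, layer in self.layers:
            if n == name:
                return layer
        raise KeyError(name)

    def forward(self, x: np.ndarray, tap: str | None = None) -> np.ndarray:
        if tap is not None and tap not in self.layer_names():
            raise KeyError(f"tap layer {tap!r} not in network")
        for name, layer in self.layers:
            x = layer(x)
            if name == tap:
                return x
        return x

    __call__ = forward

    @property
    def supports_backward(self) -> bool:
        return all(layer.supports_backward for _, layer in self.layers)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def trainable(self) -> list[Layer]:
        return [layer for _, layer in self.layers if layer.params()]

    def replace(self, name: str, layer: Layer) -> None:
        for i, (n, _) in enumerate(self.layers):
            if n == name:
                self.layers[i] = (name, layer)
                return
        raise KeyError(name)


def softmax_cross_entropy(
    logits: np.ndarray, y_idx: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), y_idx] + 1e-12).mean())
    grad = p
    grad[np.arange(n), y_idx] -= 1.0
    return loss, (grad / n).astype(np.float32)


class SGDM:
    """Stochastic gradient descent with momentum and (decoupled-in-L2 sense
    classical) weight decay: v <- m v - lr (g + wd p); p <- p + v."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-4,
        momentum: float = 0.9,
        weight_decay: float = 5e-4,
    ) -> None:
        self.layers = layers
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self._vel: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        for li, layer in enumerate(self.layers):
            params, grads = layer.params(), layer.grads()
            for name, p in params.items():
                g = grads[name]
                if g is None:
                    continue
                key = (li, name)
                v = self._vel.get(key)
                if v is None:
                    v = np.zeros_like(p)
                v = self.momentum * v - self.lr * (g + self.wd * p)
                self._vel[key] = v
                p += v
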