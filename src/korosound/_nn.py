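"""Minimal numpy convolutional network used by the scalogram classifier.

Three conv/ReLU/max-pool blocks and a dense head (~1e5 parameters),
trained with Adam on softmax cross-entropy.  Convolutions are 3x3
'valid', pooling is 2x2.  Everything is seeded and single-threaded, so
training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CompactCNN"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-k+1, W-k+1, k*k*C) patch matrix (view-based)."""
    n, h, w, c = x.shape
    out_h, out_w = h - k + 1, w - k + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, out_h, out_w, k, k, c),
        strides=(s[0], s[1], s[2], s[1], s[2], s[3]),
        writeable=False,
    )
    return patches.reshape(n, out_h, out_w, k * k * c)


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.k = k
        fan_in = k * k * c_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)

    def forward(self, x):
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k)
        return self.cols @ self.w + self.b

    def backward(self, grad):
        n, oh, ow, co = grad.shape
        g2 = grad.reshape(-1, co)
        self.dw = self.cols.reshape(-1, self.w.shape[0]).T @ g2
        self.db = g2.sum(axis=0)
        dcols = grad @ self.w.T  # (n, oh, ow, k*k*c_in)
        k, (n_, h, w, c) = self.k, self.x_shape
        dx = np.zeros(self.x_shape)
        dcols = dcols.reshape(n, oh, ow, k, k, c)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j, :]
        return dx

    def params(self):
        return [(self.w, "dw"), (self.b, "db")]


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self.x_shape = x.shape
        xr = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        self.xr = xr
        out = xr.max(axis=(2, 4))
        self.mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, grad):
        n, h, w, c = self.x_shape
        h2, w2 = h // 2, w // 2
        g = self.mask * grad[:, :, None, :, None, :]
        dx = np.zeros(self.x_shape)
        dx[:, : 2 * h2, : 2 * w2, :] = g.reshape(n, 2 * h2, 2 * w2, c)
        return dx

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self.x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self.x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, "dw"), (self.b, "db")]


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CompactCNN:
    """3-block convolutional classifier for small grayscale images."""

    def __init__(self, image_size: int = 64, n_classes: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.image_size = image_size
        self.layers = []
        size, c = image_size, 1
        for c_out in (8, 16, 32):
            self.layers += [_Conv(c, c_out, rng), _ReLU(), _MaxPool2()]
            size = (size - 2) // 2
            c = c_out
        if size < 1:
            raise ValueError(f"image size {image_size} too small for three conv blocks")
        self.layers.append(_Flatten())
        self.layers.append(_Dense(size * size * c, 64, rng))
        self.layers.append(_ReLU())
        self.layers.append(_Dense(64, n_classes, rng))
        self._adam_state = None

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p, _ in layer.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch of (N, H, W) or (N, H, W, 1) images."""
        if x.ndim == 3:
            x = x[..., None]
        out = x
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(x), axis=1)

    def _backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def train_step(self, x, y, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        """One Adam step on a batch; returns (loss, accuracy)."""
        logits = self.forward(x)
        probs = _softmax(logits)
        n = x.shape[0]
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y] = 1.0
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        acc = float(np.mean(np.argmax(logits, axis=1) == y))
        self._backward((probs - onehot) / n)

        grads = [getattr(layer, gname) for layer in self.layers for _, gname in layer.params()]
        params = [p for layer in self.layers for p, _ in layer.params()]
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for p, g, m, v in zip(params, grads, st["m"], st["v"]):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss, acc

    def evaluate(self, x, y, batch: int = 64):
        """Mean cross-entropy loss and accuracy over a dataset."""
        losses, correct, total = [], 0, 0
        for i in range(0, x.shape[0], batch):
            xb, yb = x[i : i + batch], y[i : i + batch]
            probs = self.predict_proba(xb)
            losses.append(-np.sum(np.log(probs[np.arange(len(yb)), yb] + 1e-12)))
            correct += int(np.sum(np.argmax(probs, axis=1) == yb))
            total += len(yb)
        return float(np.sum(losses) / total), float(correct / total)
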