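"""Minimal feed-forward neural-network engine on numpy.

Implements exactly what the package's two network models need: dense and
3x3 convolutional layers (NHWC layout), ReLU, 2x2 max pooling, global
average pooling, a weighted binary cross-entropy loss on logits, RMSprop
and Adam optimizers, and a training loop with plateau-based early stopping
on the (running) training loss. Backward passes are cached per layer so a
gradient can be read off at any intermediate feature map, which is what
gradient-weighted class-activation mapping needs.

All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Conv2D",
    "MaxPool2",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "RMSprop",
    "Adam",
    "bce_with_logits",
    "sigmoid",
    "train_network",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    """Mean weighted binary cross-entropy and its gradient w.r.t. logits."""
    logits = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = logits.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    # log(1+e^z) computed stably
    softplus = np.logaddexp(0.0, logits)
    loss = float(np.sum(w * (softplus - y * logits)) / np.sum(w))
    grad = w * (sigmoid(logits) - y) / np.sum(w)
    return loss, grad


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self):
        return []

    def grads(self):
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv2D(Layer):
    """3x3 same-padding convolution over NHWC arrays via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.W = rng.normal(0.0, scale, size=(k * k * c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x):
        n, h, w, c = x.shape
        p = self.k // 2
        # edge padding avoids spurious border activations (zero padding
        # creates an artificial high-contrast frame that pollutes CAMs)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="edge")
        cols = np.empty((n, h, w, self.k, self.k, c), dtype=x.dtype)
        for i in range(self.k):
            for j in range(self.k):
                cols[:, :, :, i, j, :] = xp[:, i : i + h, j : j + w, :]
        return cols.reshape(n * h * w, self.k * self.k * c)

    def forward(self, x, train=False):
        self._xshape = x.shape
        n, h, w, _ = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad):
        n, h, w, c = self._xshape
        g = grad.reshape(n * h * w, self.c_out)
        self.dW = self._cols.T @ g
        self.db = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, h, w, self.k, self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        # fold pad-region gradients back onto the replicated edge pixels
        dxp[:, p, :, :] += dxp[:, :p, :, :].sum(axis=1)
        dxp[:, h + p - 1, :, :] += dxp[:, h + p :, :, :].sum(axis=1)
        dxp[:, :, p, :] += dxp[:, :, :p, :].sum(axis=2)
        dxp[:, :, w + p - 1, :] += dxp[:, :, w + p :, :].sum(axis=2)
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        self._xr_shape = xr.shape
        return out

    def backward(self, grad):
        n, h2, _, w2, _, c = self._xr_shape
        g = grad[:, :, None, :, None, :] * self._mask
        # if a 2x2 window has tied maxima split the gradient between them
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        g = g / counts
        return g.reshape(n, h2 * 2, w2 * 2, c)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape).copy()


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def backward_to(self, index: int, grad):
        """Backpropagate ``grad`` from the output down to (but not through)
        ``layers[index]``, returning the gradient w.r.t. that layer's output."""
        for layer in reversed(self.layers[index + 1 :]):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class RMSprop:
    """Root-mean-square propagation with decay 0.9."""

    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache = None

    def step(self, params, grads):
        if self._cache is None:
            self._cache = [np.zeros_like(p) for p in params]
        for p, g, s in zip(params, grads, self._cache, strict=True):
            s[...] = self.rho * s + (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s) + self.eps)


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = None
        self._v = None
        self._t = 0

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1c = 1.0 - self.beta1**self._t
        b2c = 1.0 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v, strict=True):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def train_network(
    model: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    *,
    optimizer,
    epochs: int,
    batch_size: int,
    rng: np.random.Generator,
    sample_weight: np.ndarray | None = None,
    eval_every: int = 10,
    patience: int = 10,
    min_delta: float = 1e-5,
    augment_fn=None,
) -> dict:
    """Mini-batch training with plateau early stopping on the training loss.

    Every ``eval_every`` optimisation steps the training binary
    cross-entropy is evaluated on a fixed evaluation set (the whole
    training set, or a fixed 128-sample subset for large inputs, so the
    estimate is stable across evaluations); if ``patience`` consecutive
    evaluations bring no improvement beyond ``min_delta``, training stops
    and the best-seen weights are restored.

    ``augment_fn(batch, rng) -> batch`` is applied to training batches only.
    Returns training metadata: the loss trace at each evaluation, the
    best-so-far trace, epochs completed, and whether early stopping fired.
    """
    n = X.shape[0]
    y = np.asarray(y, dtype=float).ravel()
    if sample_weight is None:
        sample_weight = np.ones(n)
    if n > 128:
        eval_idx = rng.choice(n, size=128, replace=False)
    else:
        eval_idx = np.arange(n)

    def eval_loss() -> float:
        logits = np.concatenate(
            [model.forward(X[eval_idx[i : i + 64]]).ravel() for i in range(0, len(eval_idx), 64)]
        )
        return bce_with_logits(logits, y[eval_idx], sample_weight[eval_idx])[0]

    best_loss = np.inf
    best_weights = model.get_weights()
    trace: list[float] = []
    best_trace: list[float] = []
    stale = 0
    step = 0
    stopped = False
    epochs_run = 0

    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = X[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            logits = model.forward(xb, train=True).ravel()
            _, dlogits = bce_with_logits(logits, y[idx], sample_weight[idx])
            model.backward(dlogits.reshape(-1, 1))
            optimizer.step(model.params(), model.grads())
            step += 1
            if step % eval_every == 0:
                current = eval_loss()
                trace.append(current)
                if current < best_loss - min_delta:
                    best_loss = current
                    best_weights = model.get_weights()
                    stale = 0
                else:
                    stale += 1
                best_trace.append(best_loss)
                if stale >= patience:
                    stopped = True
                    break
        epochs_run = epoch + 1
        if stopped:
            break

    model.set_weights(best_weights)
    return {
        "loss_trace": trace,
        "best_trace": best_trace,
        "best_loss": best_loss,
        "epochs_run": epochs_run,
        "early_stopped": stopped,
        "steps": step,
    }
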