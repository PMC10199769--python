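"""Minimal neural-network primitives with explicit backpropagation.

The additive architecture needs only three building blocks, all written
directly on NumPy arrays:

* :class:`MLP` — a fully connected ReLU network y = W_L ... relu(W_1 x + b_1);
* :class:`StackedMLP` — N parallel MLPs with identical layer shapes but
  independent weights, evaluated in one einsum per layer (used for the
  per-feature encoders of tabular models);
* :class:`Adam` — the Adam optimizer with optional decoupled weight decay.

Every ``forward`` returns ``(output, cache)`` and the matching ``backward``
consumes ``(grad_output, cache)`` and returns ``(grad_input, param_grads)``,
so gradients with respect to the *inputs* (needed by saliency-style
attribution) come for free.

Parameters are plain lists of float64 arrays; initialization is
Kaiming-uniform, as is conventional for ReLU networks.
"""

from __future__ import annotations

import numpy as np


def relu(x):
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def kaiming_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class MLP:
    """Fully connected network with ReLU hidden activations and linear output.

    ``dims`` lists the layer widths, e.g. ``(24, 64, 64, 7)``.  A two-entry
    ``dims`` is a single affine (or linear, with ``bias=False``) map.
    """

    def __init__(self, dims, rng: np.random.Generator, bias: bool = True):
        self.dims = tuple(int(d) for d in dims)
        self.bias = bias
        self.weights = []
        self.biases = []
        for d_in, d_out in zip(self.dims[:-1], self.dims[1:]):
            self.weights.append(kaiming_uniform(rng, d_in, (d_in, d_out)))
            b = np.zeros(d_out)
            if bias:
                bound = 1.0 / np.sqrt(max(d_in, 1))
                b = rng.uniform(-bound, bound, size=d_out)
            self.biases.append(b)

    @property
    def params(self) -> list:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.append(w)
            if self.bias:
                out.append(b)
        return out

    def set_params(self, params: list) -> None:
        i = 0
        for l in range(len(self.weights)):
            self.weights[l] = params[i]
            i += 1
            if self.bias:
                self.biases[l] = params[i]
                i += 1

    def forward(self, x: np.ndarray):
        """x: (n, d_in) -> (n, d_out). Returns (output, cache)."""
        acts = [x]
        h = x
        n_layers = len(self.weights)
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if l < n_layers - 1:
                h = relu(h)
            acts.append(h)
        return h, acts

    def __call__(self, x):
        return self.forward(x)[0]

    def backward(self, grad_out: np.ndarray, cache):
        """Returns (grad_input, grads aligned with :attr:`params`)."""
        acts = cache
        n_layers = len(self.weights)
        g = grad_out
        w_grads = [None] * n_layers
        b_grads = [None] * n_layers
        for l in range(n_layers - 1, -1, -1):
            if l < n_layers - 1:
                g = g * (acts[l + 1] > 0)  # relu mask on this layer's output
            w_grads[l] = acts[l].T @ g
            b_grads[l] = g.sum(axis=0)
            g = g @ self.weights[l].T
        grads = []
        for wg, bg in zip(w_grads, b_grads):
            grads.append(wg)
            if self.bias:
                grads.append(bg)
        return g, grads


class StackedMLP:
    """N parallel MLPs with shared layer shapes and independent weights.

    Input (n, N, d_in) -> output (n, N, d_out); feature i is transformed by
    its own weight stack, so separability across the feature axis holds by
    construction.
    """

    def __init__(self, n_stack: int, dims, rng: np.random.Generator):
        self.n_stack = int(n_stack)
        self.dims = tuple(int(d) for d in dims)
        self.weights = []
        self.biases = []
        for d_in, d_out in zip(self.dims[:-1], self.dims[1:]):
            self.weights.append(kaiming_uniform(rng, d_in, (self.n_stack, d_in, d_out)))
            bound = 1.0 / np.sqrt(max(d_in, 1))
            self.biases.append(rng.uniform(-bound, bound, size=(self.n_stack, d_out)))

    @property
    def params(self) -> list:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def set_params(self, params: list) -> None:
        for l in range(len(self.weights)):
            self.weights[l] = params[2 * l]
            self.biases[l] = params[2 * l + 1]

    def forward(self, x: np.ndarray):
        acts = [x]
        h = x
        n_layers = len(self.weights)
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = np.einsum("sni,nio->sno", h, w, optimize=True) + b[None]
            if l < n_layers - 1:
                h = relu(h)
            acts.append(h)
        return h, acts

    def __call__(self, x):
        return self.forward(x)[0]

    def backward(self, grad_out: np.ndarray, cache):
        acts = cache
        n_layers = len(self.weights)
        g = grad_out
        grads = [None] * (2 * n_layers)
        for l in range(n_layers - 1, -1, -1):
            if l < n_layers - 1:
                g = g * (acts[l + 1] > 0)
            grads[2 * l] = np.einsum("sni,sno->nio", acts[l], g, optimize=True)
            grads[2 * l + 1] = g.sum(axis=0)
            g = np.einsum("sno,nio->sni", g, self.weights[l], optimize=True)
        return g, grads


class Adam:
    """Adam with optional decoupled weight decay, updating params in place."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)


class SGD:
    """Plain (optionally momentum) SGD; provided as an alternative optimizer."""

    def __init__(self, params, lr=1e-2, momentum=0.0, weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buf = [np.zeros_like(p) for p in params]

    def step(self, grads) -> None:
        for p, g, b in zip(self.params, grads, self.buf):
            g = g + self.weight_decay * p
            b *= self.momentum
            b += g
            p -= self.lr * b


OPTIMIZERS = {"adam": Adam, "sgd": SGD}


def cross_entropy(logits: np.ndarray, labels: np.ndarray, sample_weight=None):
    """Weighted mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    logp = log_softmax(logits)
    if sample_weight is None:
        sample_weight = np.ones(n)
    wsum = sample_weight.sum()
    loss = -(sample_weight * logp[np.arange(n), labels]).sum() / wsum
    grad = softmax(logits)
    grad[np.arange(n), labels] -= 1.0
    grad *= (sample_weight / wsum)[:, None]
    return loss, grad
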