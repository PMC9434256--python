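"""Minimal feed-forward network engine (float32, numpy + BLAS).

Just enough machinery for the small fully connected encoders/decoders used
by the neural embedding methods: Dense, ReLU and BatchNorm layers with
hand-written backprop, the Adam optimizer, and numerically stable
cross-entropy losses.  Everything is seeded through an explicit
``numpy.random.Generator``; no global state.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32

try:  # fused Adam kernel; pure-numpy fallback keeps numba optional
    from numba import njit

    @njit(fastmath=True, cache=False)
    def _adam_kernel(p, g, m, v, lr, b1, b2, eps, b1t, b2t):
        for i in range(p.size):
            m[i] = b1 * m[i] + (1.0 - b1) * g[i]
            v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            p[i] -= lr * (m[i] / b1t) / (np.sqrt(v[i] / b2t) + eps)
except ImportError:  # pragma: no cover - numba is normally present
    _adam_kernel = None


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine layer, He-initialized (suits the ReLU nets used here).

    ``input_grad=False`` skips the dx gemm — set it on the first layer of a
    network, where the gradient w.r.t. the raw genotype input is never used.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 input_grad: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self.input_grad = input_grad
        self._x = None

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T if self.input_grad else None


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, F32(0))

    def backward(self, dy):
        return np.where(self._mask, dy, F32(0))


class BatchNorm(Layer):
    """Standard batch normalization with running statistics for eval mode."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(n, dtype=F32)
        self.beta = np.zeros(n, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(n, dtype=F32)
        self.running_var = np.ones(n, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if train:
            self._cache = (xhat, inv_std.astype(F32))
        return (self.gamma * xhat + self.beta).astype(F32)

    def backward(self, dy):
        xhat, inv_std = self._cache
        m = dy.shape[0]
        self.dgamma += (dy * xhat).sum(axis=0)
        self.dbeta += dy.sum(axis=0)
        dxhat = dy * self.gamma
        dx = (dxhat - dxhat.mean(axis=0)
              - xhat * (dxhat * xhat).mean(axis=0)) * inv_std
        return dx.astype(F32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)
        for l in self.layers:
            self.params.extend(l.params)
            self.grads.extend(l.grads)

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, modules: list[Layer], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = [], []
        for mod in modules:
            self.params.extend(mod.params)
            self.grads.extend(mod.grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            if _adam_kernel is not None and p.flags.c_contiguous:
                _adam_kernel(p.reshape(-1), g.reshape(-1), m.reshape(-1),
                             v.reshape(-1), self.lr, self.b1, self.b2,
                             self.eps, b1t, b2t)
            else:
                m[...] = self.b1 * m + (1 - self.b1) * g
                v[...] = self.b2 * v + (1 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# losses (stable, mean over samples)
# ---------------------------------------------------------------------------

def softmax_xent(logits: np.ndarray, target_class: np.ndarray):
    """Categorical cross-entropy over the last axis.

    ``logits``: (n, sites, classes); ``target_class``: (n, sites) ints.
    Returns (mean loss per sample summed over sites, dlogits).
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    n = logits.shape[0]
    idx = np.ogrid[tuple(slice(s) for s in target_class.shape)]
    logp = z - np.log(ez.sum(axis=-1, keepdims=True))
    loss = -logp[idx[0], idx[1], target_class].sum() / n
    dlogits = p.copy()
    dlogits[idx[0], idx[1], target_class] -= 1
    return float(loss), (dlogits / n).astype(F32)


def bce_with_logits(logits: np.ndarray, target: np.ndarray):
    """Element-wise binary cross-entropy on logits, summed over features,
    mean over samples.  Returns (loss, dlogits)."""
    n = logits.shape[0]
    loss = (np.maximum(logits, 0) - logits * target
            + np.log1p(np.exp(-np.abs(logits)))).sum() / n
    p = 1.0 / (1.0 + np.exp(-logits))
    return float(loss), ((p - target) / n).astype(F32)


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray):
    """KL( N(mu, diag exp(logvar)) || N(0, I) ), summed over dims, mean over
    samples: ½ Σ (μ² + σ² − 1 − log σ²).  Returns (kl, dmu, dlogvar)."""
    n = mu.shape[0]
    var = np.exp(logvar)
    kl = 0.5 * (mu ** 2 + var - 1.0 - logvar).sum() / n
    dmu = mu / n
    dlogvar = 0.5 * (var - 1.0) / n
    return float(kl), dmu.astype(F32), dlogvar.astype(F32)


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
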