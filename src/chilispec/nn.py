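"""Minimal dense/convolutional network engine for the spectral regressors.

The networks here are deliberately tiny (a few thousand parameters, full-batch
training at n <= 159), so the engine is a compact numpy implementation with
explicit forward/backward passes.  Keeping the autodiff by hand also gives the
interpretability module direct access to the gradient at the second
convolution's feature map, which is exactly what 1-D Grad-CAM needs.

Layer plan of the two main architectures (kernel 3, same padding, max-pool
width 2, global average pooling over positions):

``SpectralCNN`` (spectral-only 1-D CNN, 2177 trainable parameters)
    conv(1->16) -> relu -> pool -> conv(16->32) -> relu -> GAP
    -> dense(32->16) -> relu -> dense(16->1)

``FusionNet`` (chemical-spectral fusion, 3929 trainable parameters)
    spectral encoder as above up to the 32-d GAP vector;
    chemical branch dense(2->16) -> relu -> dense(16->8) -> relu;
    concat(40) -> dense(40->48) -> batchnorm(48) -> relu -> dense(48->1)

Global average pooling makes the spectral encoder's parameter count
independent of the number of input bands.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "Conv1d", "ReLU", "MaxPool1d", "GlobalAvgPool", "BatchNorm1d",
    "SpectralCNN", "FusionNet", "ChemNet", "Adam",
]


class Layer:
    """Base class: trainable arrays live in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": _he(rng, (n_in, n_out), n_in),
                       "b": np.zeros(n_out)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class Conv1d(Layer):
    """1-D convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        assert kernel % 2 == 1
        self.kernel = kernel
        self.pad = kernel // 2
        self.params = {"W": _he(rng, (c_out, c_in, kernel), c_in * kernel),
                       "b": np.zeros(c_out)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (n, c_in, L)
        n, c_in, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp, self._L = xp, L
        W, b = self.params["W"], self.params["b"]
        out = np.zeros((n, W.shape[0], L))
        for k in range(self.kernel):
            out += np.einsum("oc,ncl->nol", W[:, :, k], xp[:, :, k:k + L])
        return out + b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        L = self._L
        self.grads["b"] += dy.sum(axis=(0, 2))
        dxp = np.zeros_like(self._xp)
        for k in range(self.kernel):
            self.grads["W"][:, :, k] += np.einsum(
                "nol,ncl->oc", dy, self._xp[:, :, k:k + L])
            dxp[:, :, k:k + L] += np.einsum("oc,nol->ncl", W[:, :, k], dy)
        return dxp[:, :, self.pad:self.pad + L]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the last axis (trailing remainder
    positions are dropped)."""

    def __init__(self, width: int = 2) -> None:
        super().__init__()
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        L2 = L // self.width
        xv = x[:, :, :L2 * self.width].reshape(n, c, L2, self.width)
        self._arg = xv.argmax(axis=3)
        self._in_shape = x.shape
        return xv.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, L = self._in_shape
        L2 = dy.shape[2]
        dx = np.zeros((n, c, L2, self.width))
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=3)
        out = np.zeros((n, c, L))
        out[:, :, :L2 * self.width] = dx.reshape(n, c, L2 * self.width)
        return out


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._L, axis=2) / self._L


class BatchNorm1d(Layer):
    """Batch normalization over (n, c) features with trainable scale + shift.

    Running statistics (not trainable, excluded from parameter counts) are
    tracked with momentum 0.1 and used in evaluation mode.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.grads["gamma"] += (dy * xhat).sum(axis=0)
        self.grads["beta"] += dy.sum(axis=0)
        g = self.params["gamma"] / self._std
        if not self._train:
            return dy * g
        return g * (dy - dy.mean(axis=0) - xhat * (dy * xhat).mean(axis=0))


class _Net:
    """Shared plumbing: parameter flattening, state save/restore, counting."""

    layers: list[Layer]
    tag: str = "net"

    def trainable_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params]

    def zero_grad(self) -> None:
        for l in self.trainable_layers():
            l.zero_grad()

    def parameters(self) -> list[np.ndarray]:
        return [l.params[k] for l in self.trainable_layers() for k in sorted(l.params)]

    def gradients(self) -> list[np.ndarray]:
        return [l.grads[k] for l in self.trainable_layers() for k in sorted(l.grads)]

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.parameters()]
        for l in self.layers:
            if isinstance(l, BatchNorm1d):
                state.append(l.running_mean.copy())
                state.append(l.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[:len(params)]):
            p[...] = s
        extra = state[len(params):]
        i = 0
        for l in self.layers:
            if isinstance(l, BatchNorm1d):
                l.running_mean[...] = extra[i]
                l.running_var[...] = extra[i + 1]
                i += 2


class _SpectralEncoder:
    """conv(1->16)-relu-pool-conv(16->32)-relu-GAP; 1632 parameters."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.conv1 = Conv1d(1, 16, 3, rng)
        self.relu1 = ReLU()
        self.pool = MaxPool1d(2)
        self.conv2 = Conv1d(16, 32, 3, rng)
        self.relu2 = ReLU()
        self.gap = GlobalAvgPool()
        self.layers = [self.conv1, self.relu1, self.pool,
                       self.conv2, self.relu2, self.gap]

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = self.conv1.forward(X[:, None, :])
        h = self.relu1.forward(h)
        h = self.pool.forward(h)
        h = self.conv2.forward(h)
        h = self.relu2.forward(h)
        self.feature_map = h  # (n, 32, L//2)
        return self.gap.forward(h)

    def backward(self, dfeat: np.ndarray) -> np.ndarray:
        d = self.gap.backward(dfeat)
        self.d_feature_map = d  # gradient at the conv2 (post-ReLU) map
        d = self.relu2.backward(d)
        d = self.conv2.backward(d)
        d = self.pool.backward(d)
        d = self.relu1.backward(d)
        return self.conv1.backward(d)


class SpectralCNN(_Net):
    """Spectral-only 1-D CNN regressor (2177 trainable parameters)."""

    tag = "spectral"

    def __init__(self, n_bands: int, seed: int = 0) -> None:
        if n_bands < 4:
            raise ValueError("n_bands must be >= 4")
        rng = np.random.default_rng(seed)
        self.n_bands = n_bands
        self.encoder = _SpectralEncoder(rng)
        self.fc1 = Dense(32, 16, rng)
        self.relu3 = ReLU()
        self.fc2 = Dense(16, 1, rng)
        self.layers = self.encoder.layers + [self.fc1, self.relu3, self.fc2]

    def forward(self, X: np.ndarray, C: np.ndarray | None = None,
                train: bool = True) -> np.ndarray:
        f = self.encoder.forward(np.asarray(X, dtype=float))
        self._features = f
        h = self.relu3.forward(self.fc1.forward(f))
        return self.fc2.forward(h)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        d = self.fc2.backward(dy[:, None])
        d = self.fc1.backward(self.relu3.backward(d))
        self.encoder.backward(d)

    def features(self, X: np.ndarray, C: np.ndarray | None = None) -> np.ndarray:
        """Pre-head feature vector (the 32-d pooled spectral encoding)."""
        self.forward(X, train=False)
        return self._features


class ChemNet(_Net):
    """Chemical-only regressor: the fusion model's chemical branch + a head."""

    tag = "chemical"

    def __init__(self, n_bands: int = 0, n_chem: int = 2, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.fc1 = Dense(n_chem, 16, rng)
        self.relu1 = ReLU()
        self.fc2 = Dense(16, 8, rng)
        self.relu2 = ReLU()
        self.head = Dense(8, 1, rng)
        self.layers = [self.fc1, self.relu1, self.fc2, self.relu2, self.head]

    def forward(self, X: np.ndarray | None, C: np.ndarray,
                train: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.fc1.forward(np.asarray(C, dtype=float)))
        h = self.relu2.forward(self.fc2.forward(h))
        self._features = h
        return self.head.forward(h)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        d = self.head.backward(dy[:, None])
        d = self.fc2.backward(self.relu2.backward(d))
        self.fc1.backward(self.relu1.backward(d))

    def features(self, X: np.ndarray | None, C: np.ndarray) -> np.ndarray:
        self.forward(X, C, train=False)
        return self._features


class FusionNet(_Net):
    """Chemical-spectral fusion regressor (3929 trainable parameters).

    The 32-d spectral encoding is concatenated with an 8-d embedding of the
    two chemical inputs; the fused 40-d vector passes through a 48-unit dense
    layer with batch normalization before the regression head.
    """

    tag = "mcsf"

    def __init__(self, n_bands: int, n_chem: int = 2, seed: int = 0) -> None:
        if n_bands < 4:
            raise ValueError("n_bands must be >= 4")
        rng = np.random.default_rng(seed)
        self.n_bands = n_bands
        self.encoder = _SpectralEncoder(rng)
        self.chem_fc1 = Dense(n_chem, 16, rng)
        self.chem_relu1 = ReLU()
        self.chem_fc2 = Dense(16, 8, rng)
        self.chem_relu2 = ReLU()
        self.fuse = Dense(32 + 8, 48, rng)
        self.bn = BatchNorm1d(48)
        self.fuse_relu = ReLU()
        self.head = Dense(48, 1, rng)
        self.layers = self.encoder.layers + [
            self.chem_fc1, self.chem_relu1, self.chem_fc2, self.chem_relu2,
            self.fuse, self.bn, self.fuse_relu, self.head,
        ]

    def forward(self, X: np.ndarray, C: np.ndarray, train: bool = True) -> np.ndarray:
        fs = self.encoder.forward(np.asarray(X, dtype=float))
        h = self.chem_relu1.forward(self.chem_fc1.forward(np.asarray(C, dtype=float)))
        fc = self.chem_relu2.forward(self.chem_fc2.forward(h))
        fused = np.concatenate([fs, fc], axis=1)
        self._features = fused
        z = self.fuse.forward(fused)
        z = self.bn.forward(z, train=train)
        z = self.fuse_relu.forward(z)
        return self.head.forward(z)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        d = self.head.backward(dy[:, None])
        d = self.fuse_relu.backward(d)
        d = self.bn.backward(d)
        d = self.fuse.backward(d)
        ds, dc = d[:, :32], d[:, 32:]
        dc = self.chem_fc2.backward(self.chem_relu2.backward(dc))
        self.chem_fc1.backward(self.chem_relu1.backward(dc))
        self.encoder.backward(ds)

    def features(self, X: np.ndarray, C: np.ndarray) -> np.ndarray:
        """Pre-head fused feature vector (40-d concat)."""
        self.forward(X, C, train=False)
        return self._features


class Adam:
    """Adaptive-moment gradient descent on a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
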