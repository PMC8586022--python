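"""Minimal numpy neural-network engine for the kmer-current regressor.

Implements exactly the layer types the architecture needs — graph
convolution with symmetric adjacency renormalization, valid 1-D convolution,
2x2 stride-1 average pooling, row-wise flatten, dense layers, and inverted
dropout — together with mean-squared-error loss and the Adam optimizer.
All gradients are hand-derived and validated against numerical
differentiation in the test suite.

The graph convolution follows the renormalized propagation rule

    H^(l+1) = sigma( D̃^(-1/2) (A + I) D̃^(-1/2) H^(l) W^(l) )

where D̃ is the degree matrix of A + I.  The inverse-square-root scaling
keeps feature magnitudes stable as layers stack; zero-padded atoms receive
only a self-loop, so their activations stay zero whenever their input
features are zero.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "normalize_adjacency",
    "elu",
    "Layer",
    "GraphConv",
    "Conv1D",
    "AvgPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "glorot_uniform",
]


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric renormalization ``D̃^(-1/2) (A + I) D̃^(-1/2)``.

    Accepts a single (P, P) matrix or a batch (B, P, P).  ``A`` must be
    symmetric with a zero diagonal; self-edges are added here.
    """
    A = np.asarray(A, dtype=np.float64)
    if not np.allclose(A, np.swapaxes(A, -1, -2)):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.abs(np.diagonal(A, axis1=-2, axis2=-1)) > 0):
        raise ValueError("adjacency must have a zero diagonal (self-edges are added here)")
    eye = np.eye(A.shape[-1])
    A_tilde = A + eye
    deg = A_tilde.sum(axis=-1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return A_tilde * inv_sqrt[..., :, None] * inv_sqrt[..., None, :]


def elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(z))


def _elu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, np.exp(z))


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: optional parameters plus forward/backward passes."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class GraphConv(Layer):
    """Graph convolution ``ELU(Â H W)`` with no bias.

    The normalized adjacency ``Â`` is per-sample and supplied by the
    network at forward time.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = glorot_uniform(rng, (c_in, c_out), c_in, c_out)

    def forward_graph(self, A_hat: np.ndarray, H: np.ndarray,
                      train: bool = False,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
        M = np.einsum("bij,bjf->bif", A_hat, H)
        Z = M @ self.params["W"]
        self._A_hat, self._M, self._Z = A_hat, M, Z
        return elu(Z)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dZ = dout * _elu_grad(self._Z)
        self.grads["W"] = np.einsum("bpi,bpo->io", self._M, dZ)
        dM = dZ @ self.params["W"].T
        # Â is symmetric, so Â^T dM = Â dM
        return np.einsum("bij,bjf->bif", self._A_hat, dM)


class Conv1D(Layer):
    """Valid 1-D convolution over the length axis with ReLU activation.

    Input (B, L, C_in) -> output (B, L - K + 1, C_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.K = c_in, c_out, kernel_size
        fan_in = kernel_size * c_in
        fan_out = kernel_size * c_out
        self.params["W"] = glorot_uniform(
            rng, (kernel_size * c_in, c_out), fan_in, fan_out
        )
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        if L < self.K:
            raise ValueError(f"input length {L} < kernel size {self.K}")
        # (B, L-K+1, C, K) -> (B, L-K+1, K, C) -> (B, L-K+1, K*C)
        win = np.lib.stride_tricks.sliding_window_view(x, self.K, axis=1)
        patches = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            B, L - self.K + 1, self.K * C
        )
        Z = patches @ self.params["W"] + self.params["b"]
        self._patches, self._Z, self._in_shape = patches, Z, x.shape
        return np.maximum(Z, 0.0)

    def backward(self, dout):
        dZ = dout * (self._Z > 0)
        self.grads["b"] = dZ.sum(axis=(0, 1))
        self.grads["W"] = np.einsum("blk,blo->ko", self._patches, dZ)
        dpatches = (dZ @ self.params["W"].T).reshape(
            dZ.shape[0], dZ.shape[1], self.K, self.c_in
        )
        dx = np.zeros(self._in_shape)
        L_out = dZ.shape[1]
        for t in range(self.K):
            dx[:, t : t + L_out, :] += dpatches[:, :, t, :]
        return dx


class AvgPool2(Layer):
    """2x2 average pooling with stride 1 over the (length, channels) matrix.

    Shrinks both dimensions by one: (B, m, n) -> (B, m-1, n-1).
    """

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return (x[:, :-1, :-1] + x[:, 1:, :-1] + x[:, :-1, 1:] + x[:, 1:, 1:]) / 4.0

    def backward(self, dout):
        dx = np.zeros(self._in_shape)
        q = dout / 4.0
        dx[:, :-1, :-1] += q
        dx[:, 1:, :-1] += q
        dx[:, :-1, 1:] += q
        dx[:, 1:, 1:] += q
        return dx


class Flatten(Layer):
    """Row-wise flatten: (B, m, n) -> (B, m*n)."""

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    """Affine layer, optionally followed by ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: Optional[str] = None):
        super().__init__()
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self.params["W"] = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False, rng=None):
        Z = x @ self.params["W"] + self.params["b"]
        self._x, self._Z = x, Z
        return np.maximum(Z, 0.0) if self.activation == "relu" else Z

    def backward(self, dout):
        dZ = dout * (self._Z > 0) if self.activation == "relu" else dout
        self.grads["W"] = self._x.T @ dZ
        self.grads["b"] = dZ.sum(axis=0)
        return dZ @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Network:
    """A feed-forward stack; graph-convolution layers consume the shared Â."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, A_hat: np.ndarray, X: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        h = np.asarray(X, dtype=np.float64)
        A_hat = np.asarray(A_hat, dtype=np.float64)
        for layer in self.layers:
            if isinstance(layer, GraphConv):
                h = layer.forward_graph(A_hat, h, train=train, rng=rng)
            else:
                h = layer.forward(h, train=train, rng=rng)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = dout
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def gcn_activations(self, A_hat: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Post-activation output of the final graph-convolution layer.

        Dropout and downstream layers are bypassed (inference mode).
        """
        h = np.asarray(X, dtype=np.float64)
        A_hat = np.asarray(A_hat, dtype=np.float64)
        for layer in self.layers:
            if isinstance(layer, GraphConv):
                h = layer.forward_graph(A_hat, h)
        return h

    def parameters(self) -> Iterator[tuple[int, str, np.ndarray]]:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield i, name, layer.params[name]

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{i}:{name}": arr.copy() for i, name, arr in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, name, _ in self.parameters():
            self.layers[i].params[name] = weights[f"{i}:{name}"].copy()


class Adam:
    """Adam optimizer with the canonical defaults (lr 1e-3, 0.9/0.999, 1e-8)."""

    def __init__(self, network: Network, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = network
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self.m = {f"{i}:{n}": np.zeros_like(p) for i, n, p in network.parameters()}
        self.v = {f"{i}:{n}": np.zeros_like(p) for i, n, p in network.parameters()}

    def step(self) -> None:
        self.t += 1
        for i, name, p in self.net.parameters():
            key = f"{i}:{name}"
            g = self.net.layers[i].grads[name]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            m_hat = self.m[key] / (1 - self.b1**self.t)
            v_hat = self.v[key] / (1 - self.b2**self.t)
            self.net.layers[i].params[name] = p - self.lr * m_hat / (
                np.sqrt(v_hat) + self.eps
            )
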