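"""Minimal fully connected networks with manual backprop and Adam.

The two decision networks are small (tens of thousands of weights), so a
self-contained numpy implementation keeps the package dependency-light and
makes every forward/backward pass bit-reproducible given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenseNet", "Adam"]


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


class DenseNet:
    """Feed-forward net: hidden layers use Leaky ReLU, the output is linear.

    ``sizes`` lists all layer widths including input and output, e.g.
    ``(21, 128, 64, 32, 8)`` for three hidden layers.
    """

    def __init__(self, sizes: tuple[int, ...], seed: int = 0, leaky_slope: float = 0.1):
        if len(sizes) < 2:
            raise ValueError("need at least an input and an output width")
        self.sizes = tuple(int(s) for s in sizes)
        self.leaky_slope = float(leaky_slope)
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for nin, nout in zip(self.sizes, self.sizes[1:]):
            # He-style init, appropriate for the rectified hidden units
            self.weights.append(rng.standard_normal((nin, nout)) * np.sqrt(2.0 / nin))
            self.biases.append(np.zeros(nout))

    @property
    def n_in(self) -> int:
        return self.sizes[0]

    @property
    def n_out(self) -> int:
        return self.sizes[-1]

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Forward pass; accepts (n_in,) or (batch, n_in)."""
        out, _ = self._forward_cache(np.atleast_2d(np.asarray(x, dtype=float)))
        return out[0] if np.asarray(x).ndim == 1 else out

    def _forward_cache(self, X: np.ndarray):
        cache = [("input", X)]
        h = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            if i < last:
                h = _leaky_relu(z, self.leaky_slope)
                cache.append(("hidden", z))
            else:
                h = z
                cache.append(("linear", z))
        return h, cache

    def backward(self, cache, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients of a scalar loss wrt parameters, given dL/d(output).

        Returns gradients in the order of :meth:`parameters`.
        """
        grads_W: list[np.ndarray] = [np.empty(0)] * len(self.weights)
        grads_b: list[np.ndarray] = [np.empty(0)] * len(self.biases)
        delta = dout
        for i in range(len(self.weights) - 1, -1, -1):
            kind, z = cache[i + 1]
            if kind == "hidden":
                delta = delta * np.where(z >= 0, 1.0, self.leaky_slope)
            h_prev = cache[i][1] if i == 0 else self._activate(cache[i])
            grads_W[i] = h_prev.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
        return grads_W + grads_b

    def _activate(self, entry):
        kind, z = entry
        if kind == "hidden":
            return _leaky_relu(z, self.leaky_slope)
        return z

    def loss_mse_selected(self, X: np.ndarray, cols: np.ndarray, targets: np.ndarray):
        """Mean squared error on one selected output column per row.

        Returns (loss, parameter gradients); the workhorse for both the
        temporal-difference and the supervised regression updates.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = np.asarray(cols, dtype=int)
        targets = np.asarray(targets, dtype=float)
        out, cache = self._forward_cache(X)
        rows = np.arange(X.shape[0])
        pred = out[rows, cols]
        resid = pred - targets
        loss = float(np.mean(resid**2))
        dout = np.zeros_like(out)
        dout[rows, cols] = 2.0 * resid / X.shape[0]
        return loss, self.backward(cache, dout)

    def state_dict(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {"sizes": np.array(self.sizes), "slope": np.array(self.leaky_slope)}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            d[f"W{i}"] = W
            d[f"b{i}"] = b
        return d

    @classmethod
    def from_state_dict(cls, d: dict[str, np.ndarray]) -> "DenseNet":
        net = cls(tuple(int(s) for s in d["sizes"]), seed=0, leaky_slope=float(d["slope"]))
        for i in range(len(net.weights)):
            net.weights[i] = np.asarray(d[f"W{i}"], dtype=float)
            net.biases[i] = np.asarray(d[f"b{i}"], dtype=float)
        return net


class Adam:
    """Standard Adam optimizer over a list of parameter arrays (in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
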