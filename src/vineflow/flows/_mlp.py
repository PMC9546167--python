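"""Small fully-connected conditioner network and Adam, in plain numpy.

The conditioner maps one coordinate of a coupling block to the unconstrained
spline parameters of the other coordinate.  Two tanh hidden layers; the
output layer is initialized near zero so the whole flow starts at the
identity map.
"""

from __future__ import annotations

import numpy as np


class MLP:
    def __init__(self, n_in: int, hidden: int, n_out: int, rng, out_scale: float = 0.01):
        sizes = [n_in, hidden, hidden, n_out]
        self.weights = []
        self.biases = []
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = np.sqrt(2.0 / a)
            w = rng.normal(0.0, scale, size=(a, b))
            if i == len(sizes) - 2:
                w *= out_scale
            self.weights.append(w)
            self.biases.append(np.zeros(b))
        self._cache = None

    def params(self):
        return self.weights + self.biases

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        acts = [x]
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = np.tanh(h)
            acts.append(h)
        if keep_cache:
            self._cache = acts
        return h

    def backward(self, gout: np.ndarray):
        """Backprop through the cached forward pass.

        Returns (ginput, grads) where grads is aligned with ``params()``.
        """
        acts = self._cache
        gw = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        g = gout
        for i in range(len(self.weights) - 1, -1, -1):
            a_in = acts[i]
            if i < len(self.weights) - 1:
                # acts[i+1] stores the post-tanh activation
                g = g * (1.0 - acts[i + 1] ** 2)
            gw[i] = a_in.T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        return g, gw + gb


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
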