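"""Small fully connected networks and an Adam optimizer on raw numpy arrays.

The forward pass is written against the operator surface shared by
``numpy.ndarray`` and :class:`idras._tensor.Tensor`, so the same code runs
with and without gradient tracking.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, as_tensor, tanh

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected network with tanh hidden activations, linear output.

    Parameters are plain float64 numpy arrays; :meth:`tensor_params` wraps
    them (sharing storage) for autodiff.  ``hidden=()`` gives a single
    linear layer.
    """

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int,
                 rng: np.random.Generator):
        sizes = [int(n_in), *map(int, hidden), int(n_out)]
        self.sizes = sizes
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            # Glorot-style scale keeps tanh pre-activations O(1)
            scale = np.sqrt(2.0 / (a + b))
            self.weights.append(rng.normal(0.0, scale, size=(a, b)))
            self.biases.append(np.zeros(b))

    @property
    def n_in(self) -> int:
        return self.sizes[0]

    @property
    def n_out(self) -> int:
        return self.sizes[-1]

    def params(self) -> list[np.ndarray]:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def tensor_params(self) -> list[Tensor]:
        return [Tensor(p, requires_grad=True) for p in self.params()]

    def forward(self, x, params=None):
        """Apply the network to a batch ``x`` of shape (B, n_in).

        ``params`` may be the flat list from :meth:`tensor_params` to run
        under autodiff; otherwise the stored numpy arrays are used.
        """
        if params is None:
            params = self.params()
        if isinstance(params[0], Tensor):
            x = as_tensor(x)
        n_layers = len(params) // 2
        h = x
        for i in range(n_layers):
            h = h @ params[2 * i] + params[2 * i + 1]
            if i < n_layers - 1:
                h = tanh(h)
        return h

    __call__ = forward


class Adam:
    """Adam over a flat list of parameter arrays, updated in place."""

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
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
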