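"""Neural building blocks on the autodiff engine: linear layers, MLPs,
a single-head graph-attention layer over a dense masked adjacency, and Adam.

Graphs in this domain are small (hundreds of nodes), so attention is
computed as a dense masked row-softmax rather than per-edge scatter ops.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, elu, leaky_relu, relu

__all__ = ["Parameter", "Linear", "MLP", "GATLayer", "Adam", "glorot", "softmax_rows"]


class Parameter(Tensor):
    """A leaf tensor that receives gradients and is updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=float), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, bias: bool = True):
        self.weight = Parameter(glorot(rng, n_in, n_out))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class MLP:
    """Multi-layer perceptron with a leaky rectifier between layers (none
    after the last).  The small negative slope avoids dead hidden units on
    the all-positive similarity inputs this model feeds it.

    ``layers`` counts linear layers; a 1-layer MLP is a plain linear map.
    """

    def __init__(self, rng, n_in: int, n_hidden: int, n_out: int, layers: int = 2,
                 slope: float = 0.2):
        if layers < 1:
            raise ValueError("an MLP needs at least one layer")
        dims = [n_in] + [n_hidden] * (layers - 1) + [n_out]
        self.linears = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        for i, lin in enumerate(self.linears):
            x = lin(x)
            if i < len(self.linears) - 1:
                x = leaky_relu(x, self.slope)
        return x

    def parameters(self):
        return [p for lin in self.linears for p in lin.parameters()]


def softmax_rows(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row softmax of ``scores`` restricted to ``mask`` (0/1 matrix).

    Masked-out entries get weight 0; rows are normalised over their masked
    support.  A stop-gradient row max keeps the exponentials stable.
    """
    shift = np.where(mask > 0, scores.data, -np.inf).max(axis=1, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)  # all-masked rows
    e = (scores - Tensor(shift)).exp() * Tensor(mask)
    denom = e.sum(axis=1, keepdims=True) + Tensor(1e-30)
    return e / denom


class GATLayer:
    """Single-head graph attention over a dense adjacency mask.

    For node i with neighbourhood N(i) (self-loop always included), the
    attention logit toward neighbour j is
    ``LeakyReLU(a_dst . W h_i + a_src . W h_j)``, normalised by a softmax
    over N(i); the output is ``act(sum_j alpha_ij W h_j)`` with an ELU
    activation.  Isolated nodes therefore return ``act(W h_i)``.
    """

    def __init__(self, rng, n_in: int, n_out: int, slope: float = 0.2):
        self.weight = Parameter(glorot(rng, n_in, n_out))
        self.att_dst = Parameter(glorot(rng, n_out, 1, shape=(n_out,)))
        self.att_src = Parameter(glorot(rng, n_out, 1, shape=(n_out,)))
        self.bias = Parameter(np.zeros(n_out))
        self.slope = slope

    def precompute(self, h: Tensor):
        """Transformed features and the dense score matrix for input ``h``.

        These depend only on the features, not the adjacency, so encoding
        several views of the same sign can share one computation.
        """
        n = h.shape[0]
        hw = h @ self.weight  # (n, d)
        e_dst = hw @ self.att_dst  # (n,)
        e_src = hw @ self.att_src  # (n,)
        scores = leaky_relu(
            e_dst.reshape(n, 1) + e_src.reshape(1, n), slope=self.slope
        )
        return hw, scores

    def __call__(self, h: Tensor, mask: np.ndarray, pre=None) -> Tensor:
        n = h.shape[0] if h is not None else pre[0].shape[0]
        mask = np.asarray(mask, dtype=float) + np.eye(n)
        mask = (mask > 0).astype(float)
        hw, scores = pre if pre is not None else self.precompute(h)
        alpha = softmax_rows(scores, mask)
        return elu(alpha @ hw + self.bias)

    def parameters(self):
        return [self.weight, self.att_dst, self.att_src, self.bias]


class Adam:
    """Adam with additive L2 weight decay on the gradients."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
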