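"""Loss functions: inter-/intra-view contrastive objectives, 3-class sign
cross-entropy, the combined losses, and the projection mean-squared error.

The contrastive terms are InfoNCE-style with cosine similarity and
temperature tau.  The inter-view loss aligns the same node across different
views of the same sign while repelling different nodes (the denominator sums
over j != i only, so a perfectly aligned pair drives the term to
-sim/tau + log-sum-exp over negatives, which can be negative).  The
intra-view loss pulls each fused embedding toward that node's positive-view
embeddings and away from its negative-view embeddings.  Training minimises

    L = L_label + beta * L_CL,    L_CL = (1 - alpha) * L_inter + alpha * L_intra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .encoder import N_VIEWS, ViewEmbeddings
from .nn import MLP

__all__ = [
    "LossConfig",
    "cosine_sim",
    "inter_view_loss",
    "intra_view_loss",
    "contrastive_loss",
    "predict_sign",
    "label_loss",
    "total_loss",
    "projection_mse",
]

_EPS = 1e-12


@dataclass
class LossConfig:
    """Contrastive-loss knobs: temperature tau, inter/intra mix alpha, and
    the total-loss weight beta on the contrastive term."""

    tau: float = 0.05
    alpha: float = 0.8
    beta: float = 0.01

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("temperature tau must be positive")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")


def _normalize_rows(z: Tensor) -> Tensor:
    """Rows scaled to unit L2 norm (zero rows stay ~zero)."""
    sq = (z * z).sum(axis=1, keepdims=True)
    return z * ((sq + _EPS) ** -0.5)


def cosine_sim(a, b) -> float:
    """Cosine similarity of two vectors; zero vectors give 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def _cosine_matrix(za: Tensor, zb: Tensor) -> Tensor:
    return _normalize_rows(za) @ _normalize_rows(zb).T


def _lse_offdiag(sim: Tensor, tau: float) -> Tensor:
    """Row-wise log(sum_{j != i} exp(sim_ij / tau)), stabilised."""
    n = sim.shape[0]
    off = 1.0 - np.eye(n)
    scaled = sim * (1.0 / tau)
    shift = np.where(off > 0, scaled.data, -np.inf).max(axis=1, keepdims=True)
    e = (scaled - Tensor(shift)).exp() * Tensor(off)
    return e.sum(axis=1, keepdims=True).log() + Tensor(shift)


def _gather(z: Tensor, batch: np.ndarray, full: bool) -> Tensor:
    return z if full else z.take_rows(batch)


def _inter_one_sign(ve: ViewEmbeddings, sign: str, cfg: LossConfig, batch) -> Tensor:
    n_all = ve.z[(0, sign)].shape[0]
    full = len(batch) == n_all and np.array_equal(batch, np.arange(n_all))
    normed = {
        k: _normalize_rows(_gather(ve.z[(k, sign)], batch, full))
        for k in range(N_VIEWS)
    }
    n = len(batch)
    eye = Tensor(np.eye(n))
    terms = []
    # sim(z_k, z_k') for the ordered pair (k', k) is the transpose of (k, k')
    for k in range(N_VIEWS):
        for kp in range(k + 1, N_VIEWS):
            sim = normed[k] @ normed[kp].T
            for s in (sim, sim.T):
                pos = (s * eye).sum(axis=1, keepdims=True) * (1.0 / cfg.tau)
                terms.append((_lse_offdiag(s, cfg.tau) - pos).mean())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def inter_view_loss(ve: ViewEmbeddings, cfg: LossConfig, batch=None) -> Tensor:
    """Inter-view InfoNCE, averaged over nodes and ordered view pairs, summed
    over the positive-graph and negative-graph perspectives."""
    ve.require_complete()
    n = ve.z[(0, "+")].shape[0]
    batch = np.arange(n) if batch is None else np.asarray(batch, dtype=int)
    if len(batch) < 2:
        raise ValueError("inter-view loss needs at least 2 nodes in the batch")
    return _inter_one_sign(ve, "+", cfg, batch) + _inter_one_sign(ve, "-", cfg, batch)


def intra_view_loss(fused: Tensor, ve: ViewEmbeddings, cfg: LossConfig, batch=None) -> Tensor:
    """Intra-view loss: -log of the ratio of summed exp-similarities of the
    fused embedding to its positive-view vs negative-view embeddings."""
    ve.require_complete()
    n = fused.shape[0]
    full = batch is None
    batch = np.arange(n) if batch is None else np.asarray(batch, dtype=int)
    zf = _normalize_rows(_gather(fused, batch, full))

    def side(sign):
        exps = []
        for k in range(N_VIEWS):
            zk = _normalize_rows(_gather(ve.z[(k, sign)], batch, full))
            sim = (zf * zk).sum(axis=1, keepdims=True)  # per-node cosine
            exps.append((sim * (1.0 / cfg.tau)).exp())
        total = exps[0]
        for e in exps[1:]:
            total = total + e
        return total

    ratio = side("+") / side("-")
    return (ratio.log() * -1.0).mean()


def contrastive_loss(l_inter, l_intra, cfg: LossConfig):
    """L_CL = (1 - alpha) L_inter + alpha L_intra."""
    return l_inter * (1.0 - cfg.alpha) + l_intra * cfg.alpha


class SignPredictor:
    """MLP mapping a concatenated node-pair embedding to a probability triple
    (P_down, P_none, P_up).

    ``output_normalization``: "softmax" (default; the three probabilities
    sum to 1 by construction) or "sigmoid" (elementwise logistic scores
    renormalised to sum to 1).
    """

    def __init__(self, rng, d: int, layers: int = 2, output_normalization: str = "softmax"):
        if output_normalization not in ("softmax", "sigmoid"):
            raise ValueError("output_normalization must be 'softmax' or 'sigmoid'")
        if not (1 <= layers <= 4):
            raise ValueError("predictor depth must be between 1 and 4 layers")
        self.mlp = MLP(rng, 2 * d, d, 3, layers=layers)
        self.output_normalization = output_normalization

    def __call__(self, z_u: Tensor, z_v: Tensor) -> Tensor:
        logits = self.mlp(concat([z_u, z_v], axis=-1))
        if self.output_normalization == "softmax":
            shift = logits.data.max(axis=-1, keepdims=True)
            e = (logits - Tensor(shift)).exp()
        else:
            e = 1.0 / ((logits * -1.0).exp() + 1.0)
        return e / e.sum(axis=-1, keepdims=True)

    def parameters(self):
        return self.mlp.parameters()


def predict_sign(z_u, z_v, predictor: SignPredictor) -> Tensor:
    """Probability triple(s) (P_down, P_none, P_up) for node pair(s)."""
    z_u = z_u if isinstance(z_u, Tensor) else Tensor(z_u)
    z_v = z_v if isinstance(z_v, Tensor) else Tensor(z_v)
    return predictor(z_u, z_v)


def label_loss(probs: Tensor, labels) -> Tensor:
    """Mean 3-class cross-entropy.

    ``labels`` are classes in {-1, 0, +1}, internally one-hot over columns
    (down, none, up); the log is floored at 1e-12.
    """
    labels = np.asarray(labels)
    onehot = np.zeros(probs.shape)
    onehot[np.arange(len(labels)), labels + 1] = 1.0
    ll = probs.log(floor=_EPS) * Tensor(onehot)
    return ll.sum() * (-1.0 / len(labels))


def total_loss(l_label, l_cl, cfg: LossConfig):
    """L = L_label + beta * L_CL."""
    return l_label + l_cl * cfg.beta


def projection_mse(outputs: Tensor, targets) -> Tensor:
    """Mean over genes of the squared L2 distance between the projection
    output and the frozen final embedding."""
    targets = targets if isinstance(targets, Tensor) else Tensor(targets)
    diff = outputs - targets
    return (diff * diff).sum(axis=1).mean()
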