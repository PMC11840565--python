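"""Signed random walk with restart (SRWR) diffusion.

A signed random surfer starts at a seed node with a positive sign and, at
each step, either restarts at the seed (probability ``c``) or moves to a
uniformly chosen neighbour.  Crossing a negative edge flips the surfer's
sign.  Strict balance theory is relaxed by two attenuation factors: a
negative surfer crossing a negative edge turns positive with probability
``beta`` (else stays negative), and crossing a positive edge stays negative
with probability ``gamma`` (else turns positive).  The stationary positive
and negative visiting probabilities r+ and r- satisfy the coupled fixed
point

    r+ = (1 - c) (A+^T r+ + beta A-^T r- + (1 - gamma) A+^T r-) + c q
    r- = (1 - c) (A-^T r+ + gamma A+^T r- + (1 - beta) A-^T r-)

where A+ / A- are the positive/negative parts of the semi-row-normalised
signed adjacency and q is the one-hot seed vector.  Running every node as a
seed fills row-stochastic score matrices r_p and r_n, which are symmetrised
into the signed diffusion matrix

    r_d = max(r_p, r_p^T) - max(r_n, r_n^T).

The top-|k| entries of |r_d| restricted to the gene x phenotype block give a
densified "diffusion graph" used for augmentation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph import SignedBipartiteGraph

__all__ = [
    "DiffusionConfig",
    "NormalizedAdjacency",
    "SeedResult",
    "DiffusionMatrix",
    "semi_row_normalize",
    "srwr_seed",
    "srwr_exact",
    "srwr_all_seeds",
    "symmetrize",
    "diffusion_to_graph",
    "adjacency_diffusion_graph",
]


@dataclass(frozen=True)
class DiffusionConfig:
    """SRWR parameters.

    c : restart probability in (0, 1].
    beta : probability a negative surfer turns positive on a negative edge.
    gamma : probability a negative surfer stays negative on a positive edge.
    epsilon : L1 convergence tolerance on the stacked iterate.
    max_iter : iteration cap; exceeding it flags the result non-converged.
    """

    c: float = 0.15
    beta: float = 0.5
    gamma: float = 0.5
    epsilon: float = 1e-9
    max_iter: int = 200

    def __post_init__(self) -> None:
        if not (0.0 < self.c <= 1.0):
            raise ValueError("restart probability c must be in (0, 1]")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


@dataclass
class NormalizedAdjacency:
    """Positive and negative parts of the semi-row-normalised adjacency."""

    a_plus: np.ndarray
    a_minus: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.a_plus.shape[0]


@dataclass
class SeedResult:
    """Converged (or last-iterate) SRWR vectors for one seed."""

    r_plus: np.ndarray
    r_minus: np.ndarray
    iterations: int
    final_delta: float
    converged: bool = True


@dataclass
class DiffusionMatrix:
    """All-seed SRWR scores; row s holds the vectors seeded at node s."""

    r_p: np.ndarray
    r_n: np.ndarray
    r_d: np.ndarray = None


def semi_row_normalize(a: np.ndarray) -> NormalizedAdjacency:
    """Split D^{-1}A into nonnegative positive/negative parts.

    D is the diagonal of absolute row sums; zero-degree rows stay all-zero.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    deg = np.abs(a).sum(axis=1)
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    at = a * inv[:, None]
    return NormalizedAdjacency(np.maximum(at, 0.0), np.maximum(-at, 0.0))


def _step(norm: NormalizedAdjacency, rp, rn, q, cfg: DiffusionConfig):
    """One simultaneous (Jacobi) update of the coupled SRWR system.

    ``rp``/``rn`` may be vectors (one seed) or matrices whose rows are
    per-seed vectors; in the matrix case ``q`` is the matching seed matrix
    and the transposed products become right-multiplications.
    """
    ap, am = norm.a_plus, norm.a_minus
    c, b, g = cfg.c, cfg.beta, cfg.gamma
    if rp.ndim == 1:
        new_p = (1 - c) * (ap.T @ rp + b * (am.T @ rn) + (1 - g) * (ap.T @ rn)) + c * q
        new_n = (1 - c) * (am.T @ rp + g * (ap.T @ rn) + (1 - b) * (am.T @ rn))
    else:
        new_p = (1 - c) * (rp @ ap + b * (rn @ am) + (1 - g) * (rn @ ap)) + c * q
        new_n = (1 - c) * (rp @ am + g * (rn @ ap) + (1 - b) * (rn @ am))
    return new_p, new_n


def srwr_seed(norm: NormalizedAdjacency, seed: int, cfg: DiffusionConfig = None) -> SeedResult:
    """Iterate the coupled SRWR updates from a one-hot seed to convergence.

    Both updates read the previous iterate (simultaneous update); iteration
    stops when the L1 distance between consecutive stacked iterates drops
    below ``cfg.epsilon`` or ``cfg.max_iter`` is reached (the latter flags
    the result non-converged with a warning).
    """
    cfg = cfg or DiffusionConfig()
    n = norm.n_nodes
    if not (0 <= seed < n):
        raise ValueError(f"seed index {seed} out of range for {n} nodes")
    q = np.zeros(n)
    q[seed] = 1.0
    rp, rn = q.copy(), np.zeros(n)
    delta = np.inf
    for it in range(1, cfg.max_iter + 1):
        new_p, new_n = _step(norm, rp, rn, q, cfg)
        delta = np.abs(new_p - rp).sum() + np.abs(new_n - rn).sum()
        rp, rn = new_p, new_n
        if delta < cfg.epsilon:
            return SeedResult(rp, rn, it, delta, True)
    warnings.warn(
        f"SRWR did not converge in {cfg.max_iter} iterations (delta={delta:.3g})"
    )
    return SeedResult(rp, rn, cfg.max_iter, delta, False)


def srwr_exact(norm: NormalizedAdjacency, seed: int, cfg: DiffusionConfig = None) -> SeedResult:
    """Solve the SRWR fixed point directly as a dense 2N x 2N linear system.

    Serves as the exact reference for the iterative solver on small graphs.
    """
    cfg = cfg or DiffusionConfig()
    n = norm.n_nodes
    if n > 2000:
        raise ValueError("dense SRWR solve is guarded to N <= 2000 nodes")
    if not (0 <= seed < n):
        raise ValueError(f"seed index {seed} out of range for {n} nodes")
    ap_t, am_t = norm.a_plus.T, norm.a_minus.T
    c, b, g = cfg.c, cfg.beta, cfg.gamma
    block = np.block(
        [
            [ap_t, b * am_t + (1 - g) * ap_t],
            [am_t, g * ap_t + (1 - b) * am_t],
        ]
    )
    lhs = np.eye(2 * n) - (1 - c) * block
    rhs = np.zeros(2 * n)
    rhs[seed] = c
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "SRWR fixed-point system is singular; use a restart probability c > 0"
        ) from exc
    return SeedResult(sol[:n], sol[n:], 0, 0.0, True)


def srwr_all_seeds(
    norm: NormalizedAdjacency, cfg: DiffusionConfig = None, seeds=None
) -> DiffusionMatrix:
    """Run SRWR from every seed (default: all nodes) in one matrix iteration.

    Row s of ``r_p`` / ``r_n`` is the r+ / r- vector seeded at node s;
    unseeded rows are zero.  The vectorised iteration performs the same
    simultaneous update as :func:`srwr_seed` on all seed rows at once.
    """
    cfg = cfg or DiffusionConfig()
    n = norm.n_nodes
    if seeds is None:
        seeds = np.arange(n)
    seeds = np.asarray(seeds, dtype=int)
    q = np.zeros((len(seeds), n))
    q[np.arange(len(seeds)), seeds] = 1.0
    rp, rn = q.copy(), np.zeros_like(q)
    delta = np.inf
    converged = False
    for _ in range(cfg.max_iter):
        new_p, new_n = _step(norm, rp, rn, q, cfg)
        delta = (
            np.abs(new_p - rp).sum(axis=1) + np.abs(new_n - rn).sum(axis=1)
        ).max() if len(seeds) else 0.0
        rp, rn = new_p, new_n
        if delta < cfg.epsilon:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SRWR (all seeds) did not converge in {cfg.max_iter} iterations "
            f"(max delta={delta:.3g})"
        )
    out_p = np.zeros((n, n))
    out_n = np.zeros((n, n))
    out_p[seeds] = rp
    out_n[seeds] = rn
    return DiffusionMatrix(out_p, out_n)


def symmetrize(dm: DiffusionMatrix) -> DiffusionMatrix:
    """Fill r_d = max(r_p, r_p^T) - max(r_n, r_n^T) (exactly symmetric)."""
    if dm.r_p is None or dm.r_n is None:
        raise ValueError("r_p and r_n must be filled before symmetrizing")
    rd = np.maximum(dm.r_p, dm.r_p.T) - np.maximum(dm.r_n, dm.r_n.T)
    return DiffusionMatrix(dm.r_p, dm.r_n, rd)


def diffusion_to_graph(
    dm: DiffusionMatrix, template: SignedBipartiteGraph, k_edges: int
) -> SignedBipartiteGraph:
    """Sparsify r_d into a signed bipartite diffusion graph.

    Restricts r_d to the gene x phenotype block, picks the ``k_edges``
    entries of largest absolute score (ties broken by ascending gene then
    phenotype index), and signs each selected edge by the sign of its r_d
    entry.  Zero entries are never selected.
    """
    if k_edges < 1:
        raise ValueError("k_edges must be >= 1")
    if dm.r_d is None:
        raise ValueError("diffusion matrix has no r_d; call symmetrize first")
    ng = template.n_genes
    block = dm.r_d[:ng, ng:]
    flat = np.abs(block).ravel()
    nonzero = np.flatnonzero(flat)
    if k_edges > len(nonzero):
        warnings.warn(
            f"requested {k_edges} diffusion edges but only {len(nonzero)} "
            f"nonzero scores exist; returning all nonzeros"
        )
        k_edges = len(nonzero)
    if k_edges == 0:
        return template.with_edges([])
    # stable sort on (-|score|, flat index) gives the deterministic tie-break
    order = nonzero[np.lexsort((nonzero, -flat[nonzero]))][:k_edges]
    edges = []
    nph = template.n_phenotypes
    for idx in sorted(order.tolist()):
        g, p = divmod(idx, nph)
        edges.append((g, p, 1 if block[g, p] > 0 else -1))
    return template.with_edges(edges)


def adjacency_diffusion_graph(
    graph: SignedBipartiteGraph, cfg: DiffusionConfig = None, k_edges: int = None
) -> SignedBipartiteGraph:
    """Full diffusion pipeline: adjacency -> SRWR all seeds -> r_d -> top-k graph.

    ``k_edges`` defaults to the input edge count, preserving density.
    """
    from .graph import adjacency

    cfg = cfg or DiffusionConfig()
    norm = semi_row_normalize(adjacency(graph))
    dm = symmetrize(srwr_all_seeds(norm, cfg))
    return diffusion_to_graph(dm, graph, k_edges or max(graph.n_edges, 1))
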