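"""Synthetic signed bipartite graphs with planted latent-factor structure.

Genes and phenotypes receive latent factor vectors drawn from a standard
normal; the true sign of a (gene, phenotype) association is the sign of the
factor inner product.  Observed edges are a uniform sample of distinct
pairs whose signs are flipped independently with probability ``flip_noise``
(emulating noisy TWAS calls).  The gene-similarity matrix is derived from
the cosine of gene factors plus centred noise, so similar genes genuinely
share association signs -- the structural assumption the diffusion and
feature pipeline exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import GeneSimilarity, SignedBipartiteGraph, TwasTable

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "truth_auc"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    flip_noise is the per-edge probability of observing the wrong sign;
    sim_noise is the standard deviation of the centred noise added to the
    cosine-derived similarity before clamping to [0, 1].
    """

    n_genes: int = 200
    n_phenotypes: int = 8
    n_edges: int = 1000
    latent_dim: int = 4
    flip_noise: float = 0.1
    sim_noise: float = 0.1
    seed: int = 0
    degree_skew: bool = False

    def __post_init__(self) -> None:
        if self.n_edges > self.n_genes * self.n_phenotypes:
            raise ValueError("n_edges exceeds the number of available pairs")
        if not (0.0 <= self.flip_noise < 0.5):
            raise ValueError("flip_noise must be in [0, 0.5)")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be nonnegative")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted factors; the true sign of (g, p) is sign(<u_g, v_p>)."""

    gene_factors: np.ndarray
    phenotype_factors: np.ndarray

    def true_sign(self, g: int, p: int) -> int:
        val = float(self.gene_factors[g] @ self.phenotype_factors[p])
        return 1 if val > 0 else -1

    def score(self, g: int, p: int) -> float:
        return float(self.gene_factors[g] @ self.phenotype_factors[p])


def _sample_pairs(rng, spec: SyntheticSpec):
    """n_edges distinct (gene, phenotype) pairs, uniform or degree-skewed."""
    total = spec.n_genes * spec.n_phenotypes
    if not spec.degree_skew:
        flat = rng.choice(total, size=spec.n_edges, replace=False)
        return [divmod(int(f), spec.n_phenotypes) for f in flat]
    # power-law phenotype popularity, mirroring real datasets where one
    # phenotype may carry most associations; flat index = g * n_phen + p
    phen_w = 1.0 / np.arange(1, spec.n_phenotypes + 1) ** 1.2
    weights = np.tile(phen_w / phen_w.sum(), spec.n_genes) / spec.n_genes
    chosen = rng.choice(total, size=spec.n_edges, replace=False, p=weights)
    return [divmod(int(f), spec.n_phenotypes) for f in chosen]


def generate(spec: SyntheticSpec):
    """Draw a synthetic dataset.

    Returns ``(graph, similarity, truth, twas)`` where the TWAS table holds
    a pseudo z-score (the factor inner product, sign-flipped where noise
    applied) for each edge.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.standard_normal((spec.n_genes, spec.latent_dim))
    v = rng.standard_normal((spec.n_phenotypes, spec.latent_dim))
    truth = SyntheticTruth(u, v)

    pairs = _sample_pairs(rng, spec)
    # measure-zero guard: resample pairs whose inner product is exactly zero
    used: set = set()
    clean = []
    for g, p in pairs:
        while (g, p) in used or u[g] @ v[p] == 0.0:
            g = int(rng.integers(spec.n_genes))
            p = int(rng.integers(spec.n_phenotypes))
        used.add((g, p))
        clean.append((g, p))
    pairs = clean

    gene_ids = [f"g{i}" for i in range(spec.n_genes)]
    phen_ids = [f"p{j}" for j in range(spec.n_phenotypes)]
    edges = []
    rows = []
    flips = rng.uniform(size=len(pairs)) < spec.flip_noise
    for (g, p), flip in zip(pairs, flips):
        s = truth.true_sign(g, p)
        if flip:
            s = -s
        edges.append((g, p, s))
        z = abs(truth.score(g, p)) * s
        rows.append((gene_ids[g], phen_ids[p], z))
    graph = SignedBipartiteGraph(gene_ids, phen_ids, edges)

    norms = np.linalg.norm(u, axis=1, keepdims=True)
    cosine = (u / norms) @ (u / norms).T
    sim = (1.0 + cosine) / 2.0
    if spec.sim_noise > 0:
        noise = rng.normal(scale=spec.sim_noise, size=sim.shape)
        sim = sim + (noise + noise.T) / 2.0
    sim = np.clip(sim, 0.0, 1.0)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    similarity = GeneSimilarity(sim, gene_ids)
    return graph, similarity, truth, TwasTable(rows)


def truth_auc(truth: SyntheticTruth, scores, pairs) -> float:
    """AUC of arbitrary scores against the planted signs over given pairs."""
    from sklearn.metrics import roc_auc_score

    y = np.array([1 if truth.true_sign(g, p) > 0 else 0 for g, p in pairs])
    if y.min() == y.max():
        return 0.5
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))
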