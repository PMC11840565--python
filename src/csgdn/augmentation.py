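"""Stochastic edge-mask augmentation for contrastive views.

Each view is produced by drawing one uniform(0,1) value per edge and
deleting edges whose draw falls below the mask ratio; node sets are kept.
Two independent views of the original graph and two of the diffusion graph
give the four views used by the contrastive objectives.  An alternative
strategy flips the signs of the selected edges instead of deleting them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import SignedBipartiteGraph

__all__ = ["ViewSet", "SignSplit", "mask_edges", "build_views", "split_by_sign"]


@dataclass
class ViewSet:
    """The four augmented views G1..G4 and where each came from."""

    views: list  # 4 SignedBipartiteGraph
    source_tags: tuple = ("original", "original", "diffusion", "diffusion")

    def __post_init__(self) -> None:
        if len(self.views) != 4:
            raise ValueError("a ViewSet holds exactly 4 views")


@dataclass
class SignSplit:
    """A view partitioned into its positive-only and negative-only subgraphs."""

    positive_graph: SignedBipartiteGraph
    negative_graph: SignedBipartiteGraph


def _view_rng(rng_seed: int, k: int) -> np.random.Generator:
    """Deterministic sub-stream k of the augmentation seed."""
    return np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(k,)))


def mask_edges(
    graph: SignedBipartiteGraph,
    ratio: float,
    rng_seed: int,
    strategy: str = "delete",
) -> SignedBipartiteGraph:
    """Randomly mask a Bernoulli(ratio) subset of edges.

    ``delete`` removes the selected edges; ``sign_flip`` flips their signs
    instead.  The draw is one uniform per edge, so the kept count is
    Binomial(|E|, 1 - ratio) across seeds; a fixed seed is fully
    deterministic.
    """
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("mask ratio must be in [0, 1]")
    if strategy not in ("delete", "sign_flip"):
        raise ValueError("strategy must be 'delete' or 'sign_flip'")
    rng = np.random.default_rng(rng_seed)
    draws = rng.uniform(size=graph.n_edges)
    masked = draws < ratio
    if strategy == "delete":
        edges = [e for e, hit in zip(graph.edges, masked) if not hit]
    else:
        edges = [
            (g, p, -s if hit else s)
            for (g, p, s), hit in zip(graph.edges, masked)
        ]
    return graph.with_edges(edges)


def build_views(
    original: SignedBipartiteGraph,
    diffusion: SignedBipartiteGraph,
    ratio: float,
    rng_seed: int,
    strategy: str = "delete",
) -> ViewSet:
    """Build the four views: two masks of the original, two of the diffusion.

    Four distinct sub-seeds are derived deterministically from ``rng_seed``.
    """
    if not original.same_nodes(diffusion):
        raise ValueError("original and diffusion graphs must share node indexing")
    sources = (original, original, diffusion, diffusion)
    views = []
    for k, src in enumerate(sources):
        sub = int(_view_rng(rng_seed, k).integers(0, 2**31 - 1))
        views.append(mask_edges(src, ratio, sub, strategy=strategy))
    return ViewSet(views)


def split_by_sign(view: SignedBipartiteGraph) -> SignSplit:
    """Partition a view into positive-only and negative-only subgraphs."""
    pos = [e for e in view.edges if e[2] == 1]
    neg = [e for e in view.edges if e[2] == -1]
    return SignSplit(view.with_edges(pos), view.with_edges(neg))
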