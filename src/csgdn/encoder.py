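"""Sign-aware graph-attention encoding of the augmented views.

Each of the four views is split into a positive-only and a negative-only
subgraph.  One two-layer GAT encoder handles all positive subgraphs and a
second, independent one handles all negative subgraphs (parameters shared
within a sign, never across signs).  For view k and sign z, the layer
outputs are concatenated [h(0) || h(1) || h(2)] and projected by a
view-and-sign-specific matrix W_k^z to the embedding dimension d.  The 8
per-view embeddings of a node (4 positive then 4 negative, view order
1..4) are concatenated and fused by a two-layer MLP into the final node
embedding z_i of dimension d.
"""

from __future__ import annotations

import numpy as np

from .augmentation import SignSplit
from .autodiff import Tensor, concat
from .graph import FeatureMatrix, SignedBipartiteGraph, adjacency
from .nn import MLP, GATLayer, Parameter, glorot

__all__ = ["EncoderParams", "ViewEmbeddings", "encode_view", "encode_views", "fuse_views"]

N_VIEWS = 4
N_LAYERS = 2


class EncoderParams:
    """All encoder parameters.

    One GAT stack per sign (shared across views), eight per-(view, sign)
    projection matrices mapping the (n_in + 2d)-dimensional layer
    concatenation to d, and the two-layer fusion MLP (8d -> d -> d).
    """

    def __init__(self, rng: np.random.Generator, n_in: int, d: int):
        self.d = d
        self.n_in = n_in
        self.gat = {
            "+": [GATLayer(rng, n_in, d), GATLayer(rng, d, d)],
            "-": [GATLayer(rng, n_in, d), GATLayer(rng, d, d)],
        }
        cat_dim = n_in + N_LAYERS * d
        self.proj = {
            (k, z): Parameter(glorot(rng, cat_dim, d))
            for z in ("+", "-")
            for k in range(N_VIEWS)
        }
        self.fusion = MLP(rng, 8 * d, d, d, layers=2)

    def parameters(self):
        out = []
        for z in ("+", "-"):
            for layer in self.gat[z]:
                out.extend(layer.parameters())
        out.extend(self.proj[(k, z)] for z in ("+", "-") for k in range(N_VIEWS))
        out.extend(self.fusion.parameters())
        return out


class ViewEmbeddings:
    """Per-view, per-sign node embeddings: z[(k, sign)] is (N, d)."""

    def __init__(self):
        self.z: dict = {}

    def require_complete(self) -> None:
        missing = [
            (k, z)
            for z in ("+", "-")
            for k in range(N_VIEWS)
            if (k, z) not in self.z
        ]
        if missing:
            raise ValueError(f"missing view embeddings: {missing}")


def _sign_mask(graph: SignedBipartiteGraph) -> np.ndarray:
    return np.abs(adjacency(graph))


def encode_view(
    split: SignSplit, features, params: EncoderParams, k: int, _pre=None
) -> dict:
    """Encode one view: run each sign's GAT stack on its sign subgraph.

    Returns ``{"+": (N, d) Tensor, "-": (N, d) Tensor}``.  An empty sign
    subgraph still encodes through self-loops.
    """
    if isinstance(features, FeatureMatrix):
        features = features.matrix
    h0 = features if isinstance(features, Tensor) else Tensor(features)
    out = {}
    for z, graph in (("+", split.positive_graph), ("-", split.negative_graph)):
        mask = _sign_mask(graph)
        first = params.gat[z][0]
        pre = _pre[z] if _pre is not None else first.precompute(h0)
        h1 = first(h0, mask, pre=pre)
        hs = [h0, h1]
        h = h1
        for layer in params.gat[z][1:]:
            h = layer(h, mask)
            hs.append(h)
        out[z] = concat(hs, axis=1) @ params.proj[(k, z)]
    return out


def encode_views(splits, features, params: EncoderParams) -> ViewEmbeddings:
    """Encode all four sign-split views.

    The first layer's feature transform and attention scores depend only on
    the input features, so each sign's stack computes them once and shares
    them across the four views (the adjacency mask is all that differs).
    """
    if len(splits) != N_VIEWS:
        raise ValueError(f"expected {N_VIEWS} sign-split views, got {len(splits)}")
    if isinstance(features, FeatureMatrix):
        features = features.matrix
    h0 = features if isinstance(features, Tensor) else Tensor(features)
    pre = {z: params.gat[z][0].precompute(h0) for z in ("+", "-")}
    ve = ViewEmbeddings()
    for k, split in enumerate(splits):
        zk = encode_view(split, h0, params, k, _pre=pre)
        ve.z[(k, "+")] = zk["+"]
        ve.z[(k, "-")] = zk["-"]
    return ve


def fuse_views(ve: ViewEmbeddings, params: EncoderParams) -> Tensor:
    """Fuse the 8 per-view embeddings into the final (N, d) embedding.

    Concatenation order is fixed: positives of views 1..4, then negatives
    of views 1..4.
    """
    ve.require_complete()
    ordered = [ve.z[(k, "+")] for k in range(N_VIEWS)] + [
        ve.z[(k, "-")] for k in range(N_VIEWS)
    ]
    return params.fusion(concat(ordered, axis=1))
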