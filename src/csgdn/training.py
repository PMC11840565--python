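"""End-to-end training, prediction and evaluation.

The training loop follows the four-stage pipeline: (1) SRWR diffusion of the
train graph into a diffusion graph (computed once per run and cached),
(2) stochastic edge masking into four views (fresh per-epoch sub-seed),
(3) sign-aware GAT encoding and fusion, and (4) joint optimisation of the
3-class sign cross-entropy on train edges plus sampled "none" pairs and the
combined contrastive loss, L = L_label + beta * L_CL, with Adam.

Ablations: ``no_diffuse`` masks the original graph for all four views,
``no_aug`` uses the unmasked original and diffusion graphs twice each, and
``no_cl`` sets beta = 0.

A separate projection MLP is fitted afterwards to map raw similarity-row
features of genes onto their trained embeddings, so genes lacking TWAS
associations can be embedded and scored at inference time.

Evaluation of held-out signed edges is binary over {up, down}: the score of
an edge is P_up / (P_up + P_down); metrics are AUC, AUPR, and F1/precision
for the up class plus micro-/macro-F1 over both classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .augmentation import build_views, split_by_sign
from .autodiff import Tensor
from .diffusion import DiffusionConfig, adjacency_diffusion_graph
from .encoder import EncoderParams, encode_views, fuse_views
from .graph import FeatureMatrix, SignedBipartiteGraph, build_feature_matrix
from .nn import MLP, Adam
from .objectives import (
    LossConfig,
    SignPredictor,
    contrastive_loss,
    inter_view_loss,
    intra_view_loss,
    label_loss,
    predict_sign,
    total_loss,
)

__all__ = [
    "TrainConfig",
    "MetricReport",
    "ModelState",
    "split_edges",
    "sample_class0_pairs",
    "train",
    "fit_projection",
    "predict_pairs",
    "evaluate",
    "perturb_signs",
    "subsample_edges",
    "run_experiment",
]

ABLATIONS = ("full", "no_diffuse", "no_aug", "no_cl")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The flagship preset: alpha 0.8, beta 0.01, embedding dimension 64,
    mask ratio 0.4, tau 0.05, 2-layer predictor; Adam lr 1e-3, weight decay
    5e-4, 300 epochs.
    """

    epochs: int = 300
    lr: float = 1e-3
    weight_decay: float = 5e-4
    seed: int = 0
    d: int = 64
    mask: float = 0.4
    split_ratio: float = 0.8
    ablation: str = "full"
    augmentation_strategy: str = "delete"
    predictor_layers: int = 2
    output_normalization: str = "softmax"
    projection_epochs: int = 300
    inference_views: int = 8
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split ratio must be in (0, 1)")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")


@dataclass
class MetricReport:
    """Binary link-sign metrics on held-out edges (positive class = up)."""

    auc: float
    f1: float
    micro_f1: float
    macro_f1: float
    aupr: float
    precision: float
    n_test_edges: int

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "f1": self.f1,
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "aupr": self.aupr,
            "precision": self.precision,
            "n_test_edges": self.n_test_edges,
        }


@dataclass
class ModelState:
    """Everything needed to predict: parameters, features, and the log."""

    config: TrainConfig
    encoder: EncoderParams
    predictor: SignPredictor
    projection: MLP = None
    features: FeatureMatrix = None
    graph: SignedBipartiteGraph = None
    fused: np.ndarray = None  # final (N, d) embeddings at the last epoch
    training_log: list = field(default_factory=list)
    twas_genes: set = field(default_factory=set)


def split_edges(graph: SignedBipartiteGraph, ratio: float = 0.8, seed: int = 0):
    """Uniform random split of signed edges into train graph + test list.

    The train graph keeps all nodes.  Test size is ``round((1-ratio)|E|)``
    via the complement of the train draw.
    """
    if graph.n_edges < 5:
        warnings.warn("fewer than 5 edges: the split will be very unstable")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(graph.n_edges)
    n_train = int(round(ratio * graph.n_edges))
    train_idx = set(perm[:n_train].tolist())
    train = [e for i, e in enumerate(graph.edges) if i in train_idx]
    test = [e for i, e in enumerate(graph.edges) if i not in train_idx]
    if not test:
        raise ValueError("split produced 0 test edges; lower the ratio")
    return graph.with_edges(train), test


def sample_class0_pairs(
    graph: SignedBipartiteGraph, n_pairs: int, seed: int = 0, exclude=None
):
    """Sample (gene, phenotype) pairs absent from the graph ("none" class).

    ``exclude`` adds further forbidden pairs (e.g. held-out test edges, so
    that no evaluation pair is ever trained toward the "none" class).
    Sampling is uniform over the remaining non-edges; if fewer exist than
    requested the sample is capped with a warning.
    """
    present = {(g, p) for g, p, _ in graph.edges}
    if exclude:
        present = present | set(exclude)
    total = graph.n_genes * graph.n_phenotypes
    avail = total - len(present)
    if n_pairs > avail:
        warnings.warn(
            f"requested {n_pairs} class-0 pairs but only {avail} non-edges exist"
        )
        n_pairs = avail
    if n_pairs == 0:
        return []
    rng = np.random.default_rng(seed)
    picked = []
    seen = set(present)
    # rejection sampling; the graphs here are sparse so acceptance is high
    while len(picked) < n_pairs:
        g = int(rng.integers(graph.n_genes))
        p = int(rng.integers(graph.n_phenotypes))
        if (g, p) in seen:
            continue
        seen.add((g, p))
        picked.append((g, p))
    return picked


def _build_diffusion_graph(train: SignedBipartiteGraph, cfg: TrainConfig):
    return adjacency_diffusion_graph(train, cfg.diffusion, k_edges=max(train.n_edges, 1))


def _epoch_views(train, diffusion_graph, cfg: TrainConfig, epoch_seed: int):
    if cfg.ablation == "no_aug":
        return [train, train, diffusion_graph, diffusion_graph]
    source = train if cfg.ablation == "no_diffuse" else diffusion_graph
    vs = build_views(train, source, cfg.mask, epoch_seed,
                     strategy=cfg.augmentation_strategy)
    return vs.views


def train(
    graph: SignedBipartiteGraph,
    features: FeatureMatrix,
    cfg: TrainConfig = None,
    known_pairs=None,
) -> ModelState:
    """Train the full model (or an ablation) on a train-split graph.

    ``known_pairs`` lists every (gene, phenotype) pair with a known signed
    association in the complete dataset (train and held-out); class-0
    "none" pairs are sampled outside this set so no genuinely associated
    pair is trained toward the undefined class.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    n_in = features.matrix.shape[1]
    enc = EncoderParams(rng, n_in, cfg.d)
    predictor = SignPredictor(
        rng, cfg.d, layers=cfg.predictor_layers,
        output_normalization=cfg.output_normalization,
    )
    params = enc.parameters() + predictor.parameters()
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    diffusion_graph = (
        graph.with_edges([]) if cfg.ablation == "no_diffuse" else _build_diffusion_graph(graph, cfg)
    )

    ng = graph.n_genes
    class0 = sample_class0_pairs(
        graph, graph.n_edges, seed=cfg.seed + 1, exclude=known_pairs
    )
    pair_u = np.array([g for g, p, _ in graph.edges] + [g for g, p in class0], dtype=int)
    pair_v = np.array(
        [ng + p for g, p, _ in graph.edges] + [ng + p for g, p in class0], dtype=int
    )
    labels = np.array([s for _, _, s in graph.edges] + [0] * len(class0), dtype=int)

    feats = Tensor(features.matrix)
    seed_seq = np.random.SeedSequence(cfg.seed, spawn_key=(1,))
    epoch_seeds = seed_seq.generate_state(cfg.epochs) % (2**31 - 1)

    log = []
    fused_data = None
    for epoch in range(cfg.epochs):
        views = _epoch_views(graph, diffusion_graph, cfg, int(epoch_seeds[epoch]))
        splits = [split_by_sign(v) for v in views]
        ve = encode_views(splits, feats, enc)
        fused = fuse_views(ve, enc)

        probs = predict_sign(fused.take_rows(pair_u), fused.take_rows(pair_v), predictor)
        l_label = label_loss(probs, labels)

        if cfg.ablation == "no_cl":
            loss = l_label
            l_inter_v = l_intra_v = l_cl_v = None
        else:
            l_inter = inter_view_loss(ve, cfg.loss)
            l_intra = intra_view_loss(fused, ve, cfg.loss)
            l_cl = contrastive_loss(l_inter, l_intra, cfg.loss)
            loss = total_loss(l_label, l_cl, cfg.loss)
            l_inter_v = float(l_inter.data)
            l_intra_v = float(l_intra.data)
            l_cl_v = float(l_cl.data)

        if not np.isfinite(loss.data):
            terms = {
                "l_label": float(l_label.data),
                "l_inter": l_inter_v,
                "l_intra": l_intra_v,
            }
            bad = [k for k, v in terms.items() if v is not None and not np.isfinite(v)]
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}; offending terms: {bad}"
            )

        opt.zero_grad()
        loss.backward()
        opt.step()
        log.append(
            {
                "epoch": epoch,
                "l_label": float(l_label.data),
                "l_inter": l_inter_v,
                "l_intra": l_intra_v,
                "l_total": float(loss.data),
            }
        )

    # inference embeddings: the predictor is trained against masked-view
    # encodings, so inference stays in-distribution by averaging the fused
    # embedding over several seeded mask draws (test-time augmentation)
    infer_seeds = np.random.SeedSequence(cfg.seed, spawn_key=(2,)).generate_state(
        cfg.inference_views
    ) % (2**31 - 1)
    acc = np.zeros((features.matrix.shape[0], cfg.d))
    for s in infer_seeds:
        views = _epoch_views(graph, diffusion_graph, cfg, int(s))
        ve = encode_views([split_by_sign(v) for v in views], feats, enc)
        acc += fuse_views(ve, enc).data
    fused_data = acc / max(len(infer_seeds), 1)

    state = ModelState(
        config=cfg,
        encoder=enc,
        predictor=predictor,
        features=features,
        graph=graph,
        fused=fused_data,
        training_log=log,
        twas_genes={g for g, _, _ in graph.edges},
    )
    return state


def fit_projection(model: ModelState, features: FeatureMatrix = None) -> ModelState:
    """Fit the projection MLP mapping raw gene features to trained embeddings.

    Minimises the mean squared distance between MLP(h_i^(0)) and the frozen
    final embedding z_i over genes that carry TWAS (train) associations.
    """
    from .objectives import projection_mse

    features = features or model.features
    cfg = model.config
    twas = sorted(model.twas_genes)
    if not twas:
        raise ValueError("no TWAS genes available to fit the projection")
    rng = np.random.default_rng(cfg.seed + 7)
    n_in = features.matrix.shape[1]
    mlp = MLP(rng, n_in, cfg.d, cfg.d, layers=2)
    # the projection is a small standalone regression; a larger step size is
    # stable here and converges in a few hundred iterations
    opt = Adam(mlp.parameters(), lr=1e-2, weight_decay=0.0)
    h0 = Tensor(features.matrix[twas])
    targets = Tensor(model.fused[twas])
    for _ in range(cfg.projection_epochs):
        out = mlp(h0)
        loss = projection_mse(out, targets)
        opt.zero_grad()
        loss.backward()
        opt.step()
    model.projection = mlp
    return model


def _embed_pairs(model: ModelState, pairs, use_projection: bool):
    """Embeddings for (gene_index, phenotype_index) pairs."""
    ng = model.graph.n_genes
    z = model.fused
    zu = np.empty((len(pairs), model.config.d))
    for i, (g, p) in enumerate(pairs):
        if p >= model.graph.n_phenotypes:
            raise ValueError(f"unknown phenotype index {p}")
        project = use_projection or (g not in model.twas_genes)
        if project:
            if model.projection is None:
                raise ValueError(
                    "projection MLP not fitted; call fit_projection first"
                )
            zu[i] = model.projection(Tensor(model.features.matrix[g])).data
        else:
            zu[i] = z[g]
    zv = np.stack([z[ng + p] for _, p in pairs])
    return zu, zv


def predict_pairs(model: ModelState, pairs, use_projection: bool = False):
    """Probability triples (P_down, P_none, P_up) for (gene, phenotype) pairs.

    Genes outside the trained (TWAS) set are always embedded through the
    projection MLP; for trained genes ``use_projection`` selects the route.
    """
    if not pairs:
        return np.zeros((0, 3))
    zu, zv = _embed_pairs(model, pairs, use_projection)
    return predict_sign(zu, zv, model.predictor).data


def evaluate(model: ModelState, test_edges) -> MetricReport:
    """Binary up-vs-down evaluation on held-out signed edges."""
    from sklearn.metrics import (
        average_precision_score,
        f1_score,
        precision_score,
        roc_auc_score,
    )

    pairs = [(g, p) for g, p, _ in test_edges]
    y_true = np.array([1 if s > 0 else 0 for _, _, s in test_edges])
    probs = predict_pairs(model, pairs)
    denom = probs[:, 2] + probs[:, 0]
    scores = np.divide(probs[:, 2], denom, out=np.full(len(pairs), 0.5), where=denom > 0)
    y_pred = (probs[:, 2] >= probs[:, 0]).astype(int)

    if y_true.min() == y_true.max():
        warnings.warn("test set contains a single sign class; AUC reported as 0.5")
        auc = 0.5
        aupr = float(y_true.mean()) if y_true.max() == 1 else 0.0
    else:
        auc = float(roc_auc_score(y_true, scores))
        aupr = float(average_precision_score(y_true, scores))
    return MetricReport(
        auc=auc,
        f1=float(f1_score(y_true, y_pred, zero_division=0)),
        micro_f1=float(f1_score(y_true, y_pred, average="micro", zero_division=0)),
        macro_f1=float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        aupr=aupr,
        precision=float(precision_score(y_true, y_pred, zero_division=0)),
        n_test_edges=len(test_edges),
    )


def perturb_signs(graph: SignedBipartiteGraph, fraction: float, seed: int = 0):
    """Flip the signs of exactly round(fraction * |E|) uniformly chosen edges."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_flip = int(round(fraction * graph.n_edges))
    idx = set(rng.choice(graph.n_edges, size=n_flip, replace=False).tolist())
    edges = [
        (g, p, -s if i in idx else s) for i, (g, p, s) in enumerate(graph.edges)
    ]
    return graph.with_edges(edges)


def subsample_edges(graph: SignedBipartiteGraph, fraction: float, seed: int = 0):
    """Keep exactly round(fraction * |E|) uniformly chosen edges; nodes stay."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_keep = int(round(fraction * graph.n_edges))
    idx = sorted(rng.choice(graph.n_edges, size=n_keep, replace=False).tolist())
    return graph.with_edges([graph.edges[i] for i in idx])


def run_experiment(
    graph: SignedBipartiteGraph,
    similarity,
    cfg: TrainConfig = None,
) -> tuple:
    """Split, train and evaluate once; returns (model, report, test_edges)."""
    cfg = cfg or TrainConfig()
    train_graph, test_edges = split_edges(graph, cfg.split_ratio, seed=cfg.seed)
    features = build_feature_matrix(similarity, graph)
    known = [(g, p) for g, p, _ in graph.edges]
    model = train(train_graph, features, cfg, known_pairs=known)
    fit_projection(model)
    report = evaluate(model, test_edges)
    return model, report, test_edges
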