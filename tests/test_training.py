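"""Training loop, splits, class-0 sampling, prediction, metrics, robustness."""

import dataclasses
import warnings

import numpy as np
import pytest

from csgdn.config import preset
from csgdn.graph import GeneSimilarity, SignedBipartiteGraph, build_feature_matrix
from csgdn.synthetic import SyntheticSpec, generate
from csgdn.training import (
    TrainConfig,
    evaluate,
    fit_projection,
    perturb_signs,
    predict_pairs,
    sample_class0_pairs,
    split_edges,
    subsample_edges,
    train,
)


def tiny_dataset(seed=0, n_genes=12, n_phenotypes=3, n_edges=24):
    spec = SyntheticSpec(
        n_genes=n_genes, n_phenotypes=n_phenotypes, n_edges=n_edges,
        latent_dim=2, flip_noise=0.0, sim_noise=0.05, seed=seed,
    )
    graph, sim, truth, _ = generate(spec)
    return graph, sim, truth


def tiny_config(**overrides):
    defaults = dict(epochs=5, d=8, seed=0, projection_epochs=400,
                    inference_views=2)
    defaults.update(overrides)
    return preset("synthetic", **defaults)


@pytest.fixture(scope="module")
def trained_tiny():
    graph, sim, truth = tiny_dataset()
    train_graph, test_edges = split_edges(graph, 0.8, seed=0)
    features = build_feature_matrix(sim, graph)
    cfg = tiny_config(epochs=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train(train_graph, features, cfg,
                      known_pairs=[(g, p) for g, p, _ in graph.edges])
        fit_projection(model)
    return model, test_edges, graph


class TestSplitEdges:
    def test_counts(self):
        graph, _, _ = tiny_dataset(n_edges=10)
        train_graph, test = split_edges(graph, 0.8, seed=1)
        assert train_graph.n_edges == 8 and len(test) == 2

    def test_same_seed_same_split(self):
        graph, _, _ = tiny_dataset()
        a = split_edges(graph, 0.8, seed=5)
        b = split_edges(graph, 0.8, seed=5)
        assert a[0].edges == b[0].edges and a[1] == b[1]

    def test_partition_property(self):
        graph, _, _ = tiny_dataset(seed=2)
        train_graph, test = split_edges(graph, 0.75, seed=3)
        assert set(train_graph.edges) | set(test) == set(graph.edges)
        assert not set(train_graph.edges) & set(test)
        assert train_graph.gene_ids == graph.gene_ids

    def test_tiny_graph_warns(self):
        g = SignedBipartiteGraph(["g1", "g2"], ["p1"], [(0, 0, 1), (1, 0, -1)])
        with pytest.warns(UserWarning, match="fewer than 5"):
            split_edges(g, 0.5, seed=0)


class TestClass0Sampling:
    def test_complete_bipartite_graph_has_no_non_edges(self):
        g = SignedBipartiteGraph(
            ["g1", "g2"], ["p1"], [(0, 0, 1), (1, 0, -1)]
        )
        with pytest.warns(UserWarning, match="non-edges"):
            pairs = sample_class0_pairs(g, 5, seed=0)
        assert pairs == []

    def test_never_collides_with_edges_or_exclusions(self):
        graph, _, _ = tiny_dataset(seed=4)
        edges = {(g, p) for g, p, _ in graph.edges}
        exclude = [(0, 0), (1, 1)]
        for seed in range(100):
            pairs = sample_class0_pairs(graph, 6, seed=seed, exclude=exclude)
            assert not set(pairs) & edges
            assert not set(pairs) & set(exclude)

    def test_same_seed_same_sample(self):
        graph, _, _ = tiny_dataset(seed=4)
        assert sample_class0_pairs(graph, 6, seed=9) == sample_class0_pairs(
            graph, 6, seed=9
        )


class TestTrain:
    def test_loss_decreases_on_toy(self):
        graph, sim, _ = tiny_dataset(seed=6)
        features = build_feature_matrix(sim, graph)
        cfg = tiny_config(epochs=12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train(graph, features, cfg)
        log = model.training_log
        assert log[-1]["l_total"] < log[0]["l_total"]

    def test_no_cl_log_has_no_contrastive_values(self):
        graph, sim, _ = tiny_dataset(seed=6)
        features = build_feature_matrix(sim, graph)
        cfg = tiny_config(epochs=3, ablation="no_cl")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train(graph, features, cfg)
        for entry in model.training_log:
            assert entry["l_inter"] is None and entry["l_intra"] is None
            assert entry["l_total"] == entry["l_label"]

    def test_seeded_determinism(self):
        graph, sim, _ = tiny_dataset(seed=7)
        features = build_feature_matrix(sim, graph)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = train(graph, features, tiny_config(epochs=4))
            b = train(graph, features, tiny_config(epochs=4))
        assert np.array_equal(a.fused, b.fused)
        for pa, pb in zip(a.encoder.parameters(), b.encoder.parameters()):
            assert np.array_equal(pa.data, pb.data)

    @pytest.mark.parametrize("ablation", ["no_diffuse", "no_aug", "no_cl"])
    def test_ablations_run(self, ablation):
        graph, sim, _ = tiny_dataset(seed=8)
        features = build_feature_matrix(sim, graph)
        cfg = tiny_config(epochs=3, ablation=ablation)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train(graph, features, cfg)
        assert np.isfinite(model.fused).all()

    def test_invalid_ablation_rejected(self):
        with pytest.raises(ValueError, match="ablation"):
            tiny_config(ablation="bogus")


class TestProjection:
    def test_mse_small_after_fit(self, trained_tiny):
        model, _, _ = trained_tiny
        twas = sorted(model.twas_genes)
        from csgdn.autodiff import Tensor
        from csgdn.objectives import projection_mse

        out = model.projection(Tensor(model.features.matrix[twas]))
        mse = projection_mse(out, model.fused[twas]).data
        # targets have O(1) scale; the projection must fit them closely
        assert mse < 1e-2

    def test_refit_is_idempotent(self, trained_tiny):
        model, _, _ = trained_tiny
        w0 = [p.data.copy() for p in model.projection.parameters()]
        fit_projection(model)
        for a, p in zip(w0, model.projection.parameters()):
            assert np.array_equal(a, p.data)


class TestPredictPairs:
    def test_triples_sum_to_one(self, trained_tiny):
        model, test_edges, _ = trained_tiny
        probs = predict_pairs(model, [(g, p) for g, p, _ in test_edges])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_projection_route_differs_for_twas_gene(self, trained_tiny):
        model, _, _ = trained_tiny
        g = sorted(model.twas_genes)[0]
        direct = predict_pairs(model, [(g, 0)], use_projection=False)
        projected = predict_pairs(model, [(g, 0)], use_projection=True)
        assert not np.allclose(direct, projected)

    def test_batch_equals_per_pair(self, trained_tiny):
        model, test_edges, _ = trained_tiny
        pairs = [(g, p) for g, p, _ in test_edges]
        batch = predict_pairs(model, pairs)
        singles = np.vstack([predict_pairs(model, [pr]) for pr in pairs])
        assert np.allclose(batch, singles, atol=1e-12)

    def test_unknown_phenotype_is_hard_error(self, trained_tiny):
        model, _, graph = trained_tiny
        with pytest.raises(ValueError, match="phenotype"):
            predict_pairs(model, [(0, graph.n_phenotypes + 3)])


class TestEvaluate:
    def test_perfect_separation_gives_unit_metrics(self, trained_tiny):
        model, _, _ = trained_tiny

        class Stub:
            pass

        # craft a model whose predictions perfectly separate the test signs
        probs = {1: (0.05, 0.05, 0.9), -1: (0.9, 0.05, 0.05)}
        test = [(0, 0, 1), (1, 0, -1), (2, 1, 1), (3, 1, -1)]
        import csgdn.training as tr

        stub = Stub()
        real_predict = tr.predict_pairs
        try:
            tr.predict_pairs = lambda m, pairs, use_projection=False: np.array(
                [probs[s] for (_, _, s) in test]
            )
            report = tr.evaluate(stub, test)
        finally:
            tr.predict_pairs = real_predict
        assert report.auc == 1.0 and report.f1 == 1.0 and report.aupr == 1.0

    def test_metrics_match_hand_rolled_reference(self, trained_tiny):
        # independent oracle: pair-counting AUC and confusion-matrix F1
        model, test_edges, _ = trained_tiny
        report = evaluate(model, test_edges)
        probs = predict_pairs(model, [(g, p) for g, p, _ in test_edges])
        scores = probs[:, 2] / (probs[:, 2] + probs[:, 0])
        y = np.array([1 if s > 0 else 0 for _, _, s in test_edges])
        if 0 < y.sum() < len(y):
            pos, neg = scores[y == 1], scores[y == 0]
            wins = sum(
                1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
            )
            auc = wins / (len(pos) * len(neg))
            assert report.auc == pytest.approx(auc, abs=1e-9)
        yhat = (probs[:, 2] >= probs[:, 0]).astype(int)
        tp = int(((yhat == 1) & (y == 1)).sum())
        fp = int(((yhat == 1) & (y == 0)).sum())
        fn = int(((yhat == 0) & (y == 1)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        assert report.f1 == pytest.approx(f1, abs=1e-9)

    def test_single_class_test_set_warns_auc_half(self, trained_tiny):
        model, test_edges, _ = trained_tiny
        mono = [(g, p, 1) for g, p, _ in test_edges]
        with pytest.warns(UserWarning, match="single sign"):
            report = evaluate(model, mono)
        assert report.auc == 0.5


class TestPerturbAndSubsample:
    def test_zero_fraction_identity(self):
        graph, _, _ = tiny_dataset(seed=9)
        assert perturb_signs(graph, 0.0, seed=1).edges == graph.edges
        assert subsample_edges(graph, 1.0, seed=1).edges == graph.edges

    def test_exact_flip_count(self):
        graph, _, _ = tiny_dataset(seed=9, n_genes=25, n_edges=50)
        out = perturb_signs(graph, 0.1, seed=2)
        flips = sum(1 for a, b in zip(graph.edges, out.edges) if a[2] != b[2])
        assert flips == 5

    def test_double_perturbation_restores_signs(self):
        graph, _, _ = tiny_dataset(seed=10)
        once = perturb_signs(graph, 0.2, seed=3)
        twice = perturb_signs(once, 0.2, seed=3)
        assert twice.edges == graph.edges

    def test_subsample_counts_and_subset(self):
        graph, _, _ = tiny_dataset(seed=11, n_genes=20, n_edges=40)
        out = subsample_edges(graph, 0.8, seed=4)
        assert out.n_edges == 32
        assert set(out.edges) <= set(graph.edges)


class TestNoLeakage:
    def test_training_inputs_never_touch_test_edges(self):
        # diffusion, views, and the label loss are all built from the train
        # graph; class-0 sampling additionally avoids the full known set
        graph, sim, _ = tiny_dataset(seed=12)
        train_graph, test = split_edges(graph, 0.8, seed=12)
        test_pairs = {(g, p) for g, p, _ in test}
        assert not {(g, p) for g, p, _ in train_graph.edges} & test_pairs
        known = [(g, p) for g, p, _ in graph.edges]
        class0 = sample_class0_pairs(train_graph, 10, seed=1, exclude=known)
        assert not set(class0) & test_pairs
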