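"""Residue graphs, embedding providers and the GAT regressor."""

import numpy as np
import pytest

from bidkit.errors import EmbeddingError, ModelError
from bidkit.graph_model import (
    ExternalEmbeddingProvider,
    GATConfig,
    GATNetwork,
    GATRegressor,
    OneHotProvider,
    ResidueGraph,
    build_graph,
    load_model,
    predict,
    save_model,
    split_validation,
    train,
)

from conftest import make_two_chain_complex

TINY = GATConfig(gat_dims=(8, 8, 4), heads=2, fc_dims=(4, 4, 1),
                 lr=5e-3, epochs=10, batch_size=2, seed=0)


def random_graph(rng, n=12, d=6, with_targets=True):
    emb = rng.normal(size=(n, d))
    iu = np.triu_indices(n, k=1)
    keep = rng.random(iu[0].size) < 0.3
    edges = np.column_stack([iu[0][keep], iu[1][keep]])
    targets = rng.uniform(0, 1, n) if with_targets else None
    return ResidueGraph("g", emb, edges, targets)


class TestBuildGraph:
    @pytest.mark.parametrize("dist,expect_edge", [(9.5, True), (11.0, False)])
    def test_edge_rule_at_10_angstrom(self, dist, expect_edge):
        ag = [[0.0, 0, 0], [dist, 0.0, 0.0]]
        rec = make_two_chain_complex(ag, [[0, 100.0, 0]])
        g = build_graph(rec, "A", [OneHotProvider()])
        has_edge = any((a, b) == (0, 1) for a, b in g.edges)
        assert has_edge == expect_edge

    def test_provider_concatenation_dims(self):
        rec = make_two_chain_complex([[0, 0, 0], [4, 0, 0]], [[0, 100, 0]])
        p1 = ExternalEmbeddingProvider(np.ones((2, 7)), "a")
        p2 = ExternalEmbeddingProvider(np.zeros((2, 5)), "b")
        g = build_graph(rec, "A", [p1, p2])
        assert g.dim == 12

    def test_provider_length_mismatch_rejected(self):
        rec = make_two_chain_complex([[0, 0, 0], [4, 0, 0]], [[0, 100, 0]])
        with pytest.raises(EmbeddingError):
            build_graph(rec, "A", [ExternalEmbeddingProvider(np.ones((3, 4)), "bad")])

    def test_consecutive_backbone_neighbors_connected(self, small_cluster):
        rec = small_cluster[0][0]
        g = build_graph(rec, "A", [OneHotProvider()])
        edge_set = {(a, b) for a, b in g.edges}
        n = rec.chain("A").n_residues
        for i in range(n - 1):
            assert (i, i + 1) in edge_set  # CA spacing 3.8 < 10


class TestProviders:
    def test_one_hot_rows(self):
        m = OneHotProvider().embed("ACD")
        assert m.shape == (3, 20)
        np.testing.assert_array_equal(m.sum(axis=1), [1, 1, 1])

    def test_one_hot_x_is_zero_row(self):
        m = OneHotProvider().embed("AXA")
        assert m[1].sum() == 0.0

    def test_one_hot_deterministic(self):
        a, b = OneHotProvider().embed("ACDW"), OneHotProvider().embed("ACDW")
        np.testing.assert_array_equal(a, b)

    def test_external_provider_round_trip(self, tmp_path):
        m = np.random.default_rng(0).normal(size=(5, 9))
        path = tmp_path / "e.csv"
        from bidkit.io_formats import write_embedding_matrix
        write_embedding_matrix(m, path)
        p = ExternalEmbeddingProvider.from_file(path)
        assert p.dim == 9
        np.testing.assert_allclose(p.embed("AAAAA"), m, atol=1e-9)

    def test_external_provider_row_mismatch(self):
        p = ExternalEmbeddingProvider(np.ones((4, 3)), "e")
        with pytest.raises(EmbeddingError):
            p.embed("AAAAA")


class TestForward:
    def test_all_zero_weights_give_final_bias(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng)
        net = GATNetwork(6, TINY, np.random.default_rng(1))
        for p in net.params():
            p[...] = 0.0
        net.fc2.b[...] = 0.37
        out = net.forward(g)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, n=15)
        net = GATNetwork(6, TINY, np.random.default_rng(3))
        perm = rng.permutation(15)
        inv = np.argsort(perm)
        edges_p = np.array(sorted(tuple(sorted((inv[a], inv[b]))) for a, b in g.edges))
        g_perm = ResidueGraph("gp", g.node_embeddings[perm], edges_p,
                              g.targets[perm])
        out = net.forward(g)
        out_perm = net.forward(g_perm)
        np.testing.assert_allclose(out[perm], out_perm, atol=1e-5)

    def test_single_node_graph(self):
        g = ResidueGraph("one", np.ones((1, 6)), np.zeros((0, 2), dtype=int))
        net = GATNetwork(6, TINY, np.random.default_rng(4))
        assert net.forward(g).shape == (1,)

    def test_dim_mismatch_rejected(self):
        g = ResidueGraph("g", np.ones((3, 5)), np.zeros((0, 2), dtype=int))
        net = GATNetwork(6, TINY, np.random.default_rng(5))
        with pytest.raises(ModelError):
            net.forward(g)

    def test_self_loops_not_storable(self):
        with pytest.raises(ModelError):
            ResidueGraph("g", np.ones((3, 2)), np.array([[1, 1]]))

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(6)
        g = random_graph(rng, n=8, d=4)
        cfg = GATConfig(gat_dims=(4, 4, 3), heads=2, fc_dims=(3, 3, 1),
                        lr=1e-3, epochs=1, seed=0)
        net = GATNetwork(4, cfg, np.random.default_rng(7))

        def loss():
            pred = net.forward(g)
            return 0.5 * ((pred - g.targets) ** 2).sum()

        pred = net.forward(g)
        net.zero_grads()
        net.backward(pred - g.targets)
        eps = 1e-6
        for p, grad in zip(net.params(), net.grads()):
            flat_idx = rng.choice(p.size, size=min(3, p.size), replace=False)
            for k in flat_idx:
                idx = np.unravel_index(k, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_loss_decreases(self):
        rng = np.random.default_rng(8)
        graphs = [random_graph(rng) for _ in range(4)]
        cfg = GATConfig(gat_dims=(8, 8, 4), heads=2, fc_dims=(4, 4, 1),
                        lr=5e-3, epochs=30, batch_size=2, seed=0)
        _, history = train(graphs, None, cfg)
        assert history["train_loss"].iloc[-1] <= history["train_loss"].iloc[0]

    def test_same_seed_identical_trajectories(self):
        rng = np.random.default_rng(9)
        graphs = [random_graph(rng) for _ in range(3)]
        val = [random_graph(rng)]
        _, h1 = train(graphs, val, TINY)
        _, h2 = train(graphs, val, TINY)
        np.testing.assert_array_equal(h1["train_loss"], h2["train_loss"])
        np.testing.assert_array_equal(h1["val_loss"], h2["val_loss"])

    def test_no_validation_falls_back_with_warning(self):
        rng = np.random.default_rng(10)
        graphs = [random_graph(rng)]
        with pytest.warns(UserWarning):
            train(graphs, None, TINY)

    def test_targets_required(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ModelError):
            train([random_graph(rng, with_targets=False)], None, TINY)

    def test_model_results_interface_and_serialization(self, tmp_path):
        rng = np.random.default_rng(12)
        graphs = [random_graph(rng) for _ in range(4)]
        res = GATRegressor(graphs[:3], graphs[3:], TINY).fit()
        assert "GAT immunodominance regressor" in res.summary()
        g = graphs[0]
        pred1 = res.predict(g)
        assert len(pred1) == g.n_nodes
        np.testing.assert_array_equal(pred1.scores_raw, res.predict(g).scores_raw)
        # clipping: raw retained, reported clipped to [0, 1]
        assert pred1.scores.min() >= 0.0 and pred1.scores.max() <= 1.0
        path = tmp_path / "model.json"
        res.save(path)
        net = load_model(path)
        np.testing.assert_array_equal(predict(g, net).scores_raw, pred1.scores_raw)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            GATConfig(gat_dims=(8, 8, 4), heads=2, fc_dims=(5, 4, 1))
        with pytest.raises(ValueError):
            GATConfig(gat_dims=(9, 8, 4), heads=2, fc_dims=(4, 4, 1))
        with pytest.raises(ValueError):
            GATConfig(fc_dims=(128, 32, 2))
        cfg = GATConfig()  # the full-size recipe
        assert cfg.gat_dims == (2048, 512, 128)
        assert cfg.heads == 8 and cfg.batch_size == 4 and cfg.epochs == 200

    def test_split_validation_seeded_and_disjoint(self):
        rng = np.random.default_rng(13)
        graphs = [random_graph(rng) for _ in range(10)]
        tr1, va1 = split_validation(graphs, fraction=0.2, seed=5)
        tr2, va2 = split_validation(graphs, fraction=0.2, seed=5)
        assert [g.antigen_id for g in va1] == [g.antigen_id for g in va2]
        assert len(tr1) + len(va1) == 10 and len(va1) == 2
        assert not ({id(g) for g in tr1} & {id(g) for g in va1})
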