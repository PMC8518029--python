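import numpy as np
import pytest

from hogcn import (
    ModelConfig,
    PowerSet,
    bilinear_fuse,
    build_normalized_adjacency,
    encode,
    hogc_layer_forward,
    init_parameters,
    predict_pairs,
    predict_probability,
    propagate_power,
)
from hogcn.model import load_checkpoint, save_checkpoint

from .conftest import random_graph


def dense_norm_adj(graph):
    """Independent dense computation of D^(-1/2)(A+I)D^(-1/2)."""
    a = graph.adjacency().toarray() + np.eye(graph.n_nodes)
    d = np.diag(1.0 / np.sqrt(a.sum(axis=1)))
    return d @ a @ d


def ref_elu(x):
    return np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1)


class TestPropagatePower:
    def test_power_zero_is_identity(self):
        g = random_graph(8, 0.3, 0)
        adj = build_normalized_adjacency(g)
        h = np.random.default_rng(0).standard_normal((8, 5))
        assert np.array_equal(propagate_power(adj, h, 0), h)

    def test_identity_features_reproduce_adjacency(self):
        g = random_graph(7, 0.4, 1)
        adj = build_normalized_adjacency(g)
        out = propagate_power(adj, np.eye(7), 1)
        assert out == pytest.approx(adj.matrix.toarray())

    def test_matches_dense_matrix_power(self):
        g = random_graph(10, 0.3, 2)
        adj = build_normalized_adjacency(g)
        h = np.random.default_rng(1).standard_normal((10, 4))
        dense = np.linalg.matrix_power(dense_norm_adj(g), 3) @ h
        assert propagate_power(adj, h, 3) == pytest.approx(dense, abs=1e-6)

    def test_linearity(self):
        g = random_graph(9, 0.3, 3)
        adj = build_normalized_adjacency(g)
        rng = np.random.default_rng(2)
        h1, h2 = rng.standard_normal((2, 9, 3))
        a, b = 0.7, -1.3
        lhs = propagate_power(adj, a * h1 + b * h2, 2)
        rhs = a * propagate_power(adj, h1, 2) + b * propagate_power(adj, h2, 2)
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_row_mismatch_raises(self):
        g = random_graph(6, 0.4, 4)
        adj = build_normalized_adjacency(g)
        with pytest.raises(ValueError, match="rows"):
            propagate_power(adj, np.zeros((5, 2)), 1)


class TestHOGCLayer:
    def test_reduces_to_plain_gcn_for_first_power(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            g = random_graph(15, 0.25, seed)
            adj = build_normalized_adjacency(g)
            h = rng.standard_normal((15, 6))
            w = rng.standard_normal((6, 4))
            out = hogc_layer_forward(adj, h, [w], PowerSet((1,)), activation="elu")
            ref = ref_elu(dense_norm_adj(g) @ h @ w)  # independent plain GCN layer
            assert out == pytest.approx(ref, abs=1e-6)

    def test_direct_plus_skip_two_block_concatenation(self):
        rng = np.random.default_rng(1)
        g = random_graph(12, 0.3, 1)
        adj = build_normalized_adjacency(g)
        h = rng.standard_normal((12, 5))
        w1, w2 = rng.standard_normal((2, 5, 3))
        out = hogc_layer_forward(adj, h, [w1, w2], PowerSet((1, 2)), activation="elu")
        a_hat = dense_norm_adj(g)
        ref = np.concatenate(
            [ref_elu(a_hat @ h @ w1), ref_elu(a_hat @ a_hat @ h @ w2)], axis=1
        )
        assert out == pytest.approx(ref, abs=1e-6)

    def test_output_width_is_d_times_num_powers(self):
        g = random_graph(10, 0.3, 2)
        adj = build_normalized_adjacency(g)
        cfg = ModelConfig(n_layers=1, powers=PowerSet.up_to(3), hidden_dim=32)
        params = init_parameters(cfg, g.n_nodes, seed=0)
        z = encode(adj, params, cfg)
        assert z.shape == (10, 128)

    def test_identity_weights_concatenate_propagated_blocks(self):
        g = random_graph(8, 0.35, 3)
        adj = build_normalized_adjacency(g)
        h = np.random.default_rng(3).standard_normal((8, 8))
        eye = np.eye(8)
        out = hogc_layer_forward(
            adj, h, [eye] * 4, PowerSet.up_to(3), activation="identity"
        )
        a_hat = dense_norm_adj(g)
        blocks = [h, a_hat @ h, a_hat @ a_hat @ h, np.linalg.matrix_power(a_hat, 3) @ h]
        assert out == pytest.approx(np.concatenate(blocks, axis=1), abs=1e-6)

    def test_shape_error_names_offending_power(self):
        g = random_graph(6, 0.4, 4)
        adj = build_normalized_adjacency(g)
        h = np.zeros((6, 3))
        with pytest.raises(ValueError, match="power 2"):
            hogc_layer_forward(adj, h, [np.zeros((3, 2)), np.zeros((4, 2))], PowerSet((1, 2)))


class TestEncode:
    def test_single_layer_identity_activation_closed_form(self):
        g = random_graph(9, 0.3, 5)
        adj = build_normalized_adjacency(g)
        cfg = ModelConfig(
            n_layers=1, powers=PowerSet((1,)), hidden_dim=4, activation="identity",
            dropout=0.0,
        )
        x = np.random.default_rng(4).standard_normal((9, 5))
        params = init_parameters(cfg, 5, seed=1)
        z = encode(adj, params, cfg, features=x)
        assert z == pytest.approx(dense_norm_adj(g) @ x @ params["enc/l0/W1"], abs=1e-8)

    def test_default_config_embedding_width(self):
        g = random_graph(20, 0.2, 6)
        adj = build_normalized_adjacency(g)
        cfg = ModelConfig()  # 2 layers, P={0..3}, d=32
        params = init_parameters(cfg, g.n_nodes, seed=2)
        assert encode(adj, params, cfg).shape == (20, 128)

    def test_one_hot_lookup_equals_explicit_identity_features(self):
        g = random_graph(30, 0.15, 7)
        adj = build_normalized_adjacency(g)
        cfg = ModelConfig(n_layers=2, powers=PowerSet.up_to(2), hidden_dim=8)
        params = init_parameters(cfg, g.n_nodes, seed=3)
        z_lookup = encode(adj, params, cfg, features=None)
        z_explicit = encode(adj, params, cfg, features=np.eye(g.n_nodes))
        assert z_lookup == pytest.approx(z_explicit, abs=1e-10)

    def test_permutation_equivariance(self):
        g = random_graph(12, 0.3, 8)
        cfg = ModelConfig(n_layers=2, powers=PowerSet.up_to(2), hidden_dim=5)
        x = np.random.default_rng(5).standard_normal((12, 7))
        params = init_parameters(cfg, 7, seed=4)
        adj = build_normalized_adjacency(g)
        z = encode(adj, params, cfg, features=x)
        rng = np.random.default_rng(6)
        for _ in range(20):
            perm = rng.permutation(12)
            inv = np.argsort(perm)
            # relabel node u -> inv[u] so row perm[i] of the original is row i
            edges = inv[g.edges]
            g_perm = g.with_edges(np.stack([edges.min(1), edges.max(1)], axis=1))
            adj_p = build_normalized_adjacency(g_perm)
            z_perm = encode(adj_p, params, cfg, features=x[perm])
            assert z_perm == pytest.approx(z[perm], abs=1e-8)


class TestBilinearDecoder:
    def test_zero_parameters_give_zero_edge_representation(self):
        z = np.ones(4)
        e = bilinear_fuse(z, z, np.zeros((3, 4, 4)), np.zeros(3))
        assert e == pytest.approx(np.zeros(3))

    def test_edge_representation_length(self):
        cfg = ModelConfig()
        params = init_parameters(cfg, 10, seed=0)
        z = np.random.default_rng(7).standard_normal(cfg.d_star)
        assert bilinear_fuse(z, z, params["dec/Wb"], params["dec/b"]).shape == (64,)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            zi, zj = rng.standard_normal((2, 3))
            wb = rng.standard_normal((2, 3, 3))
            b = rng.standard_normal(2)
            ref = np.empty(2)
            for m in range(2):
                acc = b[m]
                for p in range(3):
                    for q in range(3):
                        acc += zi[p] * wb[m, p, q] * zj[q]
                ref[m] = acc if acc > 0 else np.expm1(acc)
            assert bilinear_fuse(zi, zj, wb, b) == pytest.approx(ref, abs=1e-10)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="bilinear dim"):
            bilinear_fuse(np.ones(3), np.ones(3), np.zeros((2, 4, 4)), np.zeros(2))


class TestPredictionHead:
    def test_zero_head_gives_half(self):
        e = np.random.default_rng(9).standard_normal(4)
        p = predict_probability(e, np.zeros((4, 3)), np.zeros(3), np.zeros((3, 1)), np.zeros(1))
        assert p == pytest.approx(0.5)

    def test_probability_monotone_in_final_bias(self):
        rng = np.random.default_rng(10)
        e = rng.standard_normal(4)
        w1, b1, w2 = rng.standard_normal((4, 3)), rng.standard_normal(3), rng.standard_normal((3, 1))
        probs = [predict_probability(e, w1, b1, w2, np.array([c])) for c in (-5, 0, 5, 20)]
        assert np.all(np.diff(probs) > 0) and probs[-1] > 0.999

    def test_matches_explicit_composition(self):
        rng = np.random.default_rng(11)
        e = rng.standard_normal(4)
        w1, b1 = rng.standard_normal((4, 3)), rng.standard_normal(3)
        w2, b2 = rng.standard_normal((3, 1)), rng.standard_normal(1)
        hidden = ref_elu(e @ w1 + b1)
        s = (hidden @ w2 + b2).item()
        assert predict_probability(e, w1, b1, w2, b2) == pytest.approx(
            1 / (1 + np.exp(-s)), abs=1e-6
        )


class TestInitialization:
    def test_identical_seed_bitwise_identical(self):
        cfg = ModelConfig()
        p1 = init_parameters(cfg, 50, seed=11)
        p2 = init_parameters(cfg, 50, seed=11)
        assert p1.keys() == p2.keys()
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)

    def test_xavier_uniform_bound(self):
        cfg = ModelConfig(n_layers=1, powers=PowerSet((1,)), hidden_dim=16)
        params = init_parameters(cfg, 40, seed=12)
        w = params["enc/l0/W1"]
        limit = np.sqrt(6 / (40 + 16))
        assert np.all(np.abs(w) <= limit)
        for name in ("dec/b", "dec/b1", "dec/b2"):
            assert np.all(params[name] == 0)

    def test_empirical_variance_matches_scheme(self):
        # 10^4 entries drawn for a (100, 100) matrix: var ~ 2/(n_in+n_out)
        cfg = ModelConfig(n_layers=1, powers=PowerSet((1,)), hidden_dim=100)
        w = init_parameters(cfg, 100, seed=13)["enc/l0/W1"]
        expected = 2.0 / 200
        assert w.var() == pytest.approx(expected, rel=0.1)


class TestEndToEndForward:
    def test_probabilities_strictly_inside_unit_interval(self):
        g = random_graph(25, 0.2, 9)
        adj = build_normalized_adjacency(g)
        cfg = ModelConfig(n_layers=2, powers=PowerSet.up_to(3), hidden_dim=8, edge_dim=16)
        params = init_parameters(cfg, g.n_nodes, seed=5)
        rng = np.random.default_rng(14)
        pairs = rng.integers(0, 25, size=(60, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        p = predict_pairs(adj, params, cfg, pairs)
        assert np.all((p > 0) & (p < 1))

    def test_symmetrized_scores_invariant_to_orientation(self):
        g = random_graph(15, 0.3, 10)
        adj = build_normalized_adjacency(g)
        cfg = ModelConfig(n_layers=1, powers=PowerSet.up_to(1), hidden_dim=4, edge_dim=8)
        params = init_parameters(cfg, g.n_nodes, seed=6)
        pairs = np.array([[0, 5], [2, 9]])
        fwd = predict_pairs(adj, params, cfg, pairs, symmetrize=True)
        rev = predict_pairs(adj, params, cfg, pairs[:, ::-1], symmetrize=True)
        assert fwd == pytest.approx(rev)

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = ModelConfig(n_layers=1, powers=PowerSet.up_to(1), hidden_dim=4)
        params = init_parameters(cfg, 12, seed=7)
        path = str(tmp_path / "model.ckpt.npz")
        save_checkpoint(path, params, cfg, meta={"note": "test"})
        params2, cfg2, meta = load_checkpoint(path)
        assert cfg2 == cfg and meta == {"note": "test"}
        assert all(np.array_equal(params[k], params2[k]) for k in params)
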