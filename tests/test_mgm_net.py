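import numpy as np
import pytest

from maskmol.mgm_net import (
    ModelConfig,
    embed_graph,
    forward,
    init_parameters,
    load_checkpoint,
    mpnn_layer,
    neighborhood,
    save_checkpoint,
    standardize_property,
)
from maskmol.molgraph import MolecularGraph, build_vocabulary, pair_index, pair_list, smiles_to_graph


def permute_graph(graph, perm):
    """Relabel nodes by perm (new index = position of old in perm)."""
    n = graph.n_nodes
    inv = np.argsort(perm)
    props = graph.node_properties[perm]
    edges = np.empty_like(graph.edge_types)
    for (i, j) in pair_list(n):
        edges[pair_index(i, j, n)] = graph.edge_types[pair_index(perm[i], perm[j], n)]
    return MolecularGraph(n, props, edges), inv


class TestModelConfig:
    def test_defaults_match_reference_scale(self):
        cfg = ModelConfig()
        assert cfg.d0 == 2048 and cfg.n_layers == 4

    def test_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(d0=0)
        with pytest.raises(ValueError):
            ModelConfig(conditional=True)  # property name required
        with pytest.raises(ValueError):
            ModelConfig(message_product="outer")


class TestEmbedGraph:
    def test_fully_masked_node_is_sum_of_mask_rows(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("C", tiny_vocab)
        for k in range(6):
            g.node_properties[0, k] = tiny_vocab.mask_index(k)
        states = embed_graph(g, params, cfg, tiny_vocab)
        expected = sum(
            params[f"emb_node{k}"][tiny_vocab.mask_index(k)] for k in range(6)
        )
        np.testing.assert_array_equal(states.h_v[0], expected)

    def test_identical_nodes_identical_embeddings(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("CCO", tiny_vocab)
        states = embed_graph(g, params, cfg, tiny_vocab)
        # atoms 0 and 1 differ (H counts); craft two identical rows instead
        g.node_properties[1] = g.node_properties[0]
        states = embed_graph(g, params, cfg, tiny_vocab)
        np.testing.assert_array_equal(states.h_v[0], states.h_v[1])

    def test_linearity_in_atom_type(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("CCO", tiny_vocab)
        base = embed_graph(g, params, cfg, tiny_vocab).h_v[0].copy()
        old = g.node_properties[0, 0]
        g.node_properties[0, 0] = (old + 1) % tiny_vocab.n_categories(0)
        new = embed_graph(g, params, cfg, tiny_vocab).h_v[0]
        delta = params["emb_node0"][g.node_properties[0, 0]] - params["emb_node0"][old]
        np.testing.assert_allclose(new - base, delta, atol=1e-12)

    def test_edge_states_are_table_rows(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("CCO", tiny_vocab)
        states = embed_graph(g, params, cfg, tiny_vocab)
        np.testing.assert_array_equal(states.h_e, params["emb_edge"][g.edge_types])


class TestNeighborhood:
    def test_no_bonds_empty(self, tiny_vocab):
        g = MolecularGraph(3, np.zeros((3, 6), dtype=int), np.zeros(3, dtype=int))
        assert neighborhood(g, tiny_vocab, 0) == set()

    def test_chain_middle(self, tiny_vocab):
        g = smiles_to_graph("CCO", tiny_vocab)
        # toolkit-derived: middle carbon bonded to both others
        assert neighborhood(g, tiny_vocab, 1) == {0, 2}

    def test_fully_masked_edges(self, tiny_vocab):
        g = MolecularGraph(
            4, np.zeros((4, 6), dtype=int),
            np.full(6, tiny_vocab.edge_mask_index, dtype=int),
        )
        for i in range(4):
            assert neighborhood(g, tiny_vocab, i) == {0, 1, 2, 3} - {i}

    def test_out_of_range(self, tiny_vocab):
        g = smiles_to_graph("C", tiny_vocab)
        with pytest.raises(IndexError):
            neighborhood(g, tiny_vocab, 5)


class TestMpnnLayer:
    def test_isolated_node_zero_message(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("C", tiny_vocab)
        states = embed_graph(g, params, cfg, tiny_vocab)
        out = mpnn_layer(states, g, params, cfg, tiny_vocab)
        np.testing.assert_array_equal(out.u_v, np.zeros_like(out.u_v))

    def test_disconnected_pair_keeps_zero_message(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = MolecularGraph(2, np.zeros((2, 6), dtype=int), np.zeros(1, dtype=int))
        states = embed_graph(g, params, cfg, tiny_vocab)
        out = mpnn_layer(states, g, params, cfg, tiny_vocab)
        np.testing.assert_allclose(out.u_v, 0.0, atol=1e-12)


class TestForward:
    def test_rows_are_simplices(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("c1ccccc1", tiny_vocab)
        out = forward(g, params, cfg, tiny_vocab)
        for k, p in enumerate(out["node"]):
            assert p.shape == (6, tiny_vocab.n_categories(k))
            assert np.all(p >= 0)
            np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(out["edge"].sum(axis=-1), 1.0, atol=1e-6)
        assert out["edge"].shape == (15, 5)  # MASK excluded from the simplex

    def test_zero_head_weights_give_uniform(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        params = {k: v.copy() for k, v in params.items()}
        for k in list(params):
            if k.startswith("head_"):
                params[k][:] = 0.0
        g = smiles_to_graph("CCO", tiny_vocab)
        out = forward(g, params, cfg, tiny_vocab)
        for k, p in enumerate(out["node"]):
            np.testing.assert_allclose(p, 1.0 / tiny_vocab.n_categories(k), atol=1e-12)
        np.testing.assert_allclose(out["edge"], 0.2, atol=1e-12)

    def test_determinism(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("CNC", tiny_vocab)
        a = forward(g, params, cfg, tiny_vocab)
        b = forward(g, params, cfg, tiny_vocab)
        for pa, pb in zip(a["node"], b["node"]):
            np.testing.assert_array_equal(pa, pb)
        np.testing.assert_array_equal(a["edge"], b["edge"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_permutation_equivariance(self, tiny_vocab, tiny_model, seed):
        params, cfg = tiny_model
        g = smiles_to_graph("CC(=O)NC", tiny_vocab)
        g.edge_types[2] = tiny_vocab.edge_mask_index  # include a masked slot
        g.node_properties[0, 0] = tiny_vocab.mask_index(0)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(g.n_nodes)
        gp, _ = permute_graph(g, perm)
        out = forward(g, params, cfg, tiny_vocab)
        outp = forward(gp, params, cfg, tiny_vocab)
        n = g.n_nodes
        for k in range(6):
            np.testing.assert_allclose(outp["node"][k], out["node"][k][perm], atol=1e-8)
        for (i, j) in pair_list(n):
            np.testing.assert_allclose(
                outp["edge"][pair_index(i, j, n)],
                out["edge"][pair_index(perm[i], perm[j], n)],
                atol=1e-8,
            )

    def test_conditioner_changes_output(self, tiny_vocab):
        cfg = ModelConfig(d0=16, n_layers=2, conditional=True, property_name="molwt")
        params = init_parameters(tiny_vocab, cfg, np.random.default_rng(3))
        g = smiles_to_graph("CCO", tiny_vocab)
        a = forward(g, params, cfg, tiny_vocab, y_std=-1.5)
        b = forward(g, params, cfg, tiny_vocab, y_std=1.5)
        diffs = [np.abs(pa - pb).max() for pa, pb in zip(a["node"], b["node"])]
        assert max(diffs) > 1e-6

    def test_conditional_requires_y(self, tiny_vocab):
        cfg = ModelConfig(d0=8, n_layers=1, conditional=True, property_name="molwt")
        params = init_parameters(tiny_vocab, cfg, np.random.default_rng(0))
        g = smiles_to_graph("C", tiny_vocab)
        with pytest.raises(ValueError):
            forward(g, params, cfg, tiny_vocab)


class TestStandardize:
    def test_mean_maps_to_zero(self):
        assert standardize_property(5.0, 5.0, 2.0) == 0.0

    def test_one_sigma_maps_to_one(self):
        assert standardize_property(7.0, 5.0, 2.0) == 1.0

    def test_toy_list_oracle(self):
        ys = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        mean, std = ys.mean(), ys.std()
        for y in ys:
            assert np.isclose(standardize_property(y, mean, std), (y - mean) / std)

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            standardize_property(1.0, 0.0, 0.0)


class TestCheckpointIO:
    def test_roundtrip(self, tmp_path, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        path = str(tmp_path / "ckpt")
        save_checkpoint(path, params, cfg, tiny_vocab, {"note": "test"})
        p2, cfg2, vocab2, meta = load_checkpoint(path)
        assert cfg2 == cfg and vocab2 == tiny_vocab and meta["note"] == "test"
        for k in params:
            np.testing.assert_array_equal(params[k], p2[k])
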