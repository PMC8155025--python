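import math

import numpy as np
import pytest

from maskmol.fixtures import dataset_from_smiles
from maskmol.molgraph import MolecularGraph, build_vocabulary, smiles_to_graph
from maskmol.sample import (
    Marginals,
    SamplerConfig,
    estimate_marginals,
    generate,
    generate_ensemble,
    generate_step,
    init_graph,
)


class TestSamplerConfig:
    def test_reference_defaults(self):
        assert SamplerConfig().n_steps == 400  # QM9-like default

    def test_chembl_like_override(self):
        assert SamplerConfig(alpha=0.01, n_steps=300).n_steps == 300

    def test_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(init_strategy="other")
        with pytest.raises(ValueError):
            SamplerConfig(n_steps=-1)
        with pytest.raises(ValueError):
            SamplerConfig(alpha=1.5, n_steps=10)


class TestEstimateMarginals:
    def test_single_chain_edge_marginal(self):
        vocab = build_vocabulary(["CCO"])
        ds, _ = dataset_from_smiles(["CCO"], vocab)
        m = estimate_marginals(ds, vocab)
        np.testing.assert_allclose(m.edge_freqs, [1 / 3, 2 / 3, 0, 0, 0])

    def test_point_mass_atom_type(self):
        vocab = build_vocabulary(["C"])
        ds, _ = dataset_from_smiles(["C"], vocab)
        m = estimate_marginals(ds, vocab)
        np.testing.assert_allclose(m.node_property_freqs[0], [1.0])

    def test_frequencies_sum_to_one(self, fixture_splits, fixture_vocab):
        ds_train, _ = fixture_splits
        m = estimate_marginals(ds_train, fixture_vocab)
        for f in m.node_property_freqs:
            assert np.isclose(f.sum(), 1.0)
        assert np.isclose(m.edge_freqs.sum(), 1.0)
        assert np.isclose(m.node_count_freqs.sum(), 1.0)

    def test_empty_dataset(self, fixture_vocab):
        from maskmol.molgraph import Dataset

        with pytest.raises(ValueError):
            estimate_marginals(Dataset(graphs=[]), fixture_vocab)


class TestInitGraph:
    def test_training_one_graph_dataset(self):
        vocab = build_vocabulary(["CCO"])
        ds, _ = dataset_from_smiles(["CCO"], vocab)
        g = init_graph("training", ds, np.random.default_rng(0))
        np.testing.assert_array_equal(g.node_properties, ds.graphs[0].node_properties)

    def test_marginal_point_mass_determined(self):
        m = Marginals(
            node_property_freqs=[np.array([1.0])] * 6,
            edge_freqs=np.array([0.0, 1.0, 0.0, 0.0, 0.0]),
            node_counts=np.array([3]),
            node_count_freqs=np.array([1.0]),
        )
        g = init_graph("marginal", m, np.random.default_rng(0))
        assert g.n_nodes == 3
        assert np.all(g.node_properties == 0)
        assert np.all(g.edge_types == 1)

    def test_marginal_frequencies_within_bands(self):
        edge_p = np.array([0.5, 0.3, 0.1, 0.1, 0.0])
        m = Marginals(
            node_property_freqs=[np.array([0.7, 0.3])] + [np.array([1.0])] * 5,
            edge_freqs=edge_p,
            node_counts=np.array([4]),
            node_count_freqs=np.array([1.0]),
        )
        rng = np.random.default_rng(1)
        n_draws = 10_000
        counts = np.zeros(5)
        for _ in range(n_draws):
            g = init_graph("marginal", m, rng)
            np.add.at(counts, g.edge_types, 1)
        freqs = counts / (6 * n_draws)
        sigma = np.sqrt(edge_p * (1 - edge_p) / (6 * n_draws))
        assert np.all(np.abs(freqs - edge_p) <= 3 * np.maximum(sigma, 1e-12))

    def test_type_mismatch(self):
        vocab = build_vocabulary(["C"])
        ds, _ = dataset_from_smiles(["C"], vocab)
        with pytest.raises(TypeError):
            init_graph("marginal", ds, np.random.default_rng(0))


class TestGenerateStep:
    def test_alpha_zero_identity_with_warning(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("CCO", tiny_vocab)
        with pytest.warns(UserWarning):
            out = generate_step(g, params, cfg, tiny_vocab, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.node_properties, g.node_properties)
        np.testing.assert_array_equal(out.edge_types, g.edge_types)

    def test_changed_slots_bounded(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("CC(=O)NC", tiny_vocab)
        alpha = 0.2
        bound = math.ceil(alpha * g.n_slots)
        rng = np.random.default_rng(1)
        for _ in range(20):
            out = generate_step(g, params, cfg, tiny_vocab, alpha, rng)
            changed = int((out.node_properties != g.node_properties).sum())
            changed += int((out.edge_types != g.edge_types).sum())
            assert changed <= bound
            assert not out.has_mask(tiny_vocab)

    def test_masked_input_rejected(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        g = smiles_to_graph("CCO", tiny_vocab)
        g.edge_types[0] = tiny_vocab.edge_mask_index
        with pytest.raises(ValueError):
            generate_step(g, params, cfg, tiny_vocab, 0.1, np.random.default_rng(0))


class TestGenerate:
    def test_k_zero_trajectory_is_init(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        ds, _ = dataset_from_smiles(["CCO"], tiny_vocab)
        sampler = SamplerConfig(init_strategy="training", alpha=0.1, n_steps=0, seed=0)
        traj, recorded = generate(params, cfg, tiny_vocab, sampler, ds)
        assert len(traj) == 1

    @pytest.mark.parametrize("k", [1, 5])
    def test_trajectory_length(self, tiny_vocab, tiny_model, k):
        params, cfg = tiny_model
        ds, _ = dataset_from_smiles(["CC=O"], tiny_vocab)
        sampler = SamplerConfig(
            init_strategy="training", alpha=0.2, n_steps=k, seed=3, record_every=(0, k)
        )
        traj, recorded = generate(params, cfg, tiny_vocab, sampler, ds)
        assert len(traj) == k + 1
        assert set(recorded) == {0, k}

    def test_seeded_determinism(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        ds, _ = dataset_from_smiles(["CCO", "CNC", "CC=O"], tiny_vocab)
        sampler = SamplerConfig(init_strategy="training", alpha=0.3, n_steps=10, seed=9)
        t1, _ = generate(params, cfg, tiny_vocab, sampler, ds)
        t2, _ = generate(params, cfg, tiny_vocab, sampler, ds)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.node_properties, b.node_properties)
            np.testing.assert_array_equal(a.edge_types, b.edge_types)

    def test_conditional_requires_stats(self, tiny_vocab):
        from maskmol.mgm_net import ModelConfig, init_parameters

        cfg = ModelConfig(d0=8, n_layers=1, conditional=True, property_name="molwt")
        params = init_parameters(tiny_vocab, cfg, np.random.default_rng(0))
        ds, _ = dataset_from_smiles(["CCO"], tiny_vocab)
        sampler = SamplerConfig(init_strategy="training", alpha=0.1, n_steps=1, y_target=40.0)
        with pytest.raises(ValueError):
            generate(params, cfg, tiny_vocab, sampler, ds)


class TestGenerateEnsemble:
    def test_matches_chain_count_and_determinism(self, tiny_vocab, tiny_model):
        params, cfg = tiny_model
        ds, _ = dataset_from_smiles(["CCO", "CC=O", "C#N"], tiny_vocab)
        sampler = SamplerConfig(init_strategy="training", alpha=0.2, n_steps=5, seed=4)
        a = generate_ensemble(params, cfg, tiny_vocab, sampler, ds, 7)
        b = generate_ensemble(params, cfg, tiny_vocab, sampler, ds, 7)
        assert len(a) == 7
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.node_properties, gb.node_properties)
            np.testing.assert_array_equal(ga.edge_types, gb.edge_types)
        for g in a:
            assert not g.has_mask(tiny_vocab)
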