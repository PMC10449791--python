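import math

import numpy as np
import pytest

from gcap import autodiff as ad
from gcap.autodiff import Tensor
from gcap.featurize import smiles_to_graph
from gcap.model import (
    AttentionRecord,
    FusionModule,
    GCAPModel,
    MGAEncoder,
    ModelConfig,
    MultiScaleCNN,
)
from gcap.nn import Conv1dSame, MLPHead

from conftest import TINY_CONFIG
from oracle import cnn_oracle, conv_same_oracle, forward_oracle, fusion_oracle, mga_oracle


class TestModelConfig:
    def test_width_must_divide_heads(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(hidden_width=30, fusion_heads=4)

    def test_even_scale_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(cnn_scales=(1, 2))

    def test_zero_heads_rejected(self):
        with pytest.raises(ValueError, match="head"):
            ModelConfig(fusion_heads=0)


def make_mga(seed=0, cfg=None):
    cfg = cfg or ModelConfig(
        hidden_width=8, mga_layers=1, supernode_layers=2, cnn_layers=1,
        cnn_scales=(1, 3), fusion_heads=2, mlp_hidden=8, seed=seed,
    )
    g = smiles_to_graph("CCO")
    rng = np.random.default_rng(seed)
    return (
        MGAEncoder(g.atom_features.shape[1], g.bond_features.shape[1], cfg, rng),
        g,
        cfg,
    )


class TestMGA:
    def test_attention_groups_sum_to_one(self):
        mga, g, _ = make_mga()
        _, rec = mga(smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O"))  # aspirin
        for inc_node, alpha in rec.edge_alphas + rec.neighbor_alphas:
            for i in np.unique(inc_node):
                assert alpha[inc_node == i].sum() == pytest.approx(1.0, abs=1e-6)
        for alphas in rec.supernode_alphas:
            assert alphas.sum() == pytest.approx(1.0, abs=1e-6)

    def test_terminal_atom_single_edge_alpha_is_one(self):
        mga, g, _ = make_mga()
        _, rec = mga(g)  # CCO: atoms 0 and 2 have exactly one incident bond
        inc_node, alpha = rec.edge_alphas[0]
        assert alpha[inc_node == 0] == pytest.approx(1.0)
        assert alpha[inc_node == 2] == pytest.approx(1.0)

    def test_matches_scalar_transcription_on_path_graph(self):
        """Eqs 3-5 + GRU on the CCO path graph, loop-based oracle."""
        mga, g, _ = make_mga(seed=5)
        vec, _ = mga(g)
        expected = mga_oracle(mga, g)
        assert np.allclose(vec.data, expected, atol=1e-12)

    def test_single_atom_supernode_init_equals_atom_state(self):
        mga, _, _ = make_mga()
        g = smiles_to_graph("C")
        H = np.maximum(
            g.atom_features @ mga.atom_proj.weight.data + mga.atom_proj.bias.data, 0
        )
        # supernode init is the sum over the single node's state
        vec, rec = mga(g)
        assert np.allclose(vec.data, mga_oracle(mga, g), atol=1e-12)
        assert rec.supernode_alphas[0].shape == (1,)
        assert rec.supernode_alphas[0][0] == pytest.approx(1.0)

    def test_permutation_invariance_of_readout(self):
        # same molecule entered from either end: isomorphic graphs with
        # relabeled atoms must give the identical readout
        mga, _, _ = make_mga(seed=9)
        v1, _ = mga(smiles_to_graph("CCO"))
        v2, _ = mga(smiles_to_graph("OCC"))
        assert np.allclose(v1.data, v2.data, atol=1e-9)

    def test_isolated_node_state_passes_through(self):
        mga, _, _ = make_mga()
        g = smiles_to_graph("C")  # no bonds: edge/neighbor stages are a no-op
        vec, rec = mga(g)
        assert rec.edge_alphas == [] and rec.neighbor_alphas == []


class TestCNN:
    def test_length_preserved_at_every_layer(self):
        cfg = ModelConfig(hidden_width=8, cnn_layers=3, cnn_scales=(1, 3, 5, 7),
                          fusion_heads=2, seed=0)
        rng = np.random.default_rng(0)
        cnn = MultiScaleCNN(vocab_size=5, cfg=cfg, rng=rng)
        onehot = np.zeros((100, 5))
        onehot[np.arange(100), np.arange(100) % 5] = 1
        x = Tensor(onehot[None]) @ cnn.embedding
        for bank in cnn.layers:
            maps = ad.concat([ad.relu(conv(x)) for conv in bank], axis=-1)
            assert maps.shape[1] == 100
            x = maps + x
        assert cnn(Tensor(onehot[None])).shape == (1, 8)

    def test_scale_one_identity_convolution(self):
        rng = np.random.default_rng(0)
        conv = Conv1dSame(3, 3, 1, rng)
        conv.weight.data = np.eye(3)
        conv.bias.data = np.zeros(3)
        x = np.random.default_rng(1).normal(size=(1, 7, 3))
        assert np.allclose(conv(Tensor(x)).data, x)

    def test_hand_convolution_on_toy_input(self):
        """Windowed convolution on a length-5 input with hand-set weights."""
        rng = np.random.default_rng(0)
        conv = Conv1dSame(1, 1, 3, rng)
        conv.weight.data = np.array([[1.0], [2.0], [3.0]])  # window offsets -1,0,+1
        conv.bias.data = np.array([0.5])
        x = np.array([[[1.0], [2.0], [3.0], [4.0], [5.0]]])
        out = conv(Tensor(x)).data[0, :, 0]
        # manual windows with zero padding
        expected = [
            0 * 1 + 1 * 2 + 2 * 3 + 0.5,
            1 * 1 + 2 * 2 + 3 * 3 + 0.5,
            2 * 1 + 3 * 2 + 4 * 3 + 0.5,
            3 * 1 + 4 * 2 + 5 * 3 + 0.5,
            4 * 1 + 5 * 2 + 0 * 3 + 0.5,
        ]
        assert np.allclose(out, expected)
        oracle = conv_same_oracle(conv.weight.data, conv.bias.data, x[0], 3)
        assert np.allclose(out, oracle[:, 0])

    def test_matches_loop_oracle(self):
        cfg = ModelConfig(hidden_width=8, cnn_layers=2, cnn_scales=(1, 3),
                          fusion_heads=2, seed=3)
        cnn = MultiScaleCNN(vocab_size=6, cfg=cfg, rng=np.random.default_rng(3))
        rng = np.random.default_rng(4)
        onehot = np.zeros((20, 6))
        onehot[np.arange(20), rng.integers(0, 6, 20)] = 1
        out = cnn(Tensor(onehot[None])).data[0]
        assert np.allclose(out, cnn_oracle(cnn, onehot), atol=1e-12)


class TestFusion:
    def make_fusion(self, literal=False, pool="mean"):
        cfg = ModelConfig(hidden_width=4, fusion_heads=2, cnn_scales=(1, 3),
                          literal_eq9=literal, fusion_pool=pool, seed=7)
        return FusionModule(cfg, np.random.default_rng(7)), cfg

    def test_attention_rows_sum_to_one(self):
        fusion, _ = self.make_fusion()
        M = Tensor(np.random.default_rng(0).normal(size=(7, 4)))
        rows = fusion.attention_rows(M)
        assert np.allclose(rows.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_bruteforce_oracle_tiny_case(self):
        """7x4 stack, 2 heads: scaled dot-product attention vs loop oracle."""
        fusion, _ = self.make_fusion()
        M = np.random.default_rng(1).normal(size=(7, 4))
        out = fusion(Tensor(M[None])).data[0]
        assert np.allclose(out, fusion_oracle(fusion, M), atol=1e-12)

    def test_literal_printed_form_matches_its_oracle(self):
        lit, _ = self.make_fusion(literal=True)
        M = np.random.default_rng(2).normal(size=(7, 4))
        out = lit(Tensor(M[None])).data[0]
        assert np.allclose(out, fusion_oracle(lit, M), atol=1e-12)

    def test_single_head_degenerate_case(self):
        cfg = ModelConfig(hidden_width=4, fusion_heads=1, cnn_scales=(1, 3), seed=7)
        fusion = FusionModule(cfg, np.random.default_rng(7))
        M = np.random.default_rng(3).normal(size=(7, 4))
        assert np.allclose(
            fusion(Tensor(M[None])).data[0], fusion_oracle(fusion, M), atol=1e-12
        )


class TestHeads:
    def test_outputs_in_unit_interval(self, tiny_model, tiny_features):
        pred, _ = tiny_model.forward(tiny_features[0])
        assert 0 <= pred.association_score <= 1
        assert (pred.class_scores >= 0).all() and (pred.class_scores <= 1).all()

    def test_zero_weight_heads_output_half(self):
        head = MLPHead(4, 3, 7, np.random.default_rng(0))
        for p in head.parameters():
            p.data[...] = 0.0
        out = head(Tensor(np.ones((1, 4))))
        assert np.allclose(out.data, 0.5)

    def test_sigmoid_closed_form(self):
        head = MLPHead(2, 2, 1, np.random.default_rng(0))
        head.fc1.weight.data = np.eye(2)
        head.fc1.bias.data = np.zeros(2)
        head.fc2.weight.data = np.array([[1.0], [1.0]])
        head.fc2.bias.data = np.array([0.25])
        out = head(Tensor(np.array([[1.0, 2.0]])))
        assert out.data[0, 0] == pytest.approx(1 / (1 + math.exp(-3.25)), rel=1e-12)


class TestEncodeStack:
    def test_shape_contract(self, tiny_model, tiny_features, block_context):
        assoc, classes, _ = tiny_model.forward_batch(tiny_features[:3])
        assert assoc.shape == (3, 1) and classes.shape == (3, 7)

    def test_zero_inputs_give_bias_rows(self, tiny_model):
        d = tiny_model.config.hidden_width
        zeros = [Tensor(np.zeros((1, w))) for w in (
            d, d,
            tiny_model.proj_drug_int.weight.shape[0],
            tiny_model.proj_drug_ser.weight.shape[0],
            tiny_model.proj_semantic.weight.shape[0],
            tiny_model.proj_adr_int.weight.shape[0],
            tiny_model.proj_adr_ser.weight.shape[0],
        )]
        M = tiny_model.encode_stack(*zeros, activation=False)
        biases = [
            tiny_model.proj_graph.bias.data,
            tiny_model.proj_cnn.bias.data,
            tiny_model.proj_drug_int.bias.data,
            tiny_model.proj_drug_ser.bias.data,
            tiny_model.proj_semantic.bias.data,
            tiny_model.proj_adr_int.bias.data,
            tiny_model.proj_adr_ser.bias.data,
        ]
        assert np.allclose(M.data[0], np.stack(biases))

    def test_projections_are_affine(self, tiny_model):
        w = tiny_model.proj_semantic.weight.shape[0]
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(1, w)), rng.normal(size=(1, w))
        proj = tiny_model.proj_semantic
        lhs = proj(Tensor(a + b)).data - proj(Tensor(a)).data - proj(Tensor(b)).data
        rhs = -proj(Tensor(np.zeros((1, w)))).data
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestEndToEnd:
    def test_forward_deterministic_across_runs(self, block_context, tiny_features):
        m1 = block_context.make_model(TINY_CONFIG)
        m2 = block_context.make_model(TINY_CONFIG)
        p1, _ = m1.forward(tiny_features[0])
        p2, _ = m2.forward(tiny_features[0])
        assert p1.association_score == p2.association_score
        assert (p1.class_scores == p2.class_scores).all()

    def test_graph_branch_invariant_to_atom_order(self, block_context, tiny_features):
        # readout is a sum + softmax over atoms: relabeling the atoms of the
        # same graph must not change it
        model = block_context.make_model(TINY_CONFIG)
        pf = tiny_features[0]
        v1, _ = model.mga(pf.graph)
        from gcap.featurize.graphs import MolecularGraph

        perm = np.arange(pf.graph.n_atoms)[::-1].copy()
        inv = np.argsort(perm)
        g2 = MolecularGraph(
            atom_features=pf.graph.atom_features[perm],
            bond_features=pf.graph.bond_features,
            bonds=[(int(inv[i]), int(inv[j])) for i, j in pf.graph.bonds],
        )
        g2.incidence = [[] for _ in range(g2.n_atoms)]
        g2.neighbors = [[] for _ in range(g2.n_atoms)]
        for b, (i, j) in enumerate(g2.bonds):
            g2.incidence[i].append(b)
            g2.neighbors[i].append(j)
            g2.incidence[j].append(b)
            g2.neighbors[j].append(i)
        v2, _ = model.mga(g2)
        assert np.allclose(v1.data, v2.data, atol=1e-9)

    def test_full_forward_matches_scalar_reimplementation(
        self, tiny_model, tiny_features
    ):
        """Frozen tiny model: network forward vs from-scratch loop oracle."""
        for pf in tiny_features[:5]:
            pred, _ = tiny_model.forward(pf)
            assoc_o, classes_o = forward_oracle(tiny_model, pf)
            assert pred.association_score == pytest.approx(assoc_o[0], abs=1e-10)
            assert np.allclose(pred.class_scores, classes_o, atol=1e-10)

    def test_attention_record_export_table(self, tiny_model, tiny_features):
        _, rec = tiny_model.forward(tiny_features[0])
        frame = rec.supernode_frame()
        assert set(frame.columns) == {"layer", "atom", "score"}
        per_layer = frame.groupby("layer")["score"].sum()
        assert np.allclose(per_layer.values, 1.0, atol=1e-6)
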