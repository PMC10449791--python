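import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from gcap.featurize import (
    UNKNOWN_TOKEN,
    build_interaction_matrices,
    build_semantic_dag,
    build_semantic_vocabulary,
    build_smiles_vocabulary,
    encode_semantic_vector,
    encode_smiles_matrix,
    extract_pair_profiles,
    smiles_to_graph,
    tokenize_smiles,
)
from gcap.labeling import BenchmarkDataset, SeriousnessLabel

# Two-character element symbols a greedy tokenizer must keep whole.
TWO_CHAR_ELEMENTS = {"Cl", "Br"}


class TestTokenizer:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCO", ["C", "C", "O"]),
            ("CCl", ["C", "Cl"]),
            ("C(=O)O", ["C", "(", "=", "O", ")", "O"]),
            ("BrCC", ["Br", "C", "C"]),
            ("c1ccccc1", ["c", "1", "c", "c", "c", "c", "c", "1"]),
            ("C[nH]C", ["C", "[nH]", "C"]),
            ("C%10CC%10", ["C", "%10", "C", "C", "%10"]),
            ("C/C=C\\C", ["C", "/", "C", "=", "C", "\\", "C"]),
        ],
    )
    def test_examples_against_symbol_table(self, smiles, expected):
        assert tokenize_smiles(smiles) == expected

    def test_two_char_elements_never_split(self):
        for smi in ("CCl", "ClC", "BrBr", "C(Cl)Br"):
            for tok in tokenize_smiles(smi):
                if tok in ("C", "l", "B", "r"):
                    assert tok == "C"

    def test_unparseable_character_becomes_unknown_with_warning(self):
        with pytest.warns(UserWarning, match="unparseable"):
            tokens = tokenize_smiles("C!C")
        assert tokens == ["C", UNKNOWN_TOKEN, "C"]

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            tokenize_smiles("")


class TestEncodingMatrix:
    @pytest.fixture
    def vocab(self):
        return build_smiles_vocabulary(["CCO", "CCl", "c1ccccc1", "C(=O)N"])

    def test_twenty_tokens_pad_rows_21_to_100(self, vocab):
        tokens = ["C"] * 20
        enc = encode_smiles_matrix(tokens, vocab, l_max=100)
        assert enc.matrix.shape == (100, vocab.size)
        assert (enc.matrix[:20].sum(axis=1) == 1).all()
        assert (enc.matrix[20:] == 0).all()

    def test_truncation_beyond_l_max(self, vocab):
        enc = encode_smiles_matrix(["C"] * 120, vocab, l_max=100)
        assert enc.length == 120
        assert (enc.matrix.sum(axis=1) == 1).all()

    def test_out_of_vocabulary_token_lights_unknown_column(self, vocab):
        enc = encode_smiles_matrix(["Si"], vocab)
        assert enc.matrix[0, 0] == 1  # index 0 is reserved for <unk>

    def test_empty_token_list_warns_zero_matrix(self, vocab):
        with pytest.warns(UserWarning):
            enc = encode_smiles_matrix([], vocab)
        assert enc.matrix.sum() == 0

    @given(n=st.integers(1, 150))
    @settings(max_examples=30, deadline=None)
    def test_total_ones_is_min_length_lmax(self, n):
        vocab = build_smiles_vocabulary(["CCO"])
        enc = encode_smiles_matrix(["C"] * n, vocab, l_max=100)
        assert enc.matrix.sum() == min(n, 100)
        assert set(enc.matrix.sum(axis=1)) <= {0, 1}


class TestMolecularGraph:
    def test_chain_molecule(self):
        g = smiles_to_graph("CCO")
        assert g.n_atoms == 3 and g.n_bonds == 2

    def test_benzene_aromatic_flags(self):
        g = smiles_to_graph("c1ccccc1")
        assert g.n_atoms == 6 and g.n_bonds == 6
        mol = Chem.MolFromSmiles("c1ccccc1")
        aromatic_col = g.atom_features[:, -6]  # flag sits just before the H one-hot
        # cross-check against the chemistry toolkit's own parse
        assert all(
            bool(a) == mol.GetAtomWithIdx(i).GetIsAromatic()
            for i, a in enumerate(aromatic_col)
        )
        assert (g.bond_features[:, 3] == 1).all()  # aromatic bond type one-hot

    def test_single_atom_graph(self):
        g = smiles_to_graph("C")
        assert g.n_atoms == 1 and g.n_bonds == 0
        assert g.incidence == [[]]

    def test_parse_failure_names_the_drug(self):
        with pytest.raises(ValueError, match="drugX"):
            smiles_to_graph("not_a_smiles", name="drugX")

    def test_atom_order_permutation_invariance_of_multisets(self):
        # same molecule written from different starting atoms
        g1 = smiles_to_graph("CCO")
        g2 = smiles_to_graph("OCC")
        m1 = sorted(tuple(row) for row in g1.atom_features)
        m2 = sorted(tuple(row) for row in g2.atom_features)
        assert m1 == m2
        assert g1.n_bonds == g2.n_bonds


class TestSemanticDAG:
    def test_worked_two_id_example_has_seven_descriptors(self):
        dag = build_semantic_dag("Meningitis Bacterial", "17.06.10.002; 11.02.01.013")
        assert dag.n_descriptors == 7

    def test_single_id_four_descriptors(self):
        dag = build_semantic_dag("X", "01.02.03.004")
        assert dag.n_descriptors == 4
        assert dag.nodes == {"01", "01.02", "01.02.03", "X"}

    def test_shared_prefixes_counted_once(self):
        dag = build_semantic_dag("X", "01.02.03.004; 01.02.05.006")
        # shared 01 and 01.02, distinct 01.02.03 / 01.02.05, one leaf
        assert dag.n_descriptors == 5

    def test_malformed_id_names_the_adr(self):
        with pytest.raises(ValueError, match="BadTerm"):
            build_semantic_dag("BadTerm", "01.xx.03")

    def test_acyclic_edges_point_to_extensions(self):
        dag = build_semantic_dag("X", "01.02.03.004")
        for parent, child in dag.edges:
            if child != "X":
                assert child.startswith(parent + ".")

    @given(
        ids=st.lists(
            st.lists(st.integers(1, 5), min_size=1, max_size=4),
            min_size=1,
            max_size=4,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_node_count_equals_prefix_union_plus_leaf(self, ids):
        id_strings = [".".join(f"{x:02d}" for x in levels) for levels in ids]
        dag = build_semantic_dag("LEAF", "; ".join(id_strings))
        prefixes = set()
        for levels in ids:
            for k in range(1, len(levels)):
                prefixes.add(".".join(f"{x:02d}" for x in levels[:k]))
        assert dag.n_descriptors == len(prefixes) + 1


class TestSemanticVectors:
    def test_disjoint_ids_vocabulary_size(self):
        d1 = build_semantic_dag("A", "01.01.01.001")
        d2 = build_semantic_dag("B", "02.02.02.002")
        vocab = build_semantic_vocabulary([d1, d2])
        assert len(vocab) == 8

    def test_duplicate_dags_idempotent(self):
        d1 = build_semantic_dag("A", "01.01.01.001")
        assert len(build_semantic_vocabulary([d1, d1])) == len(
            build_semantic_vocabulary([d1])
        )

    def test_full_dag_vector_sum(self):
        dag = build_semantic_dag("Meningitis Bacterial", "17.06.10.002; 11.02.01.013")
        vocab = build_semantic_vocabulary([dag])
        vec = encode_semantic_vector(dag, vocab)
        assert vec.vector.sum() == 7

    def test_unseen_nodes_skipped_and_counted(self):
        d1 = build_semantic_dag("A", "01.01.01.001")
        d2 = build_semantic_dag("B", "01.01.02.001")
        vocab = build_semantic_vocabulary([d1])
        vec = encode_semantic_vector(d2, vocab)
        # shared prefixes 01, 01.01 present; 01.01.02 and leaf B missing
        assert vec.vector.sum() == 2
        assert vec.n_missing == 2

    def test_empty_intersection_warns(self):
        d1 = build_semantic_dag("A", "01.01.01.001")
        d2 = build_semantic_dag("B", "09.09.09.009")
        with pytest.warns(UserWarning):
            vec = encode_semantic_vector(d2, build_semantic_vocabulary([d1]))
        assert vec.vector.sum() == 0

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_vector_sum_equals_intersection_size(self, data):
        ids1 = data.draw(st.lists(st.integers(1, 3), min_size=1, max_size=4))
        ids2 = data.draw(st.lists(st.integers(1, 3), min_size=1, max_size=4))
        d1 = build_semantic_dag("A", ".".join(f"{x:02d}" for x in ids1))
        d2 = build_semantic_dag("B", ".".join(f"{x:02d}" for x in ids2))
        vocab = build_semantic_vocabulary([d1])
        vec = encode_semantic_vector(d2, vocab)
        assert vec.vector.sum() == len(d2.nodes & set(vocab))


def tiny_benchmark():
    labels = {}
    pairs = [("d1", "s1"), ("d1", "s2"), ("d2", "s1"), ("d2", "s3"), ("d3", "s2")]
    serious = {("d1", "s1"), ("d2", "s3")}
    for p in pairs:
        if p in serious:
            labels[p] = SeriousnessLabel(True, (0, 0, 0, 0, 0, 0, 1), "synthetic")
        else:
            labels[p] = SeriousnessLabel(False, (0,) * 7, "synthetic")
    return BenchmarkDataset(
        drugs=["d1", "d2", "d3"],
        adrs=["s1", "s2", "s3"],
        interactions=set(pairs),
        labels=labels,
    )


class TestInteractionMatrices:
    def test_matrix_sums_match_ground_truth(self):
        mats = build_interaction_matrices(tiny_benchmark())
        assert mats.r_interaction.sum() == 5
        assert mats.r_seriousness.sum() == 2

    def test_serious_subset_of_known(self):
        mats = build_interaction_matrices(tiny_benchmark())
        assert (mats.r_seriousness <= mats.r_interaction).all()

    def test_empty_benchmark_zero_matrices(self):
        ds = BenchmarkDataset(drugs=["d1"], adrs=["s1"], interactions=set(), labels={})
        mats = build_interaction_matrices(ds)
        assert mats.r_interaction.sum() == 0 and mats.r_seriousness.sum() == 0

    def test_unmasked_profiles_reproduce_slices(self):
        mats = build_interaction_matrices(tiny_benchmark())
        row_int, row_ser, col_int, col_ser = extract_pair_profiles(
            mats, 0, 0, mask_target=False
        )
        assert (row_int == mats.r_interaction[0]).all()
        assert (col_ser == mats.r_seriousness[:, 0]).all()

    def test_masked_profile_zero_at_own_position(self):
        mats = build_interaction_matrices(tiny_benchmark())
        i, j = 0, 0  # (d1, s1) is known and serious
        row_int, row_ser, col_int, col_ser = extract_pair_profiles(
            mats, i, j, mask_target=True
        )
        assert row_int[j] == row_ser[j] == col_int[i] == col_ser[i] == 0

    def test_profile_sums_equal_degrees(self):
        ds = tiny_benchmark()
        mats = build_interaction_matrices(ds)
        for d, i in mats.drug_index.items():
            degree = sum(1 for (dd, _) in ds.interactions if dd == d)
            row_int, *_ = extract_pair_profiles(mats, i, 0, mask_target=False)
            assert row_int.sum() == degree

    def test_out_of_range_index_rejected(self):
        mats = build_interaction_matrices(tiny_benchmark())
        with pytest.raises(IndexError):
            extract_pair_profiles(mats, 99, 0)
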