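"""Glue from a labeled benchmark to per-pair model inputs.

A :class:`FeaturizationContext` pre-computes everything that is shared
across pairs — molecular graphs, SMILES one-hot matrices and their
vocabulary, semantic vectors and their vocabulary, and the interaction /
seriousness matrices — and then materializes :class:`~gcap.model.PairFeatures`
for any subset of pairs, optionally overriding the seriousness matrix (for
fold-wise evaluation) and masking each pair's own matrix entry so profiles
cannot leak the label under prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .featurize import (
    InteractionMatrixPair,
    MolecularGraph,
    SmilesVocabulary,
    build_interaction_matrices,
    build_semantic_dag,
    build_semantic_vocabulary,
    build_smiles_vocabulary,
    encode_semantic_vector,
    encode_smiles_matrix,
    smiles_to_graph,
    tokenize_smiles,
)
from .labeling import BenchmarkDataset, OUTCOME_CODES
from .model import GCAPModel, ModelConfig, PairFeatures


@dataclass
class FeaturizationContext:
    dataset: BenchmarkDataset
    pairs: list[tuple[str, str]]
    y_serious: np.ndarray                 # (P,)
    y_classes: np.ndarray                 # (P, 7)
    graphs: dict[str, MolecularGraph]
    onehots: dict[str, np.ndarray]
    smiles_vocab: SmilesVocabulary
    semantic_vectors: dict[str, np.ndarray]
    semantic_dim: int
    matrices: InteractionMatrixPair

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def features_for(
        self,
        pair_indices: np.ndarray | list[int],
        r_seriousness: np.ndarray | None = None,
        r_interaction: np.ndarray | None = None,
        mask_target: bool = True,
    ) -> list[PairFeatures]:
        """Build PairFeatures for the given pair indices.

        ``r_seriousness``/``r_interaction`` override the full-data matrices
        (e.g. training-fold matrices with held-out labels zeroed).
        """
        r_int = self.matrices.r_interaction if r_interaction is None else r_interaction
        r_ser = self.matrices.r_seriousness if r_seriousness is None else r_seriousness
        out = []
        for p in pair_indices:
            drug, adr = self.pairs[p]
            i = self.matrices.drug_index[drug]
            j = self.matrices.adr_index[adr]
            row_int = r_int[i].astype(np.float64).copy()
            row_ser = r_ser[i].astype(np.float64).copy()
            col_int = r_int[:, j].astype(np.float64).copy()
            col_ser = r_ser[:, j].astype(np.float64).copy()
            if mask_target:
                row_int[j] = row_ser[j] = 0.0
                col_int[i] = col_ser[i] = 0.0
            out.append(
                PairFeatures(
                    drug_id=drug,
                    adr_id=adr,
                    graph=self.graphs[drug],
                    smiles_onehot=self.onehots[drug],
                    drug_row_int=row_int,
                    drug_row_ser=row_ser,
                    adr_semantic=self.semantic_vectors[adr],
                    adr_col_int=col_int,
                    adr_col_ser=col_ser,
                )
            )
        return out

    def make_model(self, config: ModelConfig | None = None) -> GCAPModel:
        """A model sized for this benchmark's geometry."""
        any_graph = next(iter(self.graphs.values()))
        return GCAPModel(
            atom_width=any_graph.atom_features.shape[1],
            bond_width=any_graph.bond_features.shape[1] if any_graph.n_bonds else 6,
            smiles_vocab_size=self.smiles_vocab.size,
            n_drugs=len(self.dataset.drugs),
            n_adrs=len(self.dataset.adrs),
            semantic_dim=self.semantic_dim,
            config=config,
        )


def build_context(
    dataset: BenchmarkDataset,
    smiles_table: pd.DataFrame,
    hierarchy_table: pd.DataFrame,
    l_max: int = 100,
) -> FeaturizationContext:
    """Featurize a labeled benchmark once, for all downstream protocols."""
    smiles_map = dict(zip(smiles_table["drug"], smiles_table["smiles"]))
    hier_map = dict(zip(hierarchy_table["adr"], hierarchy_table["ids"]))

    vocab = build_smiles_vocabulary(smiles_map[d] for d in dataset.drugs)
    graphs, onehots = {}, {}
    for d in dataset.drugs:
        graphs[d] = smiles_to_graph(smiles_map[d], name=d)
        enc = encode_smiles_matrix(tokenize_smiles(smiles_map[d]), vocab, l_max=l_max)
        onehots[d] = enc.matrix.astype(np.float64)

    dags = {s: build_semantic_dag(s, hier_map[s]) for s in dataset.adrs}
    sem_vocab = build_semantic_vocabulary(dags.values())
    sem_vectors = {
        s: encode_semantic_vector(dag, sem_vocab).vector.astype(np.float64)
        for s, dag in dags.items()
    }

    matrices = build_interaction_matrices(dataset)
    pairs = sorted(dataset.interactions)
    y_serious = np.array(
        [float(dataset.labels[p].serious) for p in pairs], dtype=np.float64
    )
    y_classes = np.array(
        [dataset.labels[p].classes for p in pairs], dtype=np.float64
    )
    return FeaturizationContext(
        dataset=dataset,
        pairs=pairs,
        y_serious=y_serious,
        y_classes=y_classes,
        graphs=graphs,
        onehots=onehots,
        smiles_vocab=vocab,
        semantic_vectors=sem_vectors,
        semantic_dim=len(sem_vocab),
        matrices=matrices,
    )
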