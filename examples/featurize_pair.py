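"""Build the four model inputs for one (drug, ADR) pair.

Shows the SMILES tokenization and one-hot matrix, the molecular graph, the
ADR's semantic DAG and multi-hot vector, and the masked interaction
profiles that describe the pair's neighborhood in the benchmark.
"""

import numpy as np

from gcap.featurize import (
    build_semantic_dag,
    build_semantic_vocabulary,
    encode_semantic_vector,
    encode_smiles_matrix,
    build_smiles_vocabulary,
    smiles_to_graph,
    tokenize_smiles,
)
from gcap.pipeline import build_context
from gcap.synthetic import generate_block_benchmark

dataset, smiles_table, hierarchy_table = generate_block_benchmark(n_drugs=8, n_adrs=6)
context = build_context(dataset, smiles_table, hierarchy_table)

drug, adr = context.pairs[0]
smi = dict(zip(smiles_table["drug"], smiles_table["smiles"]))[drug]
print(f"pair: drug {drug} ({smi}) x ADR {adr}\n")

tokens = tokenize_smiles(smi)
print(f"SMILES tokens ({len(tokens)}): {tokens}")
enc = encode_smiles_matrix(tokens, context.smiles_vocab)
print(f"one-hot matrix: {enc.matrix.shape}, occupied rows: {int(enc.matrix.sum())}")

graph = smiles_to_graph(smi)
print(f"molecular graph: {graph.n_atoms} atoms (features {graph.atom_features.shape[1]}-dim), "
      f"{graph.n_bonds} bonds")

ids = dict(zip(hierarchy_table["adr"], hierarchy_table["ids"]))[adr]
dag = build_semantic_dag(adr, ids)
print(f"\nADR hierarchy IDs: {ids}")
print(f"semantic DAG: {dag.n_descriptors} descriptors: {sorted(dag.nodes)}")
vec = context.semantic_vectors[adr]
print(f"multi-hot vector: dim {len(vec)}, ones = {int(vec.sum())} "
      "(one per descriptor present in the dataset vocabulary)")

feats = context.features_for([0])[0]
print(f"\ndrug interaction profile (row of R_interaction, own entry masked): "
      f"{feats.drug_row_int.astype(int)}")
print(f"ADR seriousness profile  (col of R_seriousness, own entry masked): "
      f"{feats.adr_col_ser.astype(int)}")
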