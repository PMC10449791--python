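"""Interaction/seriousness profile matrices and per-pair profile vectors.

``R_interaction`` is the n x m binary matrix of known drug-ADR pairs;
``R_seriousness`` marks the subset labeled serious.  A drug's row and an
ADR's column in each matrix serve as its interaction profile features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..labeling import BenchmarkDataset


@dataclass
class InteractionMatrixPair:
    """The two n x m binary matrices plus their row/column orderings."""

    r_interaction: np.ndarray
    r_seriousness: np.ndarray
    drug_index: dict[str, int]
    adr_index: dict[str, int]

    def __post_init__(self) -> None:
        if self.r_interaction.shape != self.r_seriousness.shape:
            raise ValueError("matrix shapes differ")
        if np.any(self.r_seriousness > self.r_interaction):
            raise ValueError("a serious pair must be a known pair")


def build_interaction_matrices(dataset: BenchmarkDataset) -> InteractionMatrixPair:
    """Fill both matrices from the benchmark; all other entries are zero."""
    drug_index = {d: i for i, d in enumerate(dataset.drugs)}
    adr_index = {s: j for j, s in enumerate(dataset.adrs)}
    shape = (len(dataset.drugs), len(dataset.adrs))
    r_int = np.zeros(shape, dtype=np.int8)
    r_ser = np.zeros(shape, dtype=np.int8)
    for (d, s) in dataset.interactions:
        r_int[drug_index[d], adr_index[s]] = 1
    for (d, s), lab in dataset.labels.items():
        if lab.serious:
            r_ser[drug_index[d], adr_index[s]] = 1
    return InteractionMatrixPair(r_int, r_ser, drug_index, adr_index)


def extract_pair_profiles(
    matrices: InteractionMatrixPair,
    drug_index: int,
    adr_index: int,
    mask_target: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Profile vectors for one (drug, ADR) pair.

    Returns ``(drug_row_int, drug_row_ser, adr_col_int, adr_col_ser)``: row
    ``i`` of both matrices (length m) and column ``j`` (length n).  With
    ``mask_target`` the pair's own entry is zeroed in all four vectors so the
    profiles cannot leak the label being predicted (the evaluation default).
    """
    n, m = matrices.r_interaction.shape
    if not (0 <= drug_index < n and 0 <= adr_index < m):
        raise IndexError(f"pair index ({drug_index}, {adr_index}) out of range {n}x{m}")
    row_int = matrices.r_interaction[drug_index].astype(np.float64).copy()
    row_ser = matrices.r_seriousness[drug_index].astype(np.float64).copy()
    col_int = matrices.r_interaction[:, adr_index].astype(np.float64).copy()
    col_ser = matrices.r_seriousness[:, adr_index].astype(np.float64).copy()
    if mask_target:
        row_int[adr_index] = 0.0
        row_ser[adr_index] = 0.0
        col_int[drug_index] = 0.0
        col_ser[drug_index] = 0.0
    return row_int, row_ser, col_int, col_ser
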