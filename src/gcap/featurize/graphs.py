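"""Molecular graphs from SMILES via RDKit.

One node per heavy atom, one undirected bond entry per bond.  Initial atom
features are element one-hot, degree one-hot, formal charge, aromaticity and
hydrogen count; bond features are bond-type one-hot, conjugation and ring
membership.  Linear projection of both to a common width happens inside the
network's input layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # quiet parse warnings; failures still raise


@dataclass(frozen=True)
class AtomFeatureConfig:
    """Which chemistry features enter the initial atom/bond vectors."""

    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
    max_degree: int = 5
    max_hydrogens: int = 4

    @property
    def atom_width(self) -> int:
        # element one-hot (+other) + degree one-hot + charge + aromatic + H one-hot
        return (len(self.elements) + 1) + (self.max_degree + 1) + 1 + 1 + (self.max_hydrogens + 1)

    @property
    def bond_width(self) -> int:
        return 4 + 1 + 1  # bond-type one-hot + conjugated + in-ring


@dataclass
class MolecularGraph:
    """Structural view of one drug: atoms, bonds, and incidence maps.

    ``incidence[i]`` lists the indices into ``bonds`` of atom i's incident
    bonds; ``neighbors[i]`` the corresponding neighbor atom indices (aligned).
    """

    atom_features: np.ndarray          # (A, atom_width)
    bond_features: np.ndarray          # (B, bond_width)
    bonds: list[tuple[int, int]]
    incidence: list[list[int]] = field(default_factory=list)
    neighbors: list[list[int]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


def _one_hot(value: int, size: int) -> list[float]:
    v = [0.0] * size
    v[min(value, size - 1)] = 1.0
    return v


_BOND_TYPES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def smiles_to_graph(
    smiles: str, config: AtomFeatureConfig | None = None, name: str | None = None
) -> MolecularGraph:
    """Parse a SMILES string into a featurized molecular graph.

    Raises ``ValueError`` naming the drug when RDKit cannot parse the string.
    """
    config = config or AtomFeatureConfig()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {name or smiles!r}: {smiles!r}")

    elem_index = {e: i for i, e in enumerate(config.elements)}
    atom_rows = []
    for atom in mol.GetAtoms():
        elem = [0.0] * (len(config.elements) + 1)
        elem[elem_index.get(atom.GetSymbol(), len(config.elements))] = 1.0
        row = (
            elem
            + _one_hot(atom.GetDegree(), config.max_degree + 1)
            + [float(atom.GetFormalCharge())]
            + [float(atom.GetIsAromatic())]
            + _one_hot(atom.GetTotalNumHs(), config.max_hydrogens + 1)
        )
        atom_rows.append(row)

    bond_rows, bonds = [], []
    for bond in mol.GetBonds():
        row = _one_hot(_BOND_TYPES.get(bond.GetBondType(), 0), 4) + [
            float(bond.GetIsConjugated()),
            float(bond.IsInRing()),
        ]
        bond_rows.append(row)
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))

    n_atoms = mol.GetNumAtoms()
    incidence: list[list[int]] = [[] for _ in range(n_atoms)]
    neighbors: list[list[int]] = [[] for _ in range(n_atoms)]
    for b, (i, j) in enumerate(bonds):
        incidence[i].append(b)
        neighbors[i].append(j)
        incidence[j].append(b)
        neighbors[j].append(i)

    return MolecularGraph(
        atom_features=np.asarray(atom_rows, dtype=np.float64),
        bond_features=(
            np.asarray(bond_rows, dtype=np.float64)
            if bond_rows
            else np.zeros((0, config.bond_width))
        ),
        bonds=bonds,
        incidence=incidence,
        neighbors=neighbors,
    )
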