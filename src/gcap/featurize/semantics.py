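"""ADR semantic hierarchy descriptors as DAGs and multi-hot vectors.

Each ADR term carries one or more four-level dotted numeric IDs locating it
in the ADR hierarchy (e.g. ``"17.06.10.002; 11.02.01.013"``).  Every level
prefix of every ID is an ancestor descriptor; the full IDs all denote the
ADR itself, which enters the DAG once as the leaf.  The worked example above
therefore yields 3 + 3 ancestors + 1 leaf = 7 descriptors.  Vectors are
multi-hot over the dataset-wide descriptor vocabulary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

_ID_RE = re.compile(r"^\d+(\.\d+){0,3}$")


@dataclass(frozen=True)
class SemanticDAG:
    """Descriptor DAG of one ADR: ancestor prefixes plus the leaf term."""

    adr: str
    ids: tuple[str, ...]
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @property
    def n_descriptors(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class SemanticVector:
    """Multi-hot encoding of a DAG over an ordered descriptor vocabulary."""

    vector: np.ndarray
    vocabulary: tuple[str, ...]
    n_missing: int = 0


def build_semantic_dag(adr: str, id_string: str) -> SemanticDAG:
    """Build the descriptor DAG from a semicolon-separated ID string.

    Nodes are the union of all proper level-prefixes across IDs plus the ADR
    term itself as the single leaf; edges link each prefix to its one-level
    extension and each deepest prefix to the leaf.
    """
    ids = tuple(part.strip() for part in id_string.split(";") if part.strip())
    if not ids:
        raise ValueError(f"ADR {adr!r}: empty hierarchy ID string")
    nodes: set[str] = {adr}
    edges: set[tuple[str, str]] = set()
    for id_ in ids:
        if not _ID_RE.match(id_):
            raise ValueError(f"ADR {adr!r}: malformed hierarchy ID {id_!r}")
        levels = id_.split(".")
        prefixes = [".".join(levels[: k + 1]) for k in range(len(levels) - 1)]
        nodes.update(prefixes)
        for parent, child in zip(prefixes, prefixes[1:]):
            edges.add((parent, child))
        edges.add((prefixes[-1] if prefixes else adr, adr))
    edges.discard((adr, adr))
    return SemanticDAG(adr=adr, ids=ids, nodes=frozenset(nodes), edges=frozenset(edges))


def build_semantic_vocabulary(dags: Iterable[SemanticDAG]) -> tuple[str, ...]:
    """Sorted deduplicated union of descriptor labels over all DAGs."""
    vocab: set[str] = set()
    n = 0
    for dag in dags:
        vocab.update(dag.nodes)
        n += 1
    if n == 0:
        raise ValueError("need at least one DAG to build a vocabulary")
    return tuple(sorted(vocab))


def encode_semantic_vector(
    dag: SemanticDAG, vocabulary: Sequence[str]
) -> SemanticVector:
    """Multi-hot vector with ones exactly at the DAG's in-vocabulary nodes.

    Nodes absent from the vocabulary (an unseen ADR) are skipped and counted
    in ``n_missing``; an empty intersection warns.
    """
    index = {term: i for i, term in enumerate(vocabulary)}
    vec = np.zeros(len(vocabulary), dtype=np.int8)
    missing = 0
    for node in dag.nodes:
        i = index.get(node)
        if i is None:
            missing += 1
        else:
            vec[i] = 1
    if vec.sum() == 0:
        warnings.warn(
            f"ADR {dag.adr!r}: no descriptor overlaps the vocabulary", stacklevel=2
        )
    return SemanticVector(vector=vec, vocabulary=tuple(vocabulary), n_missing=missing)
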