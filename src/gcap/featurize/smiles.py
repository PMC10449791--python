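"""SMILES tokenization and one-hot encoding matrices.

A SMILES string is tokenized by greedy longest match over a fixed symbol
table: bracket atoms (``[nH]``), two-letter halogens (``Cl``, ``Br``),
``%nn`` ring closures, single-letter atoms, bonds, digits and parentheses
each become one token.  Tokens are then encoded as one-hot rows of an
``l_max x V`` matrix (default ``l_max = 100``), zero-padded below the token
count and truncated above it.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

UNKNOWN_TOKEN = "<unk>"

#: Default maximum sequence length: one-hot matrices have this many rows.
MAX_SMILES_LENGTH = 100

# Greedy longest-match token pattern.  Order matters: bracket atoms and
# %nn ring closures first, then two-letter halogens, then single symbols.
_TOKEN_RE = re.compile(
    r"(\[[^\]]*\]"          # bracket atom, e.g. [nH], [O-], [C@@H]
    r"|%\d{2}"              # two-digit ring closure
    r"|Cl|Br"               # two-letter organic-subset elements
    r"|[BCNOPSFI]"          # single-letter organic-subset elements
    r"|[bcnops]"            # aromatic atoms
    r"|[-=#:/\\.+*$~]"      # bonds, disconnection, charge-ish symbols
    r"|[().@]"              # branches, dot, chirality marker
    r"|\d)"                 # ring-closure digit
)


def tokenize_smiles(smiles: str) -> list[str]:
    """Deterministically split a SMILES string into tokens.

    Characters that match no table entry are emitted as :data:`UNKNOWN_TOKEN`
    with a warning, never a failure.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m:
            tokens.append(m.group(0))
            pos = m.end()
        else:
            warnings.warn(
                f"unparseable character {smiles[pos]!r} at position {pos}; "
                "emitting unknown token",
                stacklevel=2,
            )
            tokens.append(UNKNOWN_TOKEN)
            pos += 1
    return tokens


@dataclass(frozen=True)
class SmilesVocabulary:
    """Ordered token list with a reserved unknown token at index 0."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tokens[0] != UNKNOWN_TOKEN:
            raise ValueError("vocabulary must reserve index 0 for the unknown token")

    @property
    def size(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            return 0

    def indices(self, tokens: Sequence[str]) -> np.ndarray:
        lookup = {t: i for i, t in enumerate(self.tokens)}
        return np.array([lookup.get(t, 0) for t in tokens], dtype=np.int64)


def build_smiles_vocabulary(corpus: Iterable[str]) -> SmilesVocabulary:
    """Collect the token vocabulary of a training corpus (plus ``<unk>``)."""
    seen: set[str] = set()
    for smi in corpus:
        seen.update(tokenize_smiles(smi))
    seen.discard(UNKNOWN_TOKEN)
    return SmilesVocabulary(tokens=(UNKNOWN_TOKEN, *sorted(seen)))


@dataclass(frozen=True)
class SmilesEncodingMatrix:
    """``l_max x V`` binary one-hot matrix plus the pre-truncation length."""

    matrix: np.ndarray
    length: int

    def __post_init__(self) -> None:
        occupied = min(self.length, self.matrix.shape[0])
        row_sums = self.matrix.sum(axis=1)
        if not (row_sums[:occupied] == 1).all() or not (row_sums[occupied:] == 0).all():
            raise ValueError("occupied rows must be one-hot and padding rows zero")


def encode_smiles_matrix(
    tokens: Sequence[str],
    vocabulary: SmilesVocabulary,
    l_max: int = MAX_SMILES_LENGTH,
) -> SmilesEncodingMatrix:
    """One-hot encode a token sequence into an ``l_max x V`` matrix.

    A sequence of 20 tokens fills rows 1-20; rows 21..l_max stay zero.
    Sequences longer than ``l_max`` are truncated.  Out-of-vocabulary
    tokens light the reserved unknown column.
    """
    matrix = np.zeros((l_max, vocabulary.size), dtype=np.int8)
    if len(tokens) == 0:
        warnings.warn("empty token list; emitting an all-zero matrix", stacklevel=2)
        return SmilesEncodingMatrix(matrix=matrix, length=0)
    idx = vocabulary.indices(tokens)[:l_max]
    matrix[np.arange(len(idx)), idx] = 1
    return SmilesEncodingMatrix(matrix=matrix, length=len(tokens))
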