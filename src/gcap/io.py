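"""Delimited-table readers/writers shared by all stages.

Tables are TSV (default) or CSV by extension, with headers.  Loading
validates against a schema (required columns plus row-level checks); bad
rows go into a rejects report instead of failing the whole load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from .labeling import OUTCOME_CODES


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    row_check: Callable[[pd.Series], str | None] | None = None


def _nonempty(columns: tuple[str, ...]) -> Callable[[pd.Series], str | None]:
    def check(row: pd.Series) -> str | None:
        for c in columns:
            v = row[c]
            if pd.isna(v) or str(v).strip() == "":
                return f"empty {c}"
        return None

    return check


def _check_report(row: pd.Series) -> str | None:
    err = _nonempty(("report_id", "drug", "adr"))(row)
    if err:
        return err
    if row["outcome"] not in OUTCOME_CODES:
        return f"unknown outcome {row['outcome']!r}"
    return None


REPORTS_SCHEMA = TableSchema("reports", ("report_id", "drug", "adr", "outcome"), _check_report)
INTERACTIONS_SCHEMA = TableSchema("interactions", ("drug", "adr"), _nonempty(("drug", "adr")))
SMILES_SCHEMA = TableSchema("smiles", ("drug", "smiles"), _nonempty(("drug", "smiles")))
HIERARCHY_SCHEMA = TableSchema("hierarchy", ("adr", "ids"), _nonempty(("adr", "ids")))


@dataclass
class LoadResult:
    records: pd.DataFrame
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_table(path: str | Path, schema: TableSchema) -> LoadResult:
    """Read and validate one table; row failures collect into ``rejects``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValueError(f"{schema.name} table missing required column(s): {missing}")
    if schema.row_check is None:
        return LoadResult(records=df)
    reasons = df.apply(schema.row_check, axis=1)
    bad = reasons.notna()
    rejects = df[bad].copy()
    if bad.any():
        rejects["reason"] = reasons[bad]
    return LoadResult(records=df[~bad].reset_index(drop=True), rejects=rejects)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False)
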