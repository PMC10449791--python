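"""Seriousness labeling of drug-ADR interactions from spontaneous reports.

Spontaneous adverse-event reporting systems (FAERS-style) attach one of seven
treatment-outcome codes to each report: DEath (DE), Life-Threatening (LT),
HOspitalization (HO), DiSability (DS), Congenital Anomaly (CA), Required
Intervention (RI) and OTher (OT).  For a known drug-ADR interaction we ask,
outcome by outcome, whether that outcome is reported disproportionally often
for the pair relative to the background of all other reports.  The statistic
is the Proportional Reporting Rate (PRR)

    PRR = (N_pair_k / N_pair_+) / ((N_+,k - N_pair_k) / (N_+,+ - N_pair_+))

with a log-normal 95% confidence interval

    CI = exp(ln PRR +/- 1.96 * SE),
    SE = sqrt(1/N_pair_k - 1/N_pair_+ + 1/(N_+,k - N_pair_k) + 1/(N_+,+ - N_pair_+)).

An outcome is flagged significant when the lower 95% bound exceeds 1; the
interaction is "serious" when any outcome is significant, and its seriousness
class vector has one bit per significant outcome, ordered OT=1 ... DE=7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Seven FAERS treatment-outcome codes in class order OT=1 ... DE=7.
OUTCOME_CODES: tuple[str, ...] = ("OT", "RI", "CA", "DS", "HO", "LT", "DE")
OUTCOME_INDEX: dict[str, int] = {c: i for i, c in enumerate(OUTCOME_CODES)}

Z_95 = 1.96  # two-sided 95% normal quantile used by the CI


class UndefinedPRRError(ValueError):
    """Raised when a contingency configuration makes the PRR undefined.

    This is an explicit signal (zero numerator, empty background, ...) rather
    than a silently propagated NaN.
    """


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report row: primary suspect drug, ADR, outcome code."""

    report_id: str
    drug: str
    adr: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_INDEX:
            raise ValueError(
                f"unknown outcome code {self.outcome!r}; expected one of {OUTCOME_CODES}"
            )
        if not self.drug or not self.adr:
            raise ValueError("drug and adr must be non-empty")


@dataclass(frozen=True)
class ContingencyCounts:
    """The four report counts behind one (drug, ADR, outcome) PRR.

    n_pair_k   -- reports with this drug AND this ADR AND this outcome
    n_pair_all -- reports with this drug AND this ADR (any outcome)
    n_all_k    -- reports with this outcome (whole table)
    n_all_all  -- all reports
    """

    n_pair_k: int
    n_pair_all: int
    n_all_k: int
    n_all_all: int

    def __post_init__(self) -> None:
        a, b, c, d = self.n_pair_k, self.n_pair_all, self.n_all_k, self.n_all_all
        if min(a, b, c, d) < 0:
            raise ValueError("counts must be non-negative")
        if not (a <= b <= d and a <= c <= d):
            raise ValueError(
                f"inconsistent contingency counts ({a}, {b}, {c}, {d}): "
                "need n_pair_k <= n_pair_all <= n_all_all and "
                "n_pair_k <= n_all_k <= n_all_all"
            )


@dataclass(frozen=True)
class PRRResult:
    """PRR point estimate, SE of ln(PRR), 95% CI and the significance call."""

    prr: float
    se: float
    ci_low: float | None = None
    ci_high: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class SeriousnessLabel:
    """Binary serious flag plus the 7-class multi-hot vector (OT..DE order).

    ``provenance`` distinguishes a pair whose PRRs were computed and all came
    out non-significant (``"computed"``) from a pair that never appears in the
    report table at all (``"unreported"``).
    """

    serious: bool
    classes: tuple[int, ...]
    provenance: str = "computed"

    def __post_init__(self) -> None:
        if len(self.classes) != 7 or any(c not in (0, 1) for c in self.classes):
            raise ValueError("classes must be a 7-dim 0/1 vector")
        if self.serious != (sum(self.classes) >= 1):
            raise ValueError("serious flag must equal OR over the class bits")


@dataclass
class BenchmarkDataset:
    """Labeled drug-ADR interaction benchmark.

    drugs/adrs are deterministic (lexicographic) orderings; ``labels`` maps
    every retained (drug, adr) pair to its SeriousnessLabel.
    """

    drugs: list[str]
    adrs: list[str]
    interactions: set[tuple[str, str]]
    labels: dict[tuple[str, str], SeriousnessLabel]
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_adrs(self) -> int:
        return len(self.adrs)

    @property
    def n_serious(self) -> int:
        return sum(1 for lab in self.labels.values() if lab.serious)


def _as_dataframe(reports: Iterable[ReportRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(reports, pd.DataFrame):
        df = reports
        missing = {"drug", "adr", "outcome"} - set(df.columns)
        if missing:
            raise ValueError(f"report table missing columns: {sorted(missing)}")
        return df
    rows = [(r.report_id, r.drug, r.adr, r.outcome) for r in reports]
    return pd.DataFrame(rows, columns=["report_id", "drug", "adr", "outcome"])


def tabulate_contingency(
    reports: Iterable[ReportRecord] | pd.DataFrame,
    drug: str,
    adr: str,
    outcome: str,
) -> ContingencyCounts:
    """Count the 2x2-style cells for one (drug, ADR, outcome) triple.

    Counting is at report-record granularity: a record contributes to
    n_pair_k iff it carries this drug, this ADR and this outcome code.
    """
    if outcome not in OUTCOME_INDEX:
        raise ValueError(f"unknown outcome code {outcome!r}")
    df = _as_dataframe(reports)
    if len(df) == 0:
        raise ValueError("empty report set")
    pair_mask = (df["drug"] == drug) & (df["adr"] == adr)
    outcome_mask = df["outcome"] == outcome
    return ContingencyCounts(
        n_pair_k=int((pair_mask & outcome_mask).sum()),
        n_pair_all=int(pair_mask.sum()),
        n_all_k=int(outcome_mask.sum()),
        n_all_all=int(len(df)),
    )


def compute_prr(counts: ContingencyCounts) -> PRRResult:
    """Point estimate of the PRR and the standard error of its log.

    Raises :class:`UndefinedPRRError` for zero cells: a zero numerator,
    an unreported pair, or a background with no occurrences of the outcome.
    No continuity correction is applied.
    """
    a, b, c, d = counts.n_pair_k, counts.n_pair_all, counts.n_all_k, counts.n_all_all
    if b == 0:
        raise UndefinedPRRError("pair never reported (n_pair_all = 0)")
    if a == 0:
        raise UndefinedPRRError("zero numerator (n_pair_k = 0)")
    if d == b:
        raise UndefinedPRRError("no background reports (n_all_all = n_pair_all)")
    if c == a:
        raise UndefinedPRRError("outcome absent from background (n_all_k = n_pair_k)")
    prr = (a / b) / ((c - a) / (d - b))
    se = math.sqrt(1.0 / a - 1.0 / b + 1.0 / (c - a) + 1.0 / (d - b))
    return PRRResult(prr=prr, se=se)


def prr_confidence_interval(result: PRRResult) -> PRRResult:
    """Attach the 95% CI (exp(ln PRR +/- 1.96 SE)) and the significance call.

    Significance means the LOWER bound exceeds 1 — the standard
    pharmacovigilance signal criterion.
    """
    if not (result.prr > 0):
        raise ValueError("prr must be positive")
    if not math.isfinite(result.se):
        raise ValueError("standard error must be finite")
    log_prr = math.log(result.prr)
    ci_low = math.exp(log_prr - Z_95 * result.se)
    ci_high = math.exp(log_prr + Z_95 * result.se)
    return replace(result, ci_low=ci_low, ci_high=ci_high, significant=ci_low > 1.0)


def prr_with_ci(counts: ContingencyCounts) -> PRRResult:
    """Convenience composition of :func:`compute_prr` and the CI step."""
    return prr_confidence_interval(compute_prr(counts))


def _pair_outcome_counts(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, int]:
    """Pre-aggregate report counts: per (drug,adr,outcome), per outcome, total."""
    per_triple = (
        df.groupby(["drug", "adr", "outcome"], sort=False).size().rename("n").reset_index()
    )
    per_outcome = df.groupby("outcome", sort=False).size()
    return per_triple, per_outcome, len(df)


def assign_seriousness(
    reports: Iterable[ReportRecord] | pd.DataFrame,
    drug: str,
    adr: str,
    min_reports: int = 0,
) -> SeriousnessLabel:
    """Label one known interaction from the report table.

    For each of the seven outcomes the PRR is computed; class bit k is set iff
    the PRR is defined and its lower 95% bound exceeds 1 (optionally also
    requiring ``n_pair_k >= min_reports``).  A pair absent from the reports
    gets a zero vector with provenance ``"unreported"``.
    """
    df = _as_dataframe(reports)
    pair = df[(df["drug"] == drug) & (df["adr"] == adr)]
    if len(pair) == 0:
        return SeriousnessLabel(serious=False, classes=(0,) * 7, provenance="unreported")
    n_pair_all = len(pair)
    n_all_all = len(df)
    outcome_totals = df["outcome"].value_counts()
    pair_totals = pair["outcome"].value_counts()
    bits = []
    for code in OUTCOME_CODES:
        a = int(pair_totals.get(code, 0))
        c = int(outcome_totals.get(code, 0))
        bit = 0
        if a > 0 and a >= min_reports:
            try:
                res = prr_with_ci(
                    ContingencyCounts(a, n_pair_all, c, n_all_all)
                )
                bit = int(bool(res.significant))
            except UndefinedPRRError:
                bit = 0
        bits.append(bit)
    return SeriousnessLabel(serious=any(bits), classes=tuple(bits), provenance="computed")


def label_pairs(
    reports: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    min_reports: int = 0,
) -> dict[tuple[str, str], SeriousnessLabel]:
    """Vectorised :func:`assign_seriousness` over many pairs.

    Aggregates the report table once; per-pair results are identical to the
    one-pair path (asserted by the test suite).
    """
    per_triple, per_outcome, n_all_all = _pair_outcome_counts(reports)
    triple_n = {
        (r.drug, r.adr, r.outcome): int(r.n) for r in per_triple.itertuples(index=False)
    }
    pair_n: dict[tuple[str, str], int] = {}
    for (d, s, _), n in triple_n.items():
        pair_n[(d, s)] = pair_n.get((d, s), 0) + n
    outcome_n = {k: int(v) for k, v in per_outcome.items()}

    out: dict[tuple[str, str], SeriousnessLabel] = {}
    for pair in pairs:
        b = pair_n.get(pair, 0)
        if b == 0:
            out[pair] = SeriousnessLabel(False, (0,) * 7, provenance="unreported")
            continue
        bits = []
        for code in OUTCOME_CODES:
            a = triple_n.get((pair[0], pair[1], code), 0)
            c = outcome_n.get(code, 0)
            bit = 0
            if a > 0 and a >= min_reports:
                try:
                    res = prr_with_ci(ContingencyCounts(a, b, c, n_all_all))
                    bit = int(bool(res.significant))
                except UndefinedPRRError:
                    bit = 0
            bits.append(bit)
        out[pair] = SeriousnessLabel(any(bits), tuple(bits), provenance="computed")
    return out


def filter_adrs_by_degree(
    interactions: pd.DataFrame, min_drugs: int = 50
) -> pd.DataFrame:
    """Keep only ADRs with strictly more than ``min_drugs`` associated drugs."""
    degree = interactions.groupby("adr")["drug"].nunique()
    keep = set(degree[degree > min_drugs].index)
    return interactions[interactions["adr"].isin(keep)].reset_index(drop=True)


def build_benchmark(
    interaction_table: pd.DataFrame,
    reports: pd.DataFrame,
    smiles_table: pd.DataFrame | None = None,
    hierarchy_table: pd.DataFrame | None = None,
    min_drugs: int = 50,
    min_reports: int = 0,
    date_range: tuple[str, str] | None = None,
) -> BenchmarkDataset:
    """Assemble the labeled benchmark from the input tables.

    Pipeline: (optional) date-window filter on reports -> drop interactions
    with missing SMILES or hierarchy annotation into a rejects report (the
    annotation checks are skipped for a table passed as None) -> remove ADRs
    with <= min_drugs associated drugs -> PRR-label every retained
    interaction.  Drug/ADR orderings are lexicographic so matrix indices are
    reproducible across runs.
    """
    if date_range is not None:
        if "date" not in reports.columns:
            raise ValueError("date_range given but reports have no 'date' column")
        lo, hi = date_range
        reports = reports[(reports["date"] >= lo) & (reports["date"] <= hi)]

    inter = interaction_table[["drug", "adr"]].drop_duplicates()
    known_smiles = set(smiles_table["drug"]) if smiles_table is not None else None
    known_hier = set(hierarchy_table["adr"]) if hierarchy_table is not None else None

    reject_rows = []
    ok_mask = []
    for row in inter.itertuples(index=False):
        reasons = []
        if known_smiles is not None and row.drug not in known_smiles:
            reasons.append("missing SMILES")
        if known_hier is not None and row.adr not in known_hier:
            reasons.append("missing hierarchy entry")
        ok_mask.append(not reasons)
        if reasons:
            reject_rows.append((row.drug, row.adr, "; ".join(reasons)))
    inter = inter[np.asarray(ok_mask, dtype=bool)]
    rejects = pd.DataFrame(reject_rows, columns=["drug", "adr", "reason"])

    inter = filter_adrs_by_degree(inter, min_drugs=min_drugs)

    pairs = [(r.drug, r.adr) for r in inter.itertuples(index=False)]
    labels = label_pairs(reports, pairs, min_reports=min_reports)

    drugs = sorted({d for d, _ in pairs})
    adrs = sorted({s for _, s in pairs})
    return BenchmarkDataset(
        drugs=drugs,
        adrs=adrs,
        interactions=set(pairs),
        labels=labels,
        rejects=rejects,
    )


def labels_to_frame(dataset: BenchmarkDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export the benchmark as two tables.

    Returns ``(interactions, serious_classes)``: all pairs with the binary
    label, and the serious pairs with one column per seriousness class.
    """
    rows = [
        (d, s, int(lab.serious), lab.provenance)
        for (d, s), lab in sorted(dataset.labels.items())
    ]
    inter = pd.DataFrame(rows, columns=["drug", "adr", "serious", "provenance"])
    srows = [
        (d, s, *lab.classes)
        for (d, s), lab in sorted(dataset.labels.items())
        if lab.serious
    ]
    classes = pd.DataFrame(srows, columns=["drug", "adr", *OUTCOME_CODES])
    return inter, classes
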