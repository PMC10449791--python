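"""Synthetic input generation with known ground truth.

Emulates the four input tables — spontaneous reports, known interactions,
drug SMILES, ADR hierarchy IDs — so every pipeline stage is testable
offline.  Signals are planted multiplicatively: a planted
(drug, ADR, outcome, multiplier) triple scales that outcome's probability
for the pair's reports before renormalization, which keeps the expected PRR
analytically computable.  ``exact_counts`` allocates outcome counts
deterministically (largest-remainder rounding of the expected counts),
removing sampling noise entirely for exactness tests.

The default background outcome rates are FAERS-flavoured: most reports end
in the non-serious OT bucket or hospitalization, congenital anomalies are
rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labeling import (
    BenchmarkDataset,
    OUTCOME_CODES,
    OUTCOME_INDEX,
    SeriousnessLabel,
)

#: Background probabilities of the seven outcome codes (OT..DE order).
DEFAULT_OUTCOME_RATES: tuple[float, ...] = (0.45, 0.02, 0.01, 0.05, 0.25, 0.07, 0.15)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_drugs: int = 50
    n_adrs: int = 20
    n_reports: int = 20000
    background_outcome_rates: tuple[float, ...] = DEFAULT_OUTCOME_RATES
    planted_signals: tuple[tuple[str, str, str, float], ...] = ()
    hierarchy_shape: tuple[int, int] = (3, 3)  # (top-level roots, branching)
    interaction_density: float = 0.3
    pair_report_floor: int = 30
    exact_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        rates = np.asarray(self.background_outcome_rates)
        if len(rates) != 7 or not np.isclose(rates.sum(), 1.0):
            raise ValueError("background_outcome_rates must be a 7-dim simplex")
        if any(m < 1 for *_, m in self.planted_signals):
            raise ValueError("signal multipliers must be >= 1")


def drug_name(i: int) -> str:
    return f"D{i:04d}"


def adr_name(j: int) -> str:
    return f"ADR{j:04d}"


def generate_hierarchy(spec: SyntheticSpec) -> pd.DataFrame:
    """Four-level dotted IDs with zero-padded fixed-width components.

    Leaves enumerate a (roots x branching^3) grid.  Every fifth ADR gets a
    second ID from a different top-level root, exercising the DAG prefix
    union exactly like the two-ID worked example (3 + 3 ancestors + 1 leaf).
    """
    roots, branch = spec.hierarchy_shape
    if branch < 1 or roots < 1:
        raise ValueError("hierarchy shape components must be >= 1")
    leaves = [
        f"{a + 1:02d}.{b + 1:02d}.{c + 1:02d}.{d + 1:03d}"
        for a in range(roots)
        for b in range(branch)
        for c in range(branch)
        for d in range(branch)
    ]
    rows = []
    for j in range(spec.n_adrs):
        ids = leaves[j % len(leaves)]
        if j % 5 == 0 and roots > 1:
            # second ID under the next root: no shared prefix with the first
            alt = leaves[(j + len(leaves) // roots) % len(leaves)]
            if alt.split(".")[0] != ids.split(".")[0]:
                ids = f"{ids}; {alt}"
        rows.append((adr_name(j), ids))
    return pd.DataFrame(rows, columns=["adr", "ids"])


# SMILES template families; structure correlates with labels when the block
# benchmark assigns families by drug group.
_FAMILIES = (
    lambda k: "C" * (3 + k % 5) + "O",                  # alcohols / chains
    lambda k: "c1ccccc1" + "C" * (1 + k % 4),           # aromatics
    lambda k: "CC(Cl)" + "C" * (1 + k % 4) + "N",       # halogenated amines
    lambda k: "CO" + "CC" * (1 + k % 3) + "C(=O)O",     # ether acids
)


def generate_smiles_set(spec: SyntheticSpec, family_of: dict[str, int] | None = None) -> pd.DataFrame:
    """Valid SMILES from parameterized templates; all parseable by RDKit.

    ``family_of`` pins each drug to a template family (used when structure
    should correlate with planted labels); otherwise families cycle.
    """
    rows = []
    for i in range(spec.n_drugs):
        name = drug_name(i)
        fam = family_of.get(name, i % 4) if family_of else i % 4
        rows.append((name, _FAMILIES[fam % 4](i // 4)))
    return pd.DataFrame(rows, columns=["drug", "smiles"])


def generate_interactions(spec: SyntheticSpec) -> pd.DataFrame:
    """Random drug-ADR pairs at the configured density, plus planted pairs."""
    rng = np.random.default_rng(spec.seed)
    pairs = {
        (drug_name(i), adr_name(j))
        for i in range(spec.n_drugs)
        for j in range(spec.n_adrs)
        if rng.random() < spec.interaction_density
    }
    pairs.update((d, s) for d, s, *_ in spec.planted_signals)
    rows = sorted(pairs)
    return pd.DataFrame(rows, columns=["drug", "adr"])


def _pair_outcome_probs(
    spec: SyntheticSpec, pair: tuple[str, str]
) -> np.ndarray:
    """Background rates with planted multipliers applied and renormalized."""
    probs = np.asarray(spec.background_outcome_rates, dtype=float).copy()
    for d, s, outcome, mult in spec.planted_signals:
        if (d, s) == pair:
            probs[OUTCOME_INDEX[outcome]] *= mult
    total = probs.sum()
    if total > 1.0 + 1e-12 and not np.isclose(total, 1.0):
        probs = probs / total
    return probs / probs.sum()


def _largest_remainder(counts: float, probs: np.ndarray) -> np.ndarray:
    """Deterministic integer allocation of ``counts`` proportional to probs."""
    raw = probs * counts
    base = np.floor(raw).astype(int)
    rem = counts - base.sum()
    order = np.argsort(-(raw - base))
    base[order[: int(rem)]] += 1
    return base


def generate_reports(
    spec: SyntheticSpec, interactions: pd.DataFrame
) -> pd.DataFrame:
    """FAERS-style report rows (report_id, drug, adr, outcome).

    Every known pair receives at least ``pair_report_floor`` reports so the
    PRR is defined; remaining volume is spread uniformly.  Outcomes are
    multinomial draws from the pair's (possibly planted) outcome
    distribution, or deterministic expected counts with ``exact_counts``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pairs = [(r.drug, r.adr) for r in interactions.itertuples(index=False)]
    planted_pairs = {(d, s) for d, s, *_ in spec.planted_signals}
    missing = planted_pairs - set(pairs)
    if missing:
        raise ValueError(f"planted signals reference unknown pairs: {sorted(missing)}")

    floor_total = spec.pair_report_floor * len(pairs)
    if floor_total > spec.n_reports:
        raise ValueError(
            f"n_reports={spec.n_reports} cannot give {len(pairs)} pairs a floor "
            f"of {spec.pair_report_floor} reports each"
        )
    extra = spec.n_reports - floor_total
    if spec.exact_counts:
        extra_counts = _largest_remainder(extra, np.full(len(pairs), 1.0 / len(pairs)))
    else:
        extra_counts = rng.multinomial(extra, np.full(len(pairs), 1.0 / len(pairs)))
    pair_counts = spec.pair_report_floor + extra_counts

    rows = []
    rid = 0
    for pair, n_pair in zip(pairs, pair_counts):
        probs = _pair_outcome_probs(spec, pair)
        if spec.exact_counts:
            outcome_counts = _largest_remainder(int(n_pair), probs)
        else:
            outcome_counts = rng.multinomial(int(n_pair), probs)
        for k, c in enumerate(outcome_counts):
            for _ in range(int(c)):
                rows.append((f"R{rid:07d}", pair[0], pair[1], OUTCOME_CODES[k]))
                rid += 1
    df = pd.DataFrame(rows, columns=["report_id", "drug", "adr", "outcome"])
    # shuffle rows so report order carries no structure
    return df.sample(frac=1.0, random_state=spec.seed + 2).reset_index(drop=True)


def generate_tables(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All four input tables: reports, interactions, smiles, hierarchy."""
    interactions = generate_interactions(spec)
    reports = generate_reports(spec, interactions)
    smiles = generate_smiles_set(spec)
    hierarchy = generate_hierarchy(spec)
    return reports, interactions, smiles, hierarchy


def generate_block_benchmark(
    n_drugs: int = 24,
    n_adrs: int = 10,
    n_groups: int = 2,
    seed: int = 0,
    class_bits: tuple[int, ...] = (6, 4),  # DE for group 0, HO for group 1
) -> tuple[BenchmarkDataset, pd.DataFrame, pd.DataFrame]:
    """A labeled benchmark with planted learnable block structure.

    Drugs and ADRs are split into ``n_groups`` groups; every pair is a known
    interaction, and a pair is serious exactly when drug and ADR belong to
    the same group (a block pattern).  Serious pairs of group g carry class
    bit ``class_bits[g % len(class_bits)]``.  SMILES template families and
    hierarchy roots follow the groups, so molecular structure and ADR
    semantics correlate with the labels (cold-start signal); interaction
    profiles expose the block pattern directly.

    Returns ``(dataset, smiles_table, hierarchy_table)``.
    """
    drugs = [drug_name(i) for i in range(n_drugs)]
    adrs = [adr_name(j) for j in range(n_adrs)]
    d_group = {d: i % n_groups for i, d in enumerate(drugs)}
    a_group = {s: j % n_groups for j, s in enumerate(adrs)}

    interactions = {(d, s) for d in drugs for s in adrs}
    labels: dict[tuple[str, str], SeriousnessLabel] = {}
    for d in drugs:
        for s in adrs:
            if d_group[d] == a_group[s]:
                bits = [0] * 7
                bits[class_bits[d_group[d] % len(class_bits)]] = 1
                labels[(d, s)] = SeriousnessLabel(True, tuple(bits), provenance="synthetic")
            else:
                labels[(d, s)] = SeriousnessLabel(False, (0,) * 7, provenance="synthetic")

    dataset = BenchmarkDataset(
        drugs=sorted(drugs),
        adrs=sorted(adrs),
        interactions=interactions,
        labels=labels,
    )
    smiles = pd.DataFrame(
        [(d, _FAMILIES[d_group[d] % 4](i // n_groups)) for i, d in enumerate(drugs)],
        columns=["drug", "smiles"],
    )
    roots = max(n_groups, 2)
    hier_rows = []
    for j, s in enumerate(adrs):
        g = a_group[s] + 1
        hier_rows.append(
            (s, f"{g:02d}.{(j % 3) + 1:02d}.{(j % 2) + 1:02d}.{j + 1:03d}")
        )
    hierarchy = pd.DataFrame(hier_rows, columns=["adr", "ids"])
    return dataset, smiles, hierarchy
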