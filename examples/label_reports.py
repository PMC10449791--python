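"""Label drug-ADR interactions from spontaneous reports with PRR + 95% CI.

Simulates a small FAERS-style report table with one planted death (DE)
signal at 10x the background rate, labels every known pair, and prints the
per-outcome PRR for the planted pair.
"""

import numpy as np

from gcap.labeling import (
    ContingencyCounts,
    OUTCOME_CODES,
    UndefinedPRRError,
    build_benchmark,
    prr_with_ci,
)
from gcap.synthetic import SyntheticSpec, generate_tables

spec = SyntheticSpec(
    n_drugs=10,
    n_adrs=6,
    n_reports=8000,
    seed=7,
    planted_signals=(("D0001", "ADR0001", "DE", 10.0),),
)
reports, interactions, smiles, hierarchy = generate_tables(spec)
dataset = build_benchmark(interactions, reports, smiles, hierarchy, min_drugs=0)

print(f"{dataset.n_drugs} drugs x {dataset.n_adrs} ADRs, "
      f"{len(dataset.interactions)} known interactions, "
      f"{dataset.n_serious} labeled serious\n")

pair = ("D0001", "ADR0001")
sub = reports[(reports["drug"] == pair[0]) & (reports["adr"] == pair[1])]
print(f"planted pair {pair}: {len(sub)} reports; per-outcome PRR:")
outcome_totals = reports["outcome"].value_counts()
for code in OUTCOME_CODES:
    a = int((sub["outcome"] == code).sum())
    try:
        res = prr_with_ci(
            ContingencyCounts(a, len(sub), int(outcome_totals.get(code, 0)), len(reports))
        )
        flag = "SIGNAL" if res.significant else ""
        print(f"  {code}: PRR={res.prr:6.2f}  CI=[{res.ci_low:5.2f}, {res.ci_high:5.2f}] {flag}")
    except UndefinedPRRError:
        print(f"  {code}: undefined (zero cell)")

label = dataset.labels[pair]
print(f"\nlabel: serious={label.serious}, classes (OT..DE) = {label.classes}")
print("A PRR lower bound above 1 for an outcome marks the pair as causing")
print("that serious outcome class; DE should be the only bit set here.")
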