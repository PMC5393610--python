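#!/usr/bin/env python
"""Exact contingency tests on the published cohort count tables.

Medication-use changes (enrollment vs follow-up) within each group via the
2x2 Fisher exact test, the across-group heparin change pattern and the
stroke-history distribution via the Freeman-Halton r x c exact test.
Writes results/cohort_stats.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from thrombomet import fisher_exact_2x2, fisher_exact_rxc
from thrombomet.study_tables import MEDICATION_USE, STROKE_HISTORY, within_group_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

rows = []
for med in MEDICATION_USE:
    for group in MEDICATION_USE[med]:
        table = within_group_table(med, group)
        p = fisher_exact_2x2(table)
        rows.append({"comparison": f"{med} within {group}", "p": p})
        print(f"{med:10s} within {group:15s} "
              f"{table[0, 0]}/{table[0].sum()} -> {table[1, 0]}/{table[1].sum()}: "
              f"p = {p:.4f}")

heparin_change = np.array([[7, 2], [7, 2], [1, 13]])  # stopped vs unchanged
p = fisher_exact_rxc(heparin_change).p_value
rows.append({"comparison": "heparin change across groups", "p": p})
print(f"heparin change pattern across groups: p = {p:.4f}")

p = fisher_exact_rxc(STROKE_HISTORY).p_value
rows.append({"comparison": "history of stroke across groups", "p": p})
print(f"history of stroke across groups: p = {p:.4f}")

pd.DataFrame(rows).to_csv(RESULTS / "cohort_stats.csv", index=False)
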