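"""Published cohort count tables used as inputs to the exact tests.

These are the enrollment-vs-follow-up medication-use counts and baseline
categorical characteristics of the analyzed cohort (9 thrombotic MI, 9
non-thrombotic MI, 14 stable CAD subjects with paired samples).  They are
inputs, not results: the package recomputes the exact-test p-values from
them.
"""

from __future__ import annotations

import numpy as np

#: paired-subject group sizes (thrombotic, non_thrombotic, stable)
PAIRED_N = {"thrombotic": 9, "non_thrombotic": 9, "stable": 14}

#: medication use counts (n using, out of group n) at enrollment / follow-up
MEDICATION_USE = {
    "aspirin": {
        "thrombotic": (9, 9), "non_thrombotic": (9, 7), "stable": (14, 14),
    },
    "heparin": {
        "thrombotic": (7, 0), "non_thrombotic": (7, 0), "stable": (1, 0),
    },
    "statins": {
        "thrombotic": (4, 9), "non_thrombotic": (2, 5), "stable": (12, 11),
    },
    "warfarin": {
        "thrombotic": (0, 0), "non_thrombotic": (1, 3), "stable": (0, 0),
    },
}


def within_group_table(medication: str, group: str) -> np.ndarray:
    """(time point x use) 2 x 2 count table for one medication and group."""
    used_before, used_after = MEDICATION_USE[medication][group]
    n = PAIRED_N[group]
    return np.array([[used_before, n - used_before],
                     [used_after, n - used_after]])


#: baseline characteristic: history of stroke (yes, no) per group
STROKE_HISTORY = np.array([
    [0, 9],   # thrombotic
    [3, 6],   # non_thrombotic
    [0, 14],  # stable
])

#: the published candidate-panel size entering recursive feature elimination
N_CANDIDATES_T0 = 65
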