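"""Published reference inputs for the breast-cancer CTC cohorts this package models.

These are the printed study numbers used as *inputs* to worked examples and
cross-checks: the exposure-time calibration table measured on control cell
lines, per-patient CTC phenotype counts of the index patients, and the
patient-frequency counts behind the cohort comparisons.  Nothing here is a
computed output of this package.
"""

from __future__ import annotations

#: Exposure-time calibration measured on labelled control cells (500 cells per
#: class on the HepG2 positive-control line, plus three breast-cancer lines).
#: Per class: (range lo, range hi, median) on the step-5 exposure grid.
ALDH1_CALIBRATION_TABLE = {
    "HepG2": {"high": (5, 25, 15), "low": (30, 55, 45), "neg": (60, 90, 70)},
    "SKBR3": {"high": (10, 25, 15), "low": (35, 55, 45), "neg": (60, 90, 80)},
    "MCF7": {"high": (20, 25, 20), "low": (35, 55, 45), "neg": (60, 90, 75)},
    "MDA.MB.231": {"high": (15, 25, 20), "low": (30, 55, 45), "neg": (60, 100, 80)},
}

#: Cohort sizes and detected-patient counts: (patients, CTC-positive patients).
DETECTION = {"early": (80, 13), "metastatic": (50, 25)}

#: Pooled CTC totals over detected patients.
TOTAL_CTCS = {"early": 31, "metastatic": 91}

#: Index patients: per-patient CTC counts by phenotype
#: (high_nuc, high_cytneg, lowneg_nuc, lowneg_cytneg).
INDEX_PATIENTS = {
    "early": [
        (0, 0, 0, 3),
        (0, 0, 0, 5),
        (1, 0, 2, 0),
        (3, 1, 2, 0),
        (0, 6, 0, 0),
    ],
    "metastatic": [
        (2, 0, 0, 0),
        (10, 1, 0, 0),
        (1, 0, 1, 0),
        (1, 2, 0, 0),
        (5, 14, 0, 2),
        (0, 0, 0, 2),
        (3, 2, 6, 0),
    ],
}

#: Detected patients with any / exclusively CTCs of a category, as counts
#: (early out of 13, metastatic out of 25), reconstructed from the published
#: patient percentages.
PATIENTS_WITH_ANY = {
    "aldh1_high": (4, 20),
    "aldh1_lowneg": (12, 8),
    "twist_nuc": (4, 20),
    "twist_cytneg": (10, 10),
    "high_nuc": (2, 19),
    "high_cytneg": (3, 6),
    "lowneg_nuc": (4, 3),
    "lowneg_cytneg": (8, 5),
}
PATIENTS_EXCLUSIVE = {
    "aldh1_high": (2, 17),
    "aldh1_lowneg": (9, 5),
    "twist_nuc": (3, 16),
    "twist_cytneg": (9, 5),
    "high_nuc": (0, 14),
    "lowneg_cytneg": (7, 4),
}
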