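"""Published panel-selection statistics used as worked-example inputs.

These are the selection frequencies (percent of 1000 re-seeded CV-LASSO
models) and ensemble mean mda values reported for the GENFI CSF cohort,
for the affected-vs-unaffected and the age/pathology-filtered
PMC-vs-NC comparisons, together with the consensus thresholds used for
each.  They serve as fixed inputs to the consensus logic (the raw cohort
data are not public), not as outputs of this package.
"""

from __future__ import annotations

# protein -> (lasso % selected, mean mda)
AFFECTED_EVIDENCE = {
    "NEFM": (100.0, 28.1),
    "NPTX2": (71.6, 8.4),
    "VGF": (40.2, 9.2),
    "AQP4": (26.5, 11.3),
    "APOE4": (55.6, 0.8),
    "SEC63": (40.2, 3.1),
    "APOA1": (31.5, 4.2),
    "PTPRN2": (8.8, 8.2),
    "CTSS": (7.6, 9.4),
    "SERPINA3": (0.0, 12.8),
    "C4A/B": (0.0, 11.0),
    "AMPH": (0.0, 9.5),
    "SPP1": (0.0, 8.8),
    "CD14": (0.0, 8.5),
}
AFFECTED_THRESHOLDS = (20.0, 8.0)  # lasso % min, mda min

PMC_NC_EVIDENCE = {
    "GRN": (99.9, 23.4),
    "TARDBP": (85.8, -0.1),
    "KNG1": (82.2, 1.6),
    "HBEGF": (82.2, 1.5),
    "MBP": (0.0, 5.0),
    "CLSTN1": (0.0, 5.0),
}
PMC_NC_THRESHOLDS = (80.0, 5.0)

# sex (F, M) per group and the printed group order, for the demographic
# balance worked example
SEX_BY_GROUP = {"AMC": (20, 27), "PMC": (58, 40), "NC": (41, 35)}

# published cluster compositions (affected, unaffected) per cluster
CLUSTER_COMPOSITIONS = {1: (1, 1), 2: (25, 2), 3: (13, 171)}

# random-forest OOB confusion bookkeeping: correct / total per class
RF_OOB_CORRECT = {"affected": (34, 39), "unaffected": (160, 174)}
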