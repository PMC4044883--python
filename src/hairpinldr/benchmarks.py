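"""Published reference numbers for the human pre-miRNA benchmark.

The standard benchmark pairs 691 non-redundant human pre-microRNA
hairpins (positive class) against 8,494 RefSeq pseudo hairpins and 754
other non-coding RNAs (negative class), giving the ~1:13 imbalance that
motivates geometric-mean scoring.  The tables below hold the published
sensitivity/specificity/Gm triples (percent) of classifiers evaluated on
this benchmark, kept here so comparisons and metric sanity checks have a
single citable home.
"""

from __future__ import annotations

__all__ = [
    "N_POSITIVE",
    "N_PSEUDO_HAIRPINS",
    "N_OTHER_NCRNA",
    "N_NEGATIVE",
    "NCRNA_COMPOSITION",
    "METHOD_RESULTS",
    "LDR_EM_SELECTION_RESULTS",
    "LDR_EM_OPTIMIZED_RESULTS",
    "LDR_EM_MAPPING_RESULTS",
]

#: benchmark class sizes
N_POSITIVE = 691
N_PSEUDO_HAIRPINS = 8494
N_OTHER_NCRNA = 754
N_NEGATIVE = N_PSEUDO_HAIRPINS + N_OTHER_NCRNA

#: subcategory counts of the 754-sequence ncRNA negative set
NCRNA_COMPOSITION = {
    "snoRNA": 334,
    "tRNA": 327,
    "snRNA": 53,
    "YRNA": 32,
    "5S-rRNA": 5,
    "other": 3,
}

#: published (SE%, SP%, Gm%) of pre-miRNA classifiers on the benchmark
METHOD_RESULTS = {
    "Triplet-SVM": (93.30, 88.10, 90.66),
    "miRabela": (71.00, 97.00, 82.99),
    "miPred-34": (89.35, 93.21, 91.26),
    "miPred-29": (84.55, 97.97, 91.01),
    "microPred": (90.02, 98.28, 93.58),
    "LDR-EM-3": (88.13, 96.45, 92.20),
    "LDR-EM-7": (89.15, 96.84, 92.91),
}

#: the LDR + explicit-RBF-map classifier during feature selection
#: (default map parameters gamma = 1.5, m = n + 15), by subset size
LDR_EM_SELECTION_RESULTS = {
    2: (84.67, 95.43, 89.89),
    3: (85.53, 97.51, 91.32),
    4: (85.82, 93.59, 89.62),
    5: (84.23, 96.16, 90.00),
    6: (83.94, 97.13, 90.29),
    7: (86.54, 96.91, 91.58),
    8: (90.59, 91.24, 90.92),
    9: (86.83, 92.68, 89.71),
    10: (87.12, 93.18, 90.10),
    11: (87.84, 92.90, 90.33),
    12: (88.32, 92.10, 90.19),
}

#: after (gamma, m) grid optimization: subset size -> (gamma, m, SE%, SP%, Gm%)
LDR_EM_OPTIMIZED_RESULTS = {
    3: (4.00, 25, 88.13, 96.45, 92.20),
    7: (0.50, 20, 89.15, 96.84, 92.91),
}

#: mapping-function comparison on the best feature subset (SE%, SP%, Gm%)
LDR_EM_MAPPING_RESULTS = {
    "none": (69.17, 98.94, 82.72),
    "poly": (76.99, 96.98, 86.41),
    "rbf": (85.23, 92.90, 88.99),
}
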