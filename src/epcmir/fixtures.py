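"""Published reference models and cohort summary tables.

Read-only fixtures transcribed from the original study this pipeline
re-implements: the clinical diagnostic-index coefficients, the best
combined miRNA + clinical index, the cohort summary statistics by outcome
group (with the published p-values), and the published per-model operating
characteristics.  These are inputs, not outputs: the pipeline never tunes
toward them, but tests and examples evaluate them directly.
"""

from __future__ import annotations

import pandas as pd

from .clinical import LinearIndex

__all__ = [
    "CLINICAL_INDEX",
    "COMBINED_INDEX",
    "COMBINED_PROBES",
    "TABLE2_N0",
    "TABLE2_N1",
    "TABLE2_CONTINUOUS",
    "TABLE2_CATEGORICAL",
    "TABLE2_PRINTED_P",
    "TABLE2_SELECTED",
    "MODEL_PERFORMANCE",
]

#: published clinical diagnostic index (higher = non-deterioration-like)
CLINICAL_INDEX = LinearIndex(
    intercept=-7.819,
    coefficients={
        "Alb": 1.819,
        "CRP": 7.503e-2,
        "ps": 2.558e-3,
        "LDH": -1.237e-3,
        "Hb": 2.193e-1,
        "Neut": -7.428e-5,
    },
)

#: probes entering the published best combination model
COMBINED_PROBES = ("miR-486-5p", "miR-7846-3p", "miR-642b-3p",
                   "miR-4707-5p", "miR-3663-3p", "miR-4732-5p")

#: published best combined miRNA + clinical diagnostic index
COMBINED_INDEX = LinearIndex(
    intercept=-17.330,
    coefficients={
        "miR-486-5p": -1.814e-1,
        "miR-7846-3p": 3.245e-1,
        "miR-642b-3p": -6.517e-1,
        "miR-4707-5p": 4.123e-1,
        "miR-3663-3p": 1.120,
        "miR-4732-5p": -1.900e-1,
        "Alb": 1.693,
        "CRP": 1.084e-1,
        "ps": 3.319e-2,
        "LDH": -9.630e-4,
        "Hb": 1.824e-1,
        "Neut": -8.891e-5,
    },
)

#: outcome-group sizes: non-deterioration (>6 months) and early deterioration
TABLE2_N0 = 149
TABLE2_N1 = 29

#: printed group summaries: variable -> (mean0, sd0, mean1, sd1)
TABLE2_CONTINUOUS = {
    "Alb": (4.2, 0.4, 3.7, 0.6),
    "AST": (28.3, 36.1, 33.8, 30.8),
    "ALT": (32.9, 78.9, 27.1, 20.4),
    "ChE": (255.0, 89.3, 237.4, 105.0),
    "LDH": (241.7, 171.6, 408.4, 579.9),
    "T-Bil": (1.00, 2.3, 0.9, 1.0),
    "BUN": (13.8, 4.4, 14.9, 6.7),
    "Cre": (0.7, 0.2, 0.8, 0.2),
    "Na": (139.6, 2.9, 138.5, 5.0),
    "K": (4.2, 0.3, 4.2, 0.5),
    "Cl": (102.6, 3.3, 102.0, 4.3),
    "RBC": (437.7, 48.4, 417.5, 60.3),
    "Hb": (13.5, 1.6, 12.5, 1.9),
    "Plt": (25.4, 8.7, 24.3, 8.0),
    "CRP": (1.6, 2.8, 3.7, 5.6),
    "Neut": (5142.1, 2054.2, 6699.7, 5207.0),
    "Lymp": (1688.3, 532.1, 1534.5, 617.9),
}

#: printed category counts: variable -> rows (categories) x columns (groups)
TABLE2_CATEGORICAL = {
    "age_ge_65": [[70, 12], [79, 17]],
    "sex": [[96, 20], [53, 9]],
    "primary_site": [[12, 4], [8, 1], [6, 1], [5, 1], [95, 13], [0, 1], [23, 8]],
    "ps": [[83, 11], [63, 15], [3, 3]],
    "stage": [[11, 1], [31, 2], [107, 26]],
    "bmi_ge_22": [[74, 18], [75, 11]],
}

#: p-values as printed in the cohort summary table
TABLE2_PRINTED_P = {
    "age_ge_65": 0.580, "sex": 0.639, "primary_site": 0.137, "ps": 0.031,
    "stage": 0.127, "bmi_ge_22": 0.221, "Alb": 1e-4, "AST": 0.446,
    "ALT": 0.695, "ChE": 0.417, "LDH": 0.004, "T-Bil": 0.905, "BUN": 0.234,
    "Cre": 0.923, "Na": 0.099, "K": 0.716, "Cl": 0.383, "RBC": 0.051,
    "Hb": 0.004, "Plt": 0.533, "CRP": 0.002, "Neut": 0.007, "Lymp": 0.167,
}

#: variables marked significant (p < 0.05) in the published screen
TABLE2_SELECTED = frozenset({"ps", "Alb", "LDH", "Hb", "CRP", "Neut"})

#: published per-model AUC / sensitivity / specificity / PPV / NPV
MODEL_PERFORMANCE = pd.DataFrame(
    [
        ("Clin model", 0.741, 0.448, 0.973, 0.765, 0.901),
        ("miR-model-01", 0.764, 0.966, 0.604, 0.322, 0.989),
        ("miR-model-02", 0.765, 0.966, 0.591, 0.315, 0.989),
        ("miR-model-03", 0.735, 0.862, 0.557, 0.275, 0.954),
        ("miR-model-04", 0.735, 0.897, 0.584, 0.295, 0.967),
        ("miR-model-05", 0.735, 0.862, 0.611, 0.301, 0.958),
        ("miR-model-06", 0.765, 0.966, 0.624, 0.333, 0.989),
        ("miR-model-07", 0.730, 0.828, 0.664, 0.324, 0.952),
        ("miR-model-08", 0.736, 0.931, 0.557, 0.290, 0.976),
        ("miR-model-09", 0.769, 0.966, 0.617, 0.329, 0.989),
        ("miR-model-10", 0.742, 0.828, 0.611, 0.293, 0.948),
        ("Comb-model-01", 0.802, 0.828, 0.624, 0.300, 0.949),
        ("Comb-model-02", 0.802, 0.828, 0.624, 0.300, 0.949),
        ("Comb-model-03", 0.806, 0.862, 0.591, 0.291, 0.957),
        ("Comb-model-04", 0.797, 0.919, 0.517, 0.556, 0.907),
        ("Comb-model-05", 0.797, 0.919, 0.517, 0.556, 0.907),
        ("Comb-model-06", 0.800, 0.839, 0.621, 0.429, 0.919),
        ("Comb-model-07", 0.806, 1.000, 0.450, 0.261, 1.000),
        ("Comb-model-08", 0.799, 0.966, 0.477, 0.264, 0.986),
        ("Comb-model-09", 0.804, 0.793, 0.658, 0.311, 0.942),
        ("Comb-model-10", 0.806, 0.828, 0.617, 0.296, 0.948),
    ],
    columns=["model", "AUC", "sensitivity", "specificity", "PPV", "NPV"],
).set_index("model")
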