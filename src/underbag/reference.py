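"""Published summary statistics of the aortic-dissection screening cohort.

The cohort itself (802 AD in-patients vs 52,411 controls, 71 features) is
not publicly available; what is public are summary tables — 2x2 counts
and group summaries for representative features, per-feature logistic
coefficients, and fold-level sensitivity/specificity of the compared
models under seven-fold cross-validation. Those printed numbers are valid
*inputs* to this package's statistics and report arithmetic, and are
frozen here for the reproduction checks.
"""

from __future__ import annotations

from .featselect import ContingencyTable2x2, GroupSummary

# Cohort-level counts.
N_POS = 802
N_NEG = 52411
T_WEAK_LEARNERS = 65          # floor(52411 / 802)
LEFTOVER_MAJORITY = 281       # 52411 - 65 * 802

# Feature-set cardinalities from the two screens.
N_FS = 49
N_FL = 35
N_OVERLAP = 26
N_FSET = 58

# 2x2 counts for two binary indicators (cases exposed / unexposed,
# controls exposed / unexposed) with their published chi-square values.
CHEST_PAIN_TABLE = ContingencyTable2x2(a=206, b=N_POS - 206,
                                       c=9460, d=N_NEG - 9460)
CHEST_PAIN_CHI2 = 30.985
SEX_TABLE = ContingencyTable2x2(a=228, b=N_POS - 228,
                                c=22417, d=N_NEG - 22417)
SEX_CHI2 = 66.471

# Group summary for neutrophil count (NEUT) with the published pooled t.
NEUT_SUMMARY = GroupSummary(n1=N_POS, mean1=7.16, sd1=4.08,
                            n2=N_NEG, mean2=4.79, sd2=3.47)
NEUT_T = 19.12

# Published logistic coefficients (B) and odds ratios for two indicators.
CHEST_PAIN_B, CHEST_PAIN_OR = 0.643, 1.903
AORTIC_MURMUR_B, AORTIC_MURMUR_OR = 1.563, 4.774

# Per-fold Se/Sp of the weighted-SVM weight study (seven folds each),
# keyed by (w1, w2), with the published "Average" row.
WEIGHT_STUDY_FOLDS = {
    (1.0, 1.0): {
        "se": [0.772, 0.746, 0.781, 0.746, 0.772, 0.728, 0.771],
        "sp": [0.792, 0.807, 0.768, 0.790, 0.805, 0.795, 0.779],
    },
    (1.3, 1.0): {
        "se": [0.825, 0.754, 0.816, 0.781, 0.781, 0.763, 0.847],
        "sp": [0.746, 0.751, 0.727, 0.751, 0.756, 0.741, 0.727],
    },
    (1.6, 1.0): {
        "se": [0.842, 0.754, 0.860, 0.807, 0.798, 0.781, 0.873],
        "sp": [0.697, 0.691, 0.675, 0.696, 0.684, 0.687, 0.679],
    },
    (2.0, 1.0): {
        "se": [0.868, 0.789, 0.868, 0.816, 0.851, 0.833, 0.898],
        "sp": [0.653, 0.669, 0.644, 0.666, 0.646, 0.648, 0.642],
    },
}
WEIGHT_STUDY_AVERAGES = {
    (1.0, 1.0): {"se": 0.759, "sp": 0.791},
    (1.3, 1.0): {"se": 0.795, "sp": 0.734},
    (1.6, 1.0): {"se": 0.816, "sp": 0.687},
    (2.0, 1.0): {"se": 0.846, "sp": 0.653},
}

# Per-fold Se/Sp of the ensemble comparison and the single-learner
# comparison, with published "Average" rows (percent for the first table,
# proportions for the second, as printed).
ENSEMBLE_STUDY_FOLDS = {
    "AdaBoost": {
        "se": [0.736, 0.675, 0.772, 0.631, 0.754, 0.631, 0.711],
        "sp": [0.742, 0.759, 0.744, 0.765, 0.748, 0.762, 0.765],
    },
    "EasyEnsemble": {
        "se": [0.798, 0.737, 0.825, 0.702, 0.798, 0.781, 0.693],
        "sp": [0.802, 0.794, 0.793, 0.816, 0.803, 0.802, 0.818],
    },
    "Ensemble model": {
        "se": [0.816, 0.798, 0.842, 0.807, 0.860, 0.825, 0.847],
        "sp": [0.705, 0.733, 0.704, 0.724, 0.717, 0.730, 0.715],
    },
    "Random forest": {
        "se": [0.781, 0.737, 0.807, 0.693, 0.754, 0.728, 0.695],
        "sp": [0.791, 0.792, 0.775, 0.789, 0.821, 0.810, 0.810],
    },
}
ENSEMBLE_STUDY_AVERAGES_PCT = {
    "AdaBoost": {"se": 70.1, "sp": 75.5},
    "EasyEnsemble": {"se": 76.1, "sp": 80.4},
    "Ensemble model": {"se": 82.8, "sp": 71.9},
    "Random forest": {"se": 74.2, "sp": 79.8},
}

SINGLE_STUDY_FOLDS = {
    "Logistic regression": {
        "se": [0.789, 0.754, 0.798, 0.711, 0.789, 0.754, 0.788],
        "sp": [0.771, 0.786, 0.754, 0.783, 0.774, 0.774, 0.773],
    },
    "Decision tree": {
        "se": [0.702, 0.596, 0.684, 0.658, 0.702, 0.667, 0.644],
        "sp": [0.690, 0.660, 0.653, 0.680, 0.682, 0.667, 0.679],
    },
    "KNN": {
        "se": [0.728, 0.684, 0.711, 0.789, 0.772, 0.667, 0.720],
        "sp": [0.715, 0.709, 0.700, 0.693, 0.656, 0.679, 0.683],
    },
    "BP": {
        "se": [0.737, 0.754, 0.789, 0.746, 0.781, 0.711, 0.788],
        "sp": [0.760, 0.773, 0.736, 0.749, 0.765, 0.765, 0.737],
    },
}
SINGLE_STUDY_AVERAGES = {
    "Logistic regression": {"se": 0.769, "sp": 0.774},
    "Decision tree": {"se": 0.665, "sp": 0.673},
    "KNN": {"se": 0.724, "sp": 0.691},
    "BP": {"se": 0.758, "sp": 0.755},
}

# Published average cells that do NOT equal the mean of their published
# fold values under standard rounding; the reproduction checks exclude
# them. (fold-value means: 0.7427 vs 0.734; 0.762 vs 0.761; 0.7183 vs 0.719)
KNOWN_AVERAGE_INCONSISTENCIES = (
    ("weight_study", (1.3, 1.0), "sp"),
    ("ensemble_study", "EasyEnsemble", "se"),
    ("ensemble_study", "Ensemble model", "sp"),
)
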