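"""Published cross-validation results of this detection method, as packaged
reference data.

The method was originally evaluated on an intracranial EEG recording from a
single pediatric patient with Lennox-Gastaut syndrome (128 cortical grid
electrodes, 1600 Hz), segmented into 5-second epochs: 73 repeated-sharp
segments, 1,752 sharp-and-slow-wave (SSW) segments and 91,701 normal
segments.  Three feature sets were compared under 10-fold cross-validation:

* ``PR``     -- the 27 geometric/relational features of this package,
* ``WL``     -- the 40-value Morlet wavelet baseline,
* ``PR+WL``  -- both concatenated.

The tables below carry the per-iteration sensitivity/specificity columns,
per-iteration balanced accuracies, and the pooled confusion distribution (in
percent of each target class).  They let the metric arithmetic of
:func:`edwave.classification.accuracy_from_rates` and
:func:`edwave.classification.eq5_metrics` be exercised against independently
reported numbers, and give users context for the synthetic benchmarks.
"""

from __future__ import annotations

#: Segment counts per class in the reference recording.
CLASS_COUNTS = {"normal": 91701, "sharp": 73, "ssw": 1752}

METHODS = ("PR", "WL", "PR+WL")

# -- Binary: EDs versus normal segments (10 iterations). ---------------------
# In a binary problem the sensitivity of one class is the specificity of the
# other, so the two sensitivity columns fully determine the accuracy.
BINARY_ED_NORMAL = {
    "PR": {
        "sens_ed": [95.00, 93.92, 91.71, 91.67, 93.92, 96.11, 91.11, 95.03, 95.03, 96.67],
        "sens_normal": [93.85, 93.73, 93.67, 93.36, 93.13, 93.35, 93.23, 93.86, 93.46, 93.41],
        "selectivity": [93.87, 93.73, 93.63, 93.33, 93.15, 93.40, 93.19, 93.88, 93.49, 93.48],
        "accuracy": [94.42, 93.83, 92.69, 92.51, 93.53, 94.73, 92.17, 94.44, 94.24, 95.04],
        "accuracy_avg": 93.76,
        "accuracy_std": 1.00,
    },
    "WL": {
        "sens_ed": [94.44, 93.92, 92.82, 94.44, 95.58, 93.89, 92.78, 88.95, 91.16, 92.78],
        "sens_normal": [89.53, 89.24, 89.78, 88.91, 89.18, 89.41, 89.44, 89.86, 89.45, 89.43],
        "selectivity": [89.63, 89.33, 89.84, 89.02, 89.31, 89.50, 89.51, 89.84, 89.49, 89.50],
        "accuracy": [91.99, 91.58, 91.30, 91.68, 92.38, 91.65, 91.11, 89.41, 90.31, 91.11],
        "accuracy_avg": 91.25,
        "accuracy_std": 0.86,
    },
    "PR+WL": {
        "sens_ed": [87.22, 90.61, 85.64, 90.00, 90.06, 89.44, 87.22, 88.40, 87.29, 86.67],
        "sens_normal": [95.80, 95.65, 95.75, 95.49, 95.23, 95.74, 95.47, 95.87, 95.51, 96.13],
        "selectivity": [95.64, 95.55, 95.55, 95.38, 95.13, 95.61, 95.32, 95.72, 95.35, 95.95],
        "accuracy": [91.51, 93.13, 90.69, 92.74, 92.64, 92.59, 91.35, 92.13, 91.40, 91.40],
        "accuracy_avg": 91.96,
        "accuracy_std": 0.79,
    },
}

# -- Binary: repeated sharps versus SSW segments. ----------------------------
SHARP_VS_SSW = {
    "PR": {
        "sens_sharp": [100.00, 100.00, 83.33, 100.00, 85.71, 83.33, 83.33, 50.00, 28.57, 83.33],
        "sens_ssw": [69.54, 74.14, 74.86, 65.52, 75.29, 75.29, 74.71, 76.00, 77.01, 77.59],
        "selectivity": [70.56, 75.14, 75.14, 66.67, 75.69, 75.56, 75.00, 75.14, 75.14, 77.78],
        "accuracy": [84.77, 87.07, 79.10, 82.76, 80.50, 79.31, 79.02, 63.00, 52.79, 80.46],
        "accuracy_avg": 76.88,
        "accuracy_std": 10.62,
    },
    "WL": {
        "sens_sharp": [0.00, 85.71, 33.33, 83.33, 28.57, 83.33, 66.67, 66.67, 57.14, 66.67],
        "sens_ssw": [97.70, 86.21, 90.29, 95.98, 99.43, 87.93, 93.68, 86.29, 87.93, 93.10],
        "selectivity": [94.44, 86.19, 88.40, 95.56, 96.69, 87.78, 92.78, 85.64, 86.74, 92.22],
        "accuracy": [48.85, 85.96, 61.81, 89.66, 64.00, 85.63, 80.17, 76.48, 72.54, 79.89],
        "accuracy_avg": 74.50,
        "accuracy_std": 12.84,
    },
    "PR+WL": {
        "sens_sharp": [50.00, 100.00, 66.67, 100.00, 42.86, 66.67, 83.33, 50.00, 42.86, 100.00],
        "sens_ssw": [91.95, 90.23, 90.29, 84.48, 95.40, 86.78, 89.08, 94.29, 87.93, 90.23],
        "selectivity": [90.56, 90.61, 89.50, 85.00, 93.37, 86.11, 88.89, 92.82, 86.19, 90.56],
        "accuracy": [70.98, 95.11, 78.48, 92.24, 69.13, 76.72, 86.21, 72.14, 65.39, 95.11],
        "accuracy_avg": 80.15,
        "accuracy_std": 11.22,
    },
}

# -- Three-class (two-step) classification. ----------------------------------
THREE_CLASS = {
    "PR": {
        "sens_normal": [93.72, 93.79, 93.69, 93.39, 93.02, 93.27, 93.10, 93.94, 93.58, 93.39],
        "spec_normal": [95.00, 93.92, 92.82, 92.22, 93.92, 95.56, 91.67, 95.58, 94.48, 96.67],
        "sens_sharp": [100.00, 85.71, 83.33, 100.00, 57.14, 83.33, 66.67, 50.00, 14.29, 83.33],
        "spec_sharp": [95.69, 96.09, 96.28, 95.82, 96.12, 96.66, 96.00, 96.51, 96.83, 96.36],
        "sens_ssw": [68.97, 74.14, 72.00, 65.52, 73.56, 74.14, 72.99, 76.00, 74.71, 77.59],
        "spec_ssw": [97.62, 97.40, 97.08, 97.16, 96.57, 96.26, 96.81, 97.09, 96.37, 96.73],
        "selectivity": [93.26, 93.42, 93.27, 92.88, 92.63, 92.91, 92.71, 93.57, 93.17, 93.09],
        "accuracy": [91.83, 90.18, 89.20, 90.68, 85.06, 89.87, 86.20, 84.85, 78.38, 90.68],
        "avg": {
            "sens_normal": 93.49, "spec_normal": 94.18, "sens_sharp": 72.38,
            "spec_sharp": 96.24, "sens_ssw": 72.96, "spec_ssw": 96.91,
            "selectivity": 93.09, "accuracy": 87.69,
        },
        "accuracy_std": 4.11,
    },
    "WL": {
        "sens_normal": [88.79, 89.31, 90.05, 89.08, 89.03, 89.50, 89.50, 89.90, 89.58, 89.55],
        "spec_normal": [95.00, 93.37, 93.92, 94.44, 95.58, 93.33, 92.22, 90.06, 90.61, 94.44],
        "sens_sharp": [0.00, 57.14, 16.67, 33.33, 28.57, 50.00, 33.33, 33.33, 42.86, 33.33],
        "spec_sharp": [98.22, 96.00, 98.00, 97.61, 99.02, 97.00, 97.59, 96.99, 97.00, 97.93],
        "sens_ssw": [93.68, 82.76, 86.29, 92.53, 95.40, 82.18, 86.78, 79.43, 80.46, 89.66],
        "spec_ssw": [90.52, 93.17, 91.89, 91.45, 89.99, 92.32, 91.82, 92.73, 92.41, 91.53],
        "selectivity": [88.82, 89.17, 89.93, 89.11, 89.10, 89.34, 89.41, 89.67, 89.38, 89.52],
        "accuracy": [77.70, 85.29, 79.47, 83.07, 82.93, 84.06, 81.87, 80.41, 82.15, 82.74],
        "avg": {
            "sens_normal": 89.43, "spec_normal": 93.30, "sens_sharp": 32.86,
            "spec_sharp": 97.54, "sens_ssw": 86.92, "spec_ssw": 91.78,
            "selectivity": 89.35, "accuracy": 81.97,
        },
        "accuracy_std": 2.24,
    },
    "PR+WL": {
        "sens_normal": [96.04, 95.76, 95.65, 95.46, 95.14, 95.59, 95.23, 95.57, 95.52, 96.01],
        "spec_normal": [86.67, 91.16, 86.19, 91.11, 90.06, 91.11, 89.44, 88.40, 88.40, 87.78],
        "sens_sharp": [50.00, 100.00, 66.67, 100.00, 14.29, 66.67, 66.67, 50.00, 28.57, 66.67],
        "spec_sharp": [99.05, 98.92, 99.02, 98.80, 99.38, 99.14, 98.78, 99.14, 99.04, 98.95],
        "sens_ssw": [79.89, 82.18, 77.14, 77.59, 87.36, 80.46, 80.46, 84.00, 77.59, 80.46],
        "spec_ssw": [96.86, 96.70, 96.47, 96.44, 95.66, 96.25, 96.29, 96.34, 96.25, 96.93],
        "selectivity": [95.71, 95.51, 95.28, 95.13, 94.93, 95.29, 94.94, 95.33, 95.13, 95.70],
        "accuracy": [84.75, 94.12, 86.86, 93.23, 80.31, 88.20, 87.81, 85.58, 80.89, 87.80],
        "avg": {
            "sens_normal": 95.60, "spec_normal": 89.03, "sens_sharp": 60.95,
            "spec_sharp": 99.02, "sens_ssw": 80.71, "spec_ssw": 96.42,
            "selectivity": 95.30, "accuracy": 86.96,
        },
        "accuracy_std": 4.49,
    },
}

# -- Pooled confusion distribution over iterations (percent of target class).
# Rows: true class (normal, sharp, ssw); columns: predicted class, same order.
CONFUSION_PCT = {
    "PR": [
        [93.49, 3.43, 3.08],
        [7.94, 71.43, 20.63],
        [5.74, 21.30, 72.96],
    ],
    "WL": [
        [89.43, 2.38, 8.20],
        [25.40, 33.33, 41.27],
        [6.03, 7.06, 86.91],
    ],
    "PR+WL": [
        [95.60, 0.84, 3.56],
        [12.70, 60.32, 26.98],
        [10.91, 8.38, 80.71],
    ],
}


def pooled_confusion_counts(method: str = "PR"):
    """Absolute pooled confusion counts reconstructed from the percentage
    distribution and the per-class segment totals (rows: true normal, sharp,
    ssw)."""
    import numpy as np

    pct = np.asarray(CONFUSION_PCT[method], dtype=float)
    totals = np.array([CLASS_COUNTS["normal"], CLASS_COUNTS["sharp"], CLASS_COUNTS["ssw"]])
    return pct / 100.0 * totals[:, None]
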