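"""Bundled reference dataset for the AML/ATV transmission-FTIR assay.

These tables are the published reference measurements of the
amlodipine-besylate / atorvastatin-calcium carbonyl band-area method:
replicate calibration AUCs over 0.10-1.00% w/w, standard-addition
accuracy data, intermediate-precision and repeatability replicates,
tablet assay results for eight commercial strengths, and the summary
statistics of the FTIR vs HPLC method comparison. They drive the worked
examples and let the validation-report functions be exercised without an
instrument.

All loaders return fresh pandas DataFrames.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_calibration_table",
    "load_accuracy_table",
    "load_intermediate_precision_table",
    "load_repeatability_table",
    "load_assay_table",
    "load_method_comparison_table",
]

# level % w/w -> three replicate AUCs
_CALIBRATION = {
    "AML": {
        0.10: (1.47, 1.48, 1.48),
        0.20: (2.63, 2.42, 2.41),
        0.40: (4.74, 4.26, 4.01),
        0.50: (5.45, 5.48, 5.46),
        0.60: (6.84, 6.85, 6.62),
        0.80: (9.16, 9.10, 8.68),
        1.00: (10.54, 11.21, 10.85),
    },
    "ATV": {
        0.10: (2.42, 2.40, 2.40),
        0.20: (3.95, 3.63, 3.63),
        0.40: (7.16, 6.43, 5.90),
        0.50: (7.91, 7.93, 7.90),
        0.60: (9.64, 9.57, 9.46),
        0.80: (13.19, 12.87, 12.10),
        1.00: (15.43, 15.60, 15.71),
    },
}

# added % w/w -> (mean AUC of n=6, AUC SD, mean found % w/w)
_ACCURACY = {
    "AML": [(0.400, 4.56, 0.12, 0.400), (0.500, 5.54, 0.09, 0.493),
            (0.600, 6.78, 0.16, 0.609)],
    "ATV": [(0.400, 6.57, 0.15, 0.394), (0.500, 8.07, 0.16, 0.496),
            (0.600, 9.67, 0.14, 0.604)],
}

# (analyte, day, nominal % w/w, mean found % w/w, SD)
_INTERMEDIATE_PRECISION = [
    ("AML", 1, 0.400, 0.395, 0.004), ("AML", 1, 0.500, 0.502, 0.001),
    ("AML", 1, 0.600, 0.611, 0.003),
    ("AML", 2, 0.400, 0.405, 0.002), ("AML", 2, 0.500, 0.504, 0.005),
    ("AML", 2, 0.600, 0.598, 0.001),
    ("AML", 3, 0.400, 0.399, 0.004), ("AML", 3, 0.500, 0.498, 0.002),
    ("AML", 3, 0.600, 0.593, 0.002),
    ("ATV", 1, 0.400, 0.403, 0.001), ("ATV", 1, 0.500, 0.509, 0.003),
    ("ATV", 1, 0.600, 0.599, 0.002),
    ("ATV", 2, 0.400, 0.394, 0.004), ("ATV", 2, 0.500, 0.501, 0.003),
    ("ATV", 2, 0.600, 0.607, 0.001),
    ("ATV", 3, 0.400, 0.403, 0.002), ("ATV", 3, 0.500, 0.509, 0.005),
    ("ATV", 3, 0.600, 0.604, 0.003),
]

# analyte -> level label -> replicate AUCs
_REPEATABILITY = {
    "AML": {"0.4": (4.44, 4.49, 4.54), "0.5": (5.52, 5.66, 5.58),
            "0.6": (6.56, 6.62, 6.58)},
    "ATV": {"0.4": (6.58, 6.56, 6.67), "0.5": (8.21, 8.17, 8.24),
            "0.6": (9.53, 9.56, 9.61)},
}

# (sample, analyte, labeled mg/tab, found mg/tab, SD)
_ASSAY = [
    ("Sample 01", "AML", 5, 4.71, 0.076), ("Sample 01", "ATV", 10, 9.88, 0.131),
    ("Sample 02", "AML", 5, 4.77, 0.107), ("Sample 02", "ATV", 20, 20.04, 0.152),
    ("Sample 03", "AML", 5, 4.89, 0.111), ("Sample 03", "ATV", 40, 39.27, 0.351),
    ("Sample 04", "AML", 5, 5.03, 0.200), ("Sample 04", "ATV", 80, 79.63, 0.666),
    ("Sample 05", "AML", 10, 9.66, 0.106), ("Sample 05", "ATV", 10, 10.00, 0.305),
    ("Sample 06", "AML", 10, 9.84, 0.170), ("Sample 06", "ATV", 20, 19.74, 0.254),
    ("Sample 07", "AML", 10, 10.05, 0.436), ("Sample 07", "ATV", 40, 40.424, 0.557),
    ("Sample 08", "AML", 10, 9.99, 0.087), ("Sample 08", "ATV", 80, 80.57, 1.150),
]

# (formulation, analyte, FTIR mean recovery %, FTIR SD, HPLC mean, HPLC SD, n)
_METHOD_COMPARISON = [
    ("5/10", "AML", 100.31, 0.167, 99.69, 0.452, 5),
    ("5/10", "ATV", 100.12, 0.241, 101.24, 0.322, 5),
    ("5/20", "AML", 100.10, 0.341, 98.57, 0.676, 5),
    ("5/20", "ATV", 100.56, 0.311, 98.69, 0.530, 5),
    ("10/20", "AML", 99.83, 0.251, 100.19, 0.421, 5),
    ("10/20", "ATV", 99.43, 0.715, 100.77, 0.721, 5),
    ("10/40", "AML", 100.34, 0.111, 101.02, 0.237, 5),
    ("10/40", "ATV", 101.12, 0.122, 99.59, 0.150, 5),
]


def load_calibration_table(analyte: str) -> pd.DataFrame:
    """Replicate calibration AUCs: columns concentration, rep1..rep3."""
    data = _CALIBRATION[analyte]
    return pd.DataFrame(
        [(c, *reps) for c, reps in sorted(data.items())],
        columns=["concentration", "rep1", "rep2", "rep3"])


def load_accuracy_table(analyte: str) -> pd.DataFrame:
    """Standard-addition accuracy data (n=6 per level)."""
    return pd.DataFrame(_ACCURACY[analyte],
                        columns=["added", "auc_mean", "auc_sd", "found"])


def load_intermediate_precision_table() -> pd.DataFrame:
    """Found concentrations over three days at three levels, both analytes."""
    return pd.DataFrame(_INTERMEDIATE_PRECISION,
                        columns=["analyte", "day", "nominal", "found_mean", "sd"])


def load_repeatability_table(analyte: str) -> dict[str, tuple[float, ...]]:
    """Replicate AUCs at three levels (triplicate layout)."""
    return dict(_REPEATABILITY[analyte])


def load_assay_table() -> pd.DataFrame:
    """Tablet assay results across eight commercial strengths."""
    return pd.DataFrame(_ASSAY,
                        columns=["sample", "analyte", "labeled_mg", "found_mg", "sd"])


def load_method_comparison_table() -> pd.DataFrame:
    """FTIR vs HPLC recovery summaries for four formulations, both analytes."""
    return pd.DataFrame(_METHOD_COMPARISON,
                        columns=["formulation", "analyte", "ftir_mean", "ftir_sd",
                                 "hplc_mean", "hplc_sd", "n"])
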