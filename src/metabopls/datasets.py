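"""Worked-example data for the reporting layer.

`example_panel_table` freezes a published 22-metabolite plasma panel for
predicting six-month serum creatinine > 1.5 mg/dL after kidney
transplantation: standardized PLS-DA coefficients with jackknife p-values
and 95% confidence intervals, plus the compounds' formulas, m/z, retention
times and adducts. `example_confusion_counts` carries the matching
LOOCV confusion matrix (n = 48 patients). Both serve as fixtures for the
significance-partition and metric computations, not as fitted output of
this package.
"""

from __future__ import annotations

import pandas as pd

from .validation import CoefficientTable

_PANEL = [
    # compound, formula, mz, rt, adduct, coefficient, p, ci_lo, ci_hi
    ("3-Methylindole (Skatole)", "C9H9N", 132.080765, 3.460, "[M+H]+", -0.16695299, 0.012, -0.29594, -0.03795),
    ("Guaiacol", "C7H8O2", 125.059898, 2.811, "[M+H]+", -0.15992134, 0.040, -0.31206, -0.00777),
    ("Homocarnosine", "C10H16N4O3", 241.129028, 13.951, "[M+H]+", 0.15774800, 0.010, 0.03892, 0.27657),
    ("5-Methylcytosine", "C5H7N3O", 126.066383, 8.141, "[M+H]+", 0.15492272, 0.023, 0.02254, 0.28729),
    ("Histidine", "C6H9N3O2", 156.076614, 13.985, "[M+H]+", -0.14781219, 0.002, -0.23791, -0.05770),
    ("Xanthosine", "C10H12N4O6", 283.068512, 8.486, "[M-H]-", 0.14141625, 0.029, 0.01564, 0.26718),
    ("Choline", "C5H13NO", 104.107384, 15.016, "[M+H]+", 0.13956783, 0.028, 0.01596, 0.26317),
    ("Glutathione disulfide", "C20H32N6O12S2", 613.161499, 13.655, "[M+H]+", 0.12867136, 0.065, -0.00778, 0.26512),
    ("3-Indolepropionic acid", "C11H11NO2", 188.071854, 2.661, "[M-H]-", -0.12850942, 0.001, -0.19942, -0.05759),
    ("Nicotinate", "C6H5NO2", 124.039261, 8.114, "[M+H]+", 0.12825902, 0.074, -0.01247, 0.26899),
    ("alpha-Lipoic acid", "C8H14O2S2", 207.051132, 2.506, "[M+H]+", -0.12588711, 0.047, -0.25017, -0.00160),
    ("Phenylalanine", "C9H11NO2", 166.086014, 8.604, "[M+H]+", 0.11587927, 0.041, 0.00471, 0.22704),
    ("Kynurenic acid", "C10H7NO3", 188.035202, 4.198, "[M-H]-", 0.11255399, 0.039, 0.00591, 0.21918),
    ("L-Kynurenine", "C10H12N2O3", 209.091873, 8.843, "[M+H]+", 0.11071323, 0.020, 0.01812, 0.20330),
    ("Urocanic acid", "C6H6N2O2", 139.050247, 7.991, "[M+H]+", 0.10565113, 0.233, -0.06970, 0.28100),
    ("N-Butyrylglycine", "C6H11NO3", 146.081177, 7.097, "[M+H]+", 0.10469998, 0.061, -0.00492, 0.21432),
    ("Indole-3-lactic acid", "C11H11NO3", 204.066437, 2.615, "[M-H]-", 0.10158428, 0.097, -0.01908, 0.22225),
    ("4-Aminohippuric acid", "C9H10N2O3", 195.076187, 5.703, "[M+H]+", 0.10137408, 0.081, -0.01293, 0.21568),
    ("Indole-3-ethanol", "C10H11NO", 162.091446, 2.668, "[M+H]+", -0.09839586, 0.137, -0.22901, 0.03222),
    ("Adenine", "C5H5N5", 134.047058, 7.545, "[M-H]-", -0.03343797, 0.339, -0.10300, 0.03612),
    # the panel lists an unresolved isomer pair sharing m/z, Rt and statistics;
    # both entries are reproduced as printed.
    ("Adenosine", "C10H13N5O4", 268.104065, 7.390, "[M+H]+", -0.02616427, 0.308, -0.07729, 0.02496),
    ("Deoxyguanosine", "C10H13N5O4", 268.104065, 7.390, "[M+H]+", -0.02616427, 0.308, -0.07729, 0.02496),
]


def example_panel_annotations() -> pd.DataFrame:
    """Compound annotations (formula, m/z, Rt, adduct) of the example panel."""
    df = pd.DataFrame(
        _PANEL,
        columns=[
            "compound", "formula", "mz", "rt", "adduct",
            "coefficient", "p_value", "ci_lower", "ci_upper",
        ],
    ).set_index("compound")
    return df[["formula", "mz", "rt", "adduct"]]


def example_panel_table(alpha: float = 0.05) -> CoefficientTable:
    """The example panel as a :class:`CoefficientTable` fixture.

    The published table prints a single standardized coefficient per
    compound; it is entered both as the point coefficient and as the
    jackknife mean, with the SE back-computed from the CI half-width.
    """
    df = pd.DataFrame(
        _PANEL,
        columns=[
            "compound", "formula", "mz", "rt", "adduct",
            "coefficient", "p_value", "ci_lower", "ci_upper",
        ],
    ).set_index("compound")
    from scipy import stats

    n = 48  # study samples behind the panel
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    frame = pd.DataFrame(
        {
            "coefficient": df["coefficient"],
            "jackknife_mean": df["coefficient"],
            "jackknife_se": (df["ci_upper"] - df["ci_lower"]) / (2 * tcrit),
            "ci_lower": df["ci_lower"],
            "ci_upper": df["ci_upper"],
            "p_value": df["p_value"],
            "significant": df["p_value"] < alpha,
        }
    )
    frame.index.name = "feature_id"
    return CoefficientTable(frame, alpha=alpha, n_components=2)


def example_confusion_counts() -> dict:
    """LOOCV confusion counts of the example panel's final model (n = 48)."""
    return {"tp": 19, "tn": 23, "fp": 3, "fn": 3}
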