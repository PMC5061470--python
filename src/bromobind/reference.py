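"""Published ITC reference panel: bromosporine against human bromodomains.

Reverse titrations (protein in the syringe at [P] uM, compound in the cell
at [L] uM) at 15 C.  Columns: fitted stoichiometry N, dissociation constant
K_D (nM), observed binding enthalpy dH (kcal/mol), and the derived entropy
term TdS and free energy dG (kcal/mol).  Four domains gave no reliable
single-site fit and are flagged weak.  These printed values anchor the
thermodynamic-consistency checks (dG = dH - TdS = RT ln K_D at 288.15 K).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["bsp_itc_panel", "REFERENCE_TEMPERATURE_C"]

#: Panel measurement temperature (degC).
REFERENCE_TEMPERATURE_C = 15.0

# protein, [P] uM, [L] uM, KD nM, KD sd, dH, dH sd, N, N sd, TdS, dG
_ROWS = [
    ("BAZ2A", 433, 15, 3745.0, 291.0, -3.04, 0.095, 1.05, 0.025, 4.12, -7.16),
    ("BAZ2B", 607, 15, None, None, None, None, None, None, None, None),
    ("BRD1", 440, 13, 1653.0, 66.0, -7.32, 0.078, 1.01, 0.008, 0.30, -7.62),
    ("BRD2(1)", 271, 25, 97.1, 6.7, -7.90, 0.034, 1.00, 0.003, 1.34, -9.25),
    ("BRD2(2)", 235, 25, 50.3, 5.0, -5.46, 0.028, 1.10, 0.003, 4.18, -9.64),
    ("BRD3(1)", 275, 20, 91.7, 5.3, -10.02, 0.039, 1.00, 0.002, -0.95, -9.08),
    ("BRD3(2)", 305, 25, 50.0, 4.7, -8.62, 0.041, 1.11, 0.003, 1.01, -9.63),
    ("BRD4(1)", 258, 20, 41.8, 2.8, -11.09, 0.038, 0.94, 0.002, -1.36, -9.73),
    ("BRD4(2)", 270, 20, 39.7, 2.2, -6.60, 0.018, 0.94, 0.001, 3.17, -9.77),
    ("BRDT(1)", 228, 20, 40.2, 2.8, -13.16, 0.047, 1.02, 0.002, -3.40, -9.76),
    ("BRDT(2)", 271, 20, 172.1, 10.6, -5.61, 0.028, 1.00, 0.003, 3.31, -8.92),
    ("BRD9", 251, 25, 41.7, 3.8, -8.75, 0.039, 1.00, 0.002, 0.98, -9.73),
    ("BRPF1B", 406, 20, 311.5, 11.2, -6.12, 0.021, 1.00, 0.003, 2.45, -8.57),
    ("BRPF3", 400, 15, 8621.0, 381.0, -4.20, 0.123, 1.08, 0.025, 2.48, -6.68),
    ("CECR2", 202, 16, 8.0, 1.0, -17.28, 0.062, 1.04, 0.002, -6.60, -10.68),
    ("CREBBP", 617, 25, 1524.0, 116.0, -2.91, 0.041, 1.03, 0.011, 4.72, -7.64),
    ("EP300", 460, 15, 7194.0, 501.0, -5.65, 0.265, 0.97, 0.036, 1.13, -6.78),
    ("BPTF", 230, 15, 1887.0, 53.0, -10.09, 0.074, 1.07, 0.005, -3.28, -6.80),
    ("GCN5L2", 336, 15, None, None, None, None, None, None, None, None),
    ("PB1(3)", 389, 15, None, None, None, None, None, None, None, None),
    ("PB1(5)", 604, 15, 14225.0, 802.0, -3.19, 0.183, 1.09, 0.053, 3.20, -6.39),
    ("PCAF", 610, 13, 4762.0, 459.0, -7.85, 0.454, 0.95, 0.044, -0.83, -7.02),
    ("SMARCA2", 222, 25, None, None, None, None, None, None, None, None),
    ("SMARCA4", 400, 13, 19685.0, 838.0, -9.05, 0.580, 0.99, 0.055, -2.84, -6.21),
    ("TAF1(1)", 460, 23, 5525.0, 199.0, -3.34, 0.046, 0.98, 0.010, 3.60, -6.94),
    ("TAF1(2)", 230, 20, 16.6, 2.7, -14.05, 0.095, 0.98, 0.003, -3.80, -10.25),
    ("TAF1L(1)", 610, 13, 25000.0, 2027.0, -4.78, 0.778, 1.00, 0.146, 1.29, -6.07),
    ("TAF1L(2)", 250, 20, 42.7, 4.4, -12.48, 0.069, 0.99, 0.003, -2.76, -9.72),
    ("TIF1A", 400, 15, 8475.0, 431.0, -2.61, 0.088, 1.09, 0.029, 4.06, -6.67),
]

_COLUMNS = [
    "protein", "p_uM", "l_uM", "kd_nM", "kd_sd_nM",
    "dh_kcal_mol", "dh_sd_kcal_mol", "n", "n_sd", "tds_kcal_mol", "dg_kcal_mol",
]


def bsp_itc_panel(include_weak: bool = True) -> pd.DataFrame:
    """The bromosporine/bromodomain ITC panel as a DataFrame.

    Weak-binding rows carry NaN thermodynamics and ``weak_binding=True``.
    """
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    df["weak_binding"] = df["kd_nM"].isna()
    if not include_weak:
        df = df[~df["weak_binding"]].reset_index(drop=True)
    return df
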