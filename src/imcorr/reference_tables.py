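"""Reported summary tables from the rabbit carotid-ligation study.

These are the published per-gene results of the original intima-media
screen: the 49 extracellular-product intimal DEGs with their log2 fold
changes and q-values at the bifurcation (BT) and straight vessel (BA), the
18 highly correlated candidates with their medial-correlate tallies, and
the study-wide correlated-pair totals.  They serve as fixed inputs for
internal-consistency checks (filter arithmetic, count identities) and are
not produced by this package's statistics.
"""

from __future__ import annotations

import pandas as pd

#: Study-wide counts of significantly correlated intima-media gene pairs.
PAIR_COUNTS = {"positive": 14_286, "negative": 15_491}

# gene, product_class, bif_log2fc, bif_q, straight_log2fc, straight_q, direction
_EXTRACELLULAR_DEGS = [
    ("CHI3L2", "enzyme", 11.88, 0.0469, 0.00, 1.0000, "up"),
    ("SERPINA6", "other", 10.72, 0.0084, 5.06, 0.4320, "up"),
    ("HBEGF", "growth factor", 4.80, 0.0014, 1.08, 1.0000, "up"),
    ("TIMP1", "cytokine", 4.52, 0.0000, 3.74, 0.0000, "up"),
    ("ADAMTS9", "peptidase", 4.08, 0.0013, 2.70, 0.1782, "up"),
    ("SERPINE1", "other", 3.91, 0.0000, 2.49, 0.0216, "up"),
    ("SEMA3F", "other", 3.39, 0.0022, 2.12, 0.3327, "up"),
    ("BMP2", "growth factor", 3.35, 0.0497, 0.34, 1.0000, "up"),
    ("IL15", "cytokine", 3.11, 0.0142, 1.79, 0.6464, "up"),
    ("PLAT", "peptidase", 2.77, 0.0261, 1.35, 0.8802, "up"),
    ("ADAMTS6", "peptidase", 2.63, 0.0456, 1.74, 0.6622, "up"),
    ("GLIPR1", "other", 1.06, 0.5043, 2.42, 0.0340, "up"),
    ("PTN", "growth factor", -17.17, 0.0000, -7.86, 0.2483, "down"),
    ("PROS1", "other", -14.76, 0.0019, -1.58, 1.0000, "down"),
    ("MFAP5", "other", -12.86, 0.0030, -9.54, 0.1498, "down"),
    ("VIT", "other", -12.80, 0.0030, 1.44, 1.0000, "down"),
    ("CST6", "other", -12.76, 0.0107, -8.97, 0.3702, "down"),
    ("C1QA", "other", -12.48, 0.0186, -0.78, 1.0000, "down"),
    ("TTR", "transporter", -12.18, 0.0275, -7.27, 0.7186, "down"),
    ("C2", "peptidase", -11.60, 0.0265, -2.14, 1.0000, "down"),
    ("CXCL10", "cytokine", -11.55, 0.0027, 3.42, 0.7338, "down"),
    ("NID2", "other", -10.86, 0.0056, -0.75, 1.0000, "down"),
    ("C1QTNF7", "other", -10.64, 0.0007, -8.63, 0.0029, "down"),
    ("CXCL11", "cytokine", -10.15, 0.0322, -0.88, 1.0000, "down"),
    ("BMP3", "growth factor", -9.57, 0.0045, -0.12, 1.0000, "down"),
    ("HP", "peptidase", -9.10, 0.0080, -1.54, 1.0000, "down"),
    ("C1QC", "other", -8.76, 0.0056, -1.71, 1.0000, "down"),
    ("ITIH2", "other", -8.61, 0.0206, 1.24, 1.0000, "down"),
    ("IGF1", "growth factor", -8.54, 0.0339, 0.80, 1.0000, "down"),
    ("PLA2G7", "enzyme", -8.30, 0.0112, -3.68, 0.7504, "down"),
    ("LYPD6", "other", -7.78, 0.0182, -9.65, 0.0609, "down"),
    ("RSPO3", "kinase", -6.86, 0.0664, 5.41, 0.9693, "down"),
    ("ANGPTL4", "other", -6.76, 0.0253, -2.53, 0.9693, "down"),
    ("NDP", "growth factor", -6.71, 0.0583, -10.76, 0.0216, "down"),
    ("SPP1", "cytokine", -5.39, 0.0004, -4.13, 0.0216, "down"),
    ("IGFBP2", "other", -5.12, 0.0286, -2.92, 0.6982, "down"),
    ("OGN", "growth factor", -4.91, 0.0000, -2.19, 0.3549, "down"),
    ("SERPINF1", "other", -4.70, 0.0322, 1.87, 0.9852, "down"),
    ("CYTL1", "cytokine", -4.14, 0.0008, -3.74, 0.0073, "down"),
    ("LUM", "other", -4.07, 0.2310, -14.04, 0.0007, "down"),
    ("OMD", "other", -3.91, 0.0000, -2.94, 0.0073, "down"),
    ("ISG15", "other", -3.56, 0.0024, 0.01, 1.0000, "down"),
    ("LCAT", "enzyme", -3.52, 0.0417, -1.14, 1.0000, "down"),
    ("ABI3BP", "other", -3.21, 0.0196, -3.57, 0.0216, "down"),
    ("CYR61", "other", -3.12, 0.0126, -1.61, 0.7504, "down"),
    ("SELENOP", "other", -2.83, 0.0040, -1.84, 0.3549, "down"),
    ("COL14A1", "other", -2.82, 0.0117, -0.79, 1.0000, "down"),
    ("IGFBP6", "other", -2.81, 0.0042, -0.52, 1.0000, "down"),
    ("SAMD9L", "other", -2.41, 0.0483, 0.92, 1.0000, "down"),
]

# gene, direction, n_total, n_pos, n_neg, product name
_CORRELATE_COUNTS = [
    ("SERPINA6", "up", 287, 182, 105, "Serpin A6"),
    ("GLIPR1", "up", 257, 153, 104, "Glioma pathogenesis-related protein 1"),
    ("SERPINE1", "up", 255, 152, 103, "Serpin E1"),
    ("ADAMTS9", "up", 235, 132, 103,
     "A disintegrin and metalloprotease with thrombospondin motifs 9"),
    ("TIMP1", "up", 224, 123, 101, "Tissue inhibitor of metalloprotease 1"),
    ("IL15", "up", 219, 112, 97, "Interleukin 15"),
    ("CYTL1", "down", 283, 106, 177, "Cytokine-like protein 1"),
    ("NDP", "down", 281, 104, 171, "Norrin"),
    ("SPP1", "down", 269, 89, 180, "Osteopontin"),
    ("C1QTNF7", "down", 267, 104, 163, "C1q and tumor necrosis factor-related protein 7"),
    ("LYPD6", "down", 254, 84, 170, "Ly6/PLAUR domain-containing 6"),
    ("LUM", "down", 251, 95, 156, "Lumican"),
    ("CYR61", "down", 250, 93, 157, "Cell communication network factor 1"),
    ("ABI3BP", "down", 239, 95, 144, "ABI family member 3 binding protein"),
    ("CST6", "down", 233, 74, 159, "Cystatin E/M"),
    ("PLA2G7", "down", 215, 76, 139, "Phospholipase A2 group VII"),
    ("OMD", "down", 204, 100, 104, "Osteomodulin"),
    ("MFAP5", "down", 202, 61, 141, "Microfibril associated protein 5"),
]


def extracellular_deg_table() -> pd.DataFrame:
    """The 49 reported extracellular-product intimal DEGs."""
    return pd.DataFrame(
        _EXTRACELLULAR_DEGS,
        columns=[
            "gene", "product_class", "bifurcation_log2_fc", "bifurcation_q",
            "straight_log2_fc", "straight_q", "direction",
        ],
    ).set_index("gene")


def correlate_count_table() -> pd.DataFrame:
    """The 18 reported candidates with > 200 medial correlates."""
    return pd.DataFrame(
        _CORRELATE_COUNTS,
        columns=["gene", "direction", "n_total", "n_pos", "n_neg", "product_name"],
    ).set_index("gene")


def significant_in_straight_vessel(q_threshold: float = 0.05) -> pd.DataFrame:
    """Rows of the extracellular DEG table significant in the straight vessel."""
    table = extracellular_deg_table()
    return table[table["straight_q"] < q_threshold]
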