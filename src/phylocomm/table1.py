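"""Published per-sample diversity and phylogenetic indices for the 16-infant
probiotic-supplementation cohort, with the high/low focal-abundance group
labels used in the study's group comparisons.

These are the printed per-sample values (richness, Pielou's evenness, inverse
Simpson, NTI, NRI); the raw array data behind them were never deposited, so
they serve as a fixed reference table for the group-comparison machinery.
"""

from __future__ import annotations

import pandas as pd

from .io import HIGH, LOW, UNASSIGNED, SampleGroups

__all__ = ["table1_fixture", "TABLE1_COLUMNS"]

TABLE1_COLUMNS = ["richness", "pielou", "inv_simpson", "nti", "nri"]

# sample_id, richness, Pielou J, inverse Simpson, NTI, NRI, group
_ROWS = [
    ("TIPS103", 1333, 0.9906, 1185.09, -1.50, 2.26, LOW),
    ("TIPS104", 1014, 0.9934, 933.92, -1.04, -0.05, LOW),
    ("TIPS105", 1061, 0.9932, 974.79, 1.25, 1.39, UNASSIGNED),
    ("TIPS106", 1285, 0.9938, 1187.24, -0.02, -5.30, HIGH),
    ("TIPS108", 1158, 0.9942, 1076.34, -0.30, -0.33, HIGH),
    ("TIPS110", 1203, 0.9949, 1129.03, -0.64, -0.25, HIGH),
    ("TIPS111", 1278, 0.9938, 1183.64, -2.40, -0.67, LOW),
    ("TIPS114", 950, 0.9875, 814.61, -2.77, -2.01, UNASSIGNED),
    ("TIPS116", 1032, 0.9943, 962.01, 1.24, 1.20, UNASSIGNED),
    ("TIPS117", 1161, 0.9935, 1069.16, -0.72, -2.31, UNASSIGNED),
    ("TIPS122", 1253, 0.9911, 1124.22, -2.11, -2.56, LOW),
    ("TIPS123", 1064, 0.9926, 970.82, 0.16, 1.94, LOW),
    ("TIPS124", 1117, 0.9938, 1033.53, 0.82, -2.12, UNASSIGNED),
    ("TIPS301", 1319, 0.9939, 1223.26, -1.74, -1.30, HIGH),
    ("TIPS501", 1020, 0.9938, 945.40, 0.76, 1.52, HIGH),
    ("TIPS601", 1100, 0.9932, 1010.23, -2.22, -1.95, UNASSIGNED),
]


def table1_fixture() -> tuple[pd.DataFrame, SampleGroups]:
    """Return the published 16-sample metric table and its group labels.

    The DataFrame is indexed by sample id with columns
    ``richness, pielou, inv_simpson, nti, nri``; the groups mark the five
    highest- and five lowest-focal-abundance samples (six unassigned).
    """
    df = pd.DataFrame(
        [(r[0], *r[1:6]) for r in _ROWS],
        columns=["sample_id", *TABLE1_COLUMNS],
    ).set_index("sample_id")
    groups = SampleGroups({r[0]: r[6] for r in _ROWS})
    return df, groups
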