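"""Concordance of array-reported focal-taxon abundance with qPCR.

The qPCR cycle threshold (Ct) falls as template abundance rises, so inverse
Ct (1/Ct by default; 40 − Ct exposed as an option) is regressed on the
focal taxon's array fluorescence intensity. Pearson r with its two-tailed p
and the OLS slope/intercept summarize agreement between the two independent
molecular measurements. Replicate Ct values are averaged before regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError

__all__ = ["QpcrTable", "ConcordanceResult", "read_qpcr_table", "concordance"]


@dataclass
class QpcrTable:
    """Replicate-averaged Ct per sample."""

    ct: pd.Series  # index: sample_id, values: mean Ct (> 0)

    def __post_init__(self) -> None:
        if self.ct.index.duplicated().any():
            raise FormatError("duplicate sample ids in qPCR table")
        if not (self.ct > 0).all():
            raise FormatError("Ct values must be positive")


@dataclass
class ConcordanceResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def read_qpcr_table(path: str | Path) -> QpcrTable:
    """Read a TSV with ``sample_id`` and one or more ``ct_rep*`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing column sample_id")
    rep_cols = [c for c in df.columns if c.startswith("ct")]
    if not rep_cols:
        raise FormatError(f"{path}: no Ct replicate columns (ct_rep1, …)")
    ct = df.set_index("sample_id")[rep_cols].mean(axis=1)
    return QpcrTable(ct.rename("ct"))


def concordance(
    qpcr: QpcrTable,
    intensity: pd.Series,
    transform: str = "inverse",
) -> ConcordanceResult:
    """Regress inverse Ct on focal-taxon array intensity over shared samples.

    ``transform`` is ``"inverse"`` (1/Ct) or ``"subtract40"`` (40 − Ct).
    Needs ≥4 shared samples and non-zero variance on both axes.
    """
    shared = sorted(set(qpcr.ct.index) & set(intensity.index))
    if len(shared) < 4:
        raise ValueError(f"concordance needs ≥4 shared samples, found {len(shared)}")
    x = intensity.loc[shared].to_numpy(float)
    ct = qpcr.ct.loc[shared].to_numpy(float)
    if transform == "inverse":
        y = 1.0 / ct
    elif transform == "subtract40":
        y = 40.0 - ct
    else:
        raise ValueError("transform must be 'inverse' or 'subtract40'")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in intensity or inverse Ct")
    ols = stats.linregress(x, y)
    r, p = stats.pearsonr(x, y)
    return ConcordanceResult(
        r=float(r), p=float(p),
        slope=float(ols.slope), intercept=float(ols.intercept),
        n=len(shared),
    )
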