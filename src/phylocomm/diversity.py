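"""Per-sample diversity and evenness indices.

Relative abundances within a sample derive from the raw (exponentiated)
probe-set intensities of taxa called present in that sample — intensities
proxy taxon relative abundance, log intensities do not — with absent taxa
forced to zero. Shannon entropy uses the natural log, so Pielou's evenness is
J = H' / ln S.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import TaxonAbundanceMatrix
from .presence import sample_richness

__all__ = [
    "relative_abundances",
    "shannon_entropy",
    "pielou_evenness",
    "inverse_simpson",
    "per_sample_metrics",
]


def relative_abundances(matrix: TaxonAbundanceMatrix, sample_id: str) -> np.ndarray:
    """Relative-abundance vector p over the matrix's taxa for one sample.

    p_i is the exp-scale intensity of present taxa normalized to sum one;
    taxa failing the presence call in this sample get p_i = 0.
    """
    j = matrix.sample_index(sample_id)
    present = matrix.present[:, j]
    if not present.any():
        raise ValueError(f"sample {sample_id!r} has no present taxa")
    weights = np.where(present, np.exp(matrix.abundance[:, j]), 0.0)
    return weights / weights.sum()


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"relative abundances must sum to 1 (got {p.sum():.12g})")
    return p


def shannon_entropy(p: np.ndarray) -> float:
    """H' = −Σ p_i ln p_i over the strictly positive entries."""
    p = _check_p(p)
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


def pielou_evenness(p: np.ndarray) -> float:
    """Pielou's J = H' / ln S, S the number of taxa with p_i > 0. Needs S ≥ 2."""
    p = _check_p(p)
    s = int((p > 0).sum())
    if s < 2:
        raise ValueError("Pielou's evenness is undefined for fewer than 2 taxa (ln 1 = 0)")
    return shannon_entropy(p) / np.log(s)


def inverse_simpson(p: np.ndarray) -> float:
    """Inverse Simpson 1/D = 1 / Σ p_i²; equals S for a uniform community."""
    p = _check_p(p)
    if not (p > 0).any():
        raise ValueError("inverse Simpson needs at least one taxon")
    return float(1.0 / np.square(p).sum())


def per_sample_metrics(matrix: TaxonAbundanceMatrix) -> pd.DataFrame:
    """Richness, Pielou J and inverse Simpson for every sample (table rows)."""
    rich = sample_richness(matrix.present, matrix.sample_ids)
    rows = []
    for s in matrix.sample_ids:
        p = relative_abundances(matrix, s)
        rows.append((int(rich[s]), pielou_evenness(p), inverse_simpson(p)))
    return pd.DataFrame(
        rows,
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=["richness", "pielou", "inv_simpson"],
    )
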