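"""Presence calling from probe-set positive fractions.

A taxon is called present in a sample when at least a fraction
``pf_threshold`` (default 0.90, inclusive) of the probes in its probe set
scored positive. Taxa present in no sample are dropped; for the retained taxa
the probe-set fluorescence intensity is log transformed (natural log by
default) in every sample, including samples below the presence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProbeCallTable, TaxonAbundanceMatrix

__all__ = [
    "PresenceParams",
    "positive_fraction",
    "call_presence",
    "build_abundance_matrix",
    "sample_richness",
]

_LOG_FUNCS = {"e": np.log, "2": np.log2, "10": np.log10}


@dataclass(frozen=True)
class PresenceParams:
    """Presence-call threshold on the probe-set positive fraction (pf)."""

    pf_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not 0 <= self.pf_threshold <= 1:
            raise ValueError("pf_threshold must be in [0, 1]")


def positive_fraction(table: ProbeCallTable) -> np.ndarray:
    """pf matrix: probes_positive / probes_total, elementwise in [0, 1]."""
    if (table.probes_total <= 0).any():
        raise ValueError("probes_total must be positive for every taxon")
    return table.probes_positive / table.probes_total[:, None]


def call_presence(pf: np.ndarray, params: PresenceParams | float = PresenceParams()) -> np.ndarray:
    """Boolean presence matrix: present iff pf ≥ threshold (inclusive)."""
    if not isinstance(params, PresenceParams):
        params = PresenceParams(float(params))
    pf = np.asarray(pf, dtype=float)
    if (pf < 0).any() or (pf > 1).any():
        raise ValueError("pf values must lie in [0, 1]")
    return pf >= params.pf_threshold


def build_abundance_matrix(
    table: ProbeCallTable, presence: np.ndarray, log_base: str = "e"
) -> TaxonAbundanceMatrix:
    """Log-transform intensities of taxa present in ≥1 sample.

    The returned matrix keeps the log intensity of every retained taxon in
    every sample (presence mask carried alongside); taxa absent everywhere
    are dropped. ``log_base`` is ``"e"`` (default), ``"2"`` or ``"10"``.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.shape != table.shape:
        raise ValueError("presence mask shape must match the probe-call table")
    if log_base not in _LOG_FUNCS:
        raise ValueError(f"log_base must be one of {sorted(_LOG_FUNCS)}")
    if not np.all(table.intensity > 0):
        raise ValueError("intensity must be strictly positive before log transform")
    keep = presence.any(axis=1)
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    log = _LOG_FUNCS[log_base]
    return TaxonAbundanceMatrix(
        taxon_ids=taxa,
        sample_ids=list(table.sample_ids),
        abundance=log(table.intensity[keep]),
        present=presence[keep],
    )


def sample_richness(presence: np.ndarray, sample_ids: list[str] | None = None) -> pd.Series:
    """Number of present taxa per sample (column sums of the presence mask)."""
    presence = np.asarray(presence, dtype=bool)
    counts = presence.sum(axis=0)
    if sample_ids is None:
        sample_ids = list(range(presence.shape[1]))
    return pd.Series(counts, index=pd.Index(sample_ids, name="sample_id"), name="richness")
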