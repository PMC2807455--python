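"""Sample-by-sample Bray-Curtis dissimilarity and UPGMA clustering.

Bray-Curtis is computed on the log-transformed intensities of all retained
taxa (the working abundance matrix); log fluorescence on the raw array scale
is strictly positive, and non-positive values are rejected rather than
shifted. UPGMA (unweighted average linkage) uses a deterministic tie-break —
the lexicographically smallest cluster pair merges first — so dendrograms are
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import TaxonAbundanceMatrix

__all__ = ["DissimilarityMatrix", "Dendrogram", "bray_curtis", "upgma"]


@dataclass
class DissimilarityMatrix:
    """Square symmetric Bray-Curtis matrix in [0, 1] with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square over sample_ids")
        if np.isnan(self.values).any():
            raise ValueError("dissimilarity matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("dissimilarity diagonal must be zero")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("Bray-Curtis values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.sample_ids, name="sample_id")
        return pd.DataFrame(self.values, index=idx, columns=idx)


@dataclass
class Dendrogram:
    """Average-linkage merge sequence over samples.

    ``merges`` lists, in order, the two cluster member-tuples joined and the
    merge height; heights are non-decreasing (average linkage is monotone).
    """

    leaf_ids: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def clusters(self) -> list[frozenset[str]]:
        """Every cluster (leaf set) formed during the merge sequence."""
        out = [frozenset([l]) for l in self.leaf_ids]
        out += [frozenset(a) | frozenset(b) for a, b, _ in self.merges]
        return out

    def has_cluster(self, members: set[str]) -> bool:
        """True if ``members`` appears as an exact cluster (clade) in the tree."""
        return frozenset(members) in set(self.clusters())

    def to_newick(self) -> str:
        """Ultrametric Newick; branch length = parent height − child height."""
        node: dict[frozenset[str], tuple[str, float]] = {
            frozenset([l]): (l, 0.0) for l in self.leaf_ids
        }
        nwk = ""
        for a, b, h in self.merges:
            fa, fb = frozenset(a), frozenset(b)
            (sa, ha), (sb, hb) = node.pop(fa), node.pop(fb)
            nwk = f"({sa}:{h - ha:.10g},{sb}:{h - hb:.10g})"
            node[fa | fb] = (nwk, h)
        (s, _), = node.values()
        return s + ";"


def bray_curtis(matrix: TaxonAbundanceMatrix | np.ndarray,
                sample_ids: list[str] | None = None) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    d(j, k) = Σ_i |x_ij − x_ik| / Σ_i (x_ij + x_ik) over retained taxa.
    """
    if isinstance(matrix, TaxonAbundanceMatrix):
        x = matrix.abundance
        sample_ids = list(matrix.sample_ids)
    else:
        x = np.asarray(matrix, dtype=float)
        if sample_ids is None:
            sample_ids = [str(j) for j in range(x.shape[1])]
    if x.shape[1] < 2:
        raise ValueError("Bray-Curtis needs at least two samples")
    if (x < 0).any():
        raise ValueError("Bray-Curtis input must be non-negative")
    cols = x.T
    sums = cols.sum(axis=1)
    if np.add.outer(sums, sums)[~np.eye(len(sums), dtype=bool)].min() <= 0:
        raise ValueError("a sample pair has all-zero combined abundance")
    d = squareform(pdist(cols, metric="braycurtis"))
    return DissimilarityMatrix(sample_ids, d)


def upgma(dissim: DissimilarityMatrix) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) clustering of the samples.

    The inter-cluster distance is the mean of all cross-pair original
    distances. Equal candidate distances are broken by the lexicographically
    smallest (cluster-label, cluster-label) pair, where a cluster's label is
    its smallest member id.
    """
    ids = list(dissim.sample_ids)
    d0 = dissim.values
    if np.isnan(d0).any():
        raise ValueError("dissimilarity matrix contains NaN")
    index = {s: i for i, s in enumerate(ids)}
    clusters: dict[str, tuple[str, ...]] = {s: (s,) for s in ids}

    def avg(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return float(np.mean([[d0[index[x], index[y]] for y in b] for x in a]))

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        labels = sorted(clusters)
        best: tuple[float, str, str] | None = None
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                cand = (avg(clusters[la], clusters[lb]), la, lb)
                if best is None or cand < best:
                    best = cand
        h, la, lb = best
        a, b = clusters.pop(la), clusters.pop(lb)
        merges.append((a, b, h))
        clusters[min(la, lb)] = tuple(sorted(a + b))
    return Dendrogram(ids, merges)
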