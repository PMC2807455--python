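"""Phylogenetic community-structure statistics: MPD, MNTD, NRI and NTI.

MPD is the mean patristic distance over all unordered pairs of community
members; MNTD the mean distance from each member to its nearest other member.
Both are unweighted (presence-based). NRI and NTI are negated z-scores of MPD
and MNTD against a phylogeny-shuffle null: tip labels are permuted across the
taxon pool, which for a fixed community size is equivalent to drawing random
same-size subsets of the pool. Positive NRI/NTI indicate phylogenetic
clustering; the null standard deviation uses the n−1 sample estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import TaxonAbundanceMatrix

__all__ = [
    "NullModelConfig",
    "PhyloStructureResult",
    "patristic_matrix",
    "mpd",
    "mntd",
    "nri_nti",
    "per_sample_phylo_metrics",
]


@dataclass(frozen=True)
class NullModelConfig:
    """Permutation-null settings for NRI/NTI."""

    n_permutations: int = 999
    rng_seed: int = 0
    shuffle: str = "tip_labels"

    def __post_init__(self) -> None:
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be ≥ 99")
        if self.shuffle != "tip_labels":
            raise ValueError("only the tip-label shuffle null is implemented")


@dataclass
class PhyloStructureResult:
    """Observed MPD/MNTD with their permutation-null moments and z-scores."""

    mpd_obs: float
    mntd_obs: float
    mpd_null_mean: float
    mpd_null_sd: float
    mntd_null_mean: float
    mntd_null_sd: float
    nri: float
    nti: float
    n_permutations: int


def patristic_matrix(tree: dendropy.Tree, tips: Sequence[str] | None = None) -> pd.DataFrame:
    """Tip-to-tip path-length (sum of branch lengths) distance matrix.

    ``tips`` restricts and orders the rows/columns; unknown tips are an error.
    """
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace if t.label is not None}
    if tips is None:
        tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = [t for t in tips if t not in by_label]
    if missing:
        raise KeyError(f"tips not on tree: {missing[:5]}")
    n = len(tips)
    d = np.zeros((n, n))
    taxa = [by_label[t] for t in tips]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    idx = pd.Index(list(tips), name="taxon_id")
    return pd.DataFrame(d, index=idx, columns=idx)


def _submatrix(dist: pd.DataFrame, community: Sequence[str]) -> np.ndarray:
    missing = [t for t in community if t not in dist.index]
    if missing:
        raise KeyError(f"community tips not in distance matrix: {missing[:5]}")
    return dist.loc[list(community), list(community)].to_numpy(float)


def mpd(community: Sequence[str], dist: pd.DataFrame) -> float:
    """Mean patristic distance over all unordered pairs of community members."""
    if len(community) < 2:
        raise ValueError("MPD needs a community of ≥2 taxa")
    d = _submatrix(dist, community)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def mntd(community: Sequence[str], dist: pd.DataFrame) -> float:
    """Mean distance from each member to its nearest other community member."""
    if len(community) < 2:
        raise ValueError("MNTD needs a community of ≥2 taxa")
    d = _submatrix(dist, community)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def _mpd_mntd_arrays(d: np.ndarray) -> tuple[float, float]:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    mpd_v = d[iu].mean()
    dd = d.copy()
    np.fill_diagonal(dd, np.inf)
    mntd_v = dd.min(axis=1).mean()
    return float(mpd_v), float(mntd_v)


def nri_nti(
    community: Sequence[str],
    dist: pd.DataFrame,
    pool: Sequence[str] | None = None,
    config: NullModelConfig = NullModelConfig(),
) -> PhyloStructureResult:
    """NRI and NTI of a community against random same-size pool subsets.

    NRI = −(MPD_obs − mean_null)/sd_null, NTI likewise from MNTD. The null
    draws ``config.n_permutations`` random subsets of the pool of the
    community's size (tip-label shuffle). Errors when the community equals
    the pool or the null has (near-)zero spread.
    """
    community = [str(t) for t in community]
    if pool is None:
        pool = list(dist.index)
    pool = [str(t) for t in pool]
    if len(set(community)) != len(community):
        raise ValueError("duplicate taxa in community")
    if not set(community) <= set(pool):
        raise ValueError("community must be a subset of the pool")
    if len(community) < 2:
        raise ValueError("community must have ≥2 taxa")
    if len(community) >= len(pool):
        raise ValueError("community must be strictly smaller than the pool "
                         "(null spread is zero otherwise)")
    missing = [t for t in pool if t not in dist.index]
    if missing:
        raise KeyError(f"pool tips not in distance matrix: {missing[:5]}")

    dpool = dist.loc[list(pool), list(pool)].to_numpy(float)
    pos = {t: i for i, t in enumerate(pool)}
    comm_idx = np.array([pos[t] for t in community])
    mpd_obs, mntd_obs = _mpd_mntd_arrays(dpool[np.ix_(comm_idx, comm_idx)])

    rng = np.random.default_rng(config.rng_seed)
    k, npool = len(community), len(pool)
    mpd_null = np.empty(config.n_permutations)
    mntd_null = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        sub = rng.choice(npool, size=k, replace=False)
        mpd_null[b], mntd_null[b] = _mpd_mntd_arrays(dpool[np.ix_(sub, sub)])

    mpd_sd = mpd_null.std(ddof=1)
    mntd_sd = mntd_null.std(ddof=1)
    if mpd_sd < 1e-12 or mntd_sd < 1e-12:
        raise ValueError("degenerate null distribution (sd ≈ 0); "
                         "is the pool phylogenetically uniform?")
    return PhyloStructureResult(
        mpd_obs=mpd_obs,
        mntd_obs=mntd_obs,
        mpd_null_mean=float(mpd_null.mean()),
        mpd_null_sd=float(mpd_sd),
        mntd_null_mean=float(mntd_null.mean()),
        mntd_null_sd=float(mntd_sd),
        nri=float(-(mpd_obs - mpd_null.mean()) / mpd_sd),
        nti=float(-(mntd_obs - mntd_null.mean()) / mntd_sd),
        n_permutations=config.n_permutations,
    )


def per_sample_phylo_metrics(
    matrix: TaxonAbundanceMatrix,
    tree: dendropy.Tree,
    config: NullModelConfig = NullModelConfig(),
) -> pd.DataFrame:
    """Per-sample NRI/NTI with the pool of all detected taxa.

    Tree tips absent from the matrix are ignored (pruned at analysis time);
    matrix taxa missing from the tree are a hard error. Samples whose present
    community equals the pool (no null spread) get NaN rows.
    """
    tree_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [t for t in matrix.taxon_ids if t not in tree_tips]
    if missing:
        raise KeyError(
            f"{len(missing)} matrix taxa missing from the tree, e.g. {missing[:5]}"
        )
    pool = [t for t, det in zip(matrix.taxon_ids, matrix.detected_anywhere) if det]
    dist = patristic_matrix(tree, pool)
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    for j, s in enumerate(matrix.sample_ids):
        community = [t for t, p in zip(matrix.taxon_ids, matrix.present[:, j]) if p]
        sample_cfg = NullModelConfig(
            n_permutations=config.n_permutations,
            rng_seed=int(rng.integers(2**31)),
        )
        try:
            res = nri_nti(community, dist, pool, sample_cfg)
            rows.append((s, res.mpd_obs, res.mntd_obs, res.nri, res.nti))
        except ValueError:
            rows.append((s, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["sample_id", "mpd", "mntd", "nri", "nti"]
    ).set_index("sample_id")
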