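"""Synthetic PhyloChip-like experiments with planted structure.

The generator emulates a 16S microarray study of the infant gut: ~hundreds of
taxa on a phylogeny, two sample groups distinguished by the abundance of a
focal (probiotic) taxon, a phylogenetically clustered "promoted" clade whose
members are boosted alongside the focal taxon, and taxa whose abundance is
correlated (positively or negatively) with the focal taxon through a shared
latent factor. Probe-level positive calls are drawn from a binomial whose
success probability rises logistically with latent log abundance, so the
presence-calling positive-fraction rule is exercised end to end.

Every artifact is a deterministic function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
from scipy.special import expit

from .io import HIGH, LOW, ProbeCallTable, SampleGroups, tree_from_string

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_experiment",
    "simulate_dataset",
]

#: logistic link from latent log intensity to per-probe positive probability:
#: P(probe positive) = expit((a - PROBE_MIDPOINT) / PROBE_SCALE). The midpoint
#: sits two baseline standard deviations below the mean baseline so typical
#: taxa call present while rare taxa straddle the pf threshold.
PROBE_MIDPOINT = 5.0
PROBE_SCALE = 0.5

#: mean and SD of per-taxon baseline log intensity (natural-log fluorescence)
BASELINE_MEAN = 7.0
BASELINE_SD = 1.0

#: mean branch length (substitutions/site) for simulated trees
BRANCH_MEAN = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated experiment."""

    n_taxa: int = 200
    n_samples: int = 16              # split evenly high/low
    probes_per_set: int = 24
    focal_taxon_boost: float = 8.0   # × intensity in high-group samples
    promoted_clade_size: int = 20
    promoted_boost: float = 3.0      # × intensity in high-group samples
    n_correlated_pos: int = 15
    n_correlated_neg: int = 3
    corr_target: float = 0.7         # target |Pearson r| with the focal taxon
    noise_sd: float = 0.3            # SD of log-intensity noise
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be ≥ 3")
        if self.promoted_clade_size >= self.n_taxa:
            raise ValueError("promoted_clade_size must be < n_taxa")
        if self.focal_taxon_boost < 1 or self.promoted_boost < 1:
            raise ValueError("boosts must be ≥ 1")
        if not 0 <= self.corr_target < 1:
            raise ValueError("corr_target must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.rng_seed is None:
            raise ValueError("rng_seed must be set explicitly")


@dataclass
class GroundTruth:
    """Planted structure of one simulated experiment."""

    focal_taxon_id: str
    promoted_taxon_ids: list[str]
    correlated_pos_ids: list[str]
    correlated_neg_ids: list[str]
    groups: SampleGroups

    def __post_init__(self) -> None:
        sets = [
            {self.focal_taxon_id},
            set(self.promoted_taxon_ids),
            set(self.correlated_pos_ids),
            set(self.correlated_neg_ids),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("planted taxon sets must be disjoint")

    @property
    def effect_taxon_ids(self) -> set[str]:
        """All taxa with any planted group effect (focal, promoted, correlated)."""
        return (
            {self.focal_taxon_id}
            | set(self.promoted_taxon_ids)
            | set(self.correlated_pos_ids)
            | set(self.correlated_neg_ids)
        )


def simulate_tree(n_taxa: int, seed: int | np.random.SeedSequence) -> dendropy.Tree:
    """Random rooted binary tree with ``n_taxa`` tips labelled T0001, T0002, …

    Topology by recursive uniform random splitting of the tip set; branch
    lengths i.i.d. Exponential with mean 0.05 substitutions/site.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be ≥ 3")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_taxa)))
    labels = [f"T{i + 1:0{width}d}" for i in range(n_taxa)]
    perm = rng.permutation(n_taxa)
    shuffled = [labels[i] for i in perm]

    def bl() -> str:
        return f"{rng.exponential(BRANCH_MEAN):.10g}"

    def build(tips: list[str]) -> str:
        if len(tips) == 1:
            return tips[0]
        split = int(rng.integers(1, len(tips)))
        left, right = tips[:split], tips[split:]
        return f"({build(left)}:{bl()},{build(right)}:{bl()})"

    return tree_from_string(build(shuffled) + ";")


def _pick_promoted_clade(tree: dendropy.Tree, size: int) -> list[str]:
    """First-preorder internal node whose tip count is closest to ``size``
    within ±25%; its tips become the promoted clade."""
    lo = int(np.ceil(0.75 * size))
    hi = int(np.floor(1.25 * size))
    best: tuple[int, int] | None = None  # (|count-size|, preorder index)
    best_tips: list[str] | None = None
    for order, node in enumerate(tree.preorder_internal_node_iter()):
        if node is tree.seed_node:
            continue
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        if lo <= len(tips) <= hi:
            key = (abs(len(tips) - size), order)
            if best is None or key < best:
                best, best_tips = key, tips
    if best_tips is None:
        raise ValueError(
            f"no subtree with {lo}–{hi} tips (requested clade size {size} ±25%); "
            "try a different seed"
        )
    return sorted(best_tips)


def simulate_experiment(
    config: SimulationConfig, tree: dendropy.Tree
) -> tuple[ProbeCallTable, GroundTruth]:
    """Draw one probe-call table with planted structure on ``tree``.

    Latent log abundance: ``a_ij = mu_i + effects + noise`` with per-taxon
    baseline ``mu_i ~ N(7, 1)`` and noise ``N(0, noise_sd)``. The focal taxon
    and every promoted-clade member gain ``log(boost)`` in high-group samples.
    Correlated taxa replace their noise with ``noise_sd * (s·rho·z + sqrt(1 -
    rho²)·eps)`` where ``z`` is the standardized focal log abundance across
    samples, giving Pearson correlation ≈ ``s·rho`` with the focal taxon.
    Intensity is ``exp(a)``; probes positive ~ Binomial(probes_per_set,
    expit((a - 5) / 0.5)).
    """
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(tips) < config.n_taxa:
        raise ValueError(
            f"tree has {len(tips)} tips but config requests {config.n_taxa} taxa"
        )
    taxa = tips[: config.n_taxa]
    taxon_set = set(taxa)

    promoted = [t for t in _pick_promoted_clade(tree, config.promoted_clade_size)
                if t in taxon_set]
    if not promoted:
        raise ValueError("promoted clade lies outside the simulated taxon set; "
                         "try a different seed")
    promoted_set = set(promoted)
    candidates = [t for t in taxa if t not in promoted_set]
    need = 1 + config.n_correlated_pos + config.n_correlated_neg
    if len(candidates) < need:
        raise ValueError("not enough taxa outside the promoted clade for the "
                         "focal and correlated sets")
    focal = candidates[0]
    corr_pos = candidates[1 : 1 + config.n_correlated_pos]
    corr_neg = candidates[1 + config.n_correlated_pos : need]

    n_high = config.n_samples // 2
    sample_ids = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    groups = SampleGroups(
        {s: (HIGH if j < n_high else LOW) for j, s in enumerate(sample_ids)}
    )
    is_high = np.array([j < n_high for j in range(config.n_samples)])

    rng = np.random.default_rng(config.rng_seed)
    n_t, n_s = len(taxa), config.n_samples
    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_t)
    noise = rng.normal(0.0, 1.0, size=(n_t, n_s))  # unit noise, scaled below
    a = mu[:, None] + config.noise_sd * noise

    idx = {t: i for i, t in enumerate(taxa)}
    f = idx[focal]
    a[f] += np.log(config.focal_taxon_boost) * is_high
    for t in promoted:
        a[idx[t]] += np.log(config.promoted_boost) * is_high

    # correlated taxa track the standardized focal profile across samples
    focal_sd = a[f].std()
    z = (a[f] - a[f].mean()) / focal_sd if focal_sd > 0 else np.zeros(n_s)
    rho = config.corr_target
    mix = np.sqrt(1.0 - rho * rho)
    for sign, ids in ((+1.0, corr_pos), (-1.0, corr_neg)):
        for t in ids:
            i = idx[t]
            a[i] = mu[i] + config.noise_sd * (sign * rho * z + mix * noise[i])

    intensity = np.exp(a)
    p_probe = expit((a - PROBE_MIDPOINT) / PROBE_SCALE)
    probes_positive = rng.binomial(config.probes_per_set, p_probe)
    probes_total = np.full(n_t, config.probes_per_set, dtype=int)

    table = ProbeCallTable(taxa, sample_ids, probes_total, probes_positive, intensity)
    truth = GroundTruth(focal, promoted, list(corr_pos), list(corr_neg), groups)
    return table, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dendropy.Tree, ProbeCallTable, GroundTruth]:
    """Simulate tree and experiment from the single configuration seed."""
    ss = np.random.SeedSequence(config.rng_seed)
    tree_ss, exp_ss = ss.spawn(2)
    tree = simulate_tree(config.n_taxa, tree_ss)
    exp_seed = int(exp_ss.generate_state(1, np.uint32)[0] % (2**31))
    table, truth = simulate_experiment(replace(config, rng_seed=exp_seed), tree)
    return tree, table, truth
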