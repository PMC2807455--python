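# Methods

## Analysis model

The pipeline treats a 16S oligonucleotide-microarray experiment as a taxa ×
samples table of probe-set summaries. Detection is conservative: a taxon is
scored present in a sample only when the positive fraction of its probe set
reaches **pf ≥ 0.9**, with the boundary inclusive. Changes in probe-set
fluorescence intensity are taken as proportional to changes in a taxon's
relative abundance between samples; intensity is therefore the abundance
proxy throughout. Taxa present in no sample are removed, and the retained
intensities are log transformed before any between-sample statistics.

**Log base.** The transform is the natural log by default, with log2/log10
exposed (`build_abundance_matrix(..., log_base=...)`). Every downstream
statistic is either invariant to the base (Welch t, Pearson r, presence-based
indices) or rescales linearly (Bray–Curtis numerator and denominator scale
together), so the choice is cosmetic; ln keeps Shannon entropy and Pielou's J
in their conventional units (nats).

**Relative abundances for diversity.** Within a sample, pᵢ is the raw
(exponentiated) intensity of each *present* taxon normalized to sum one;
absent taxa are forced to pᵢ = 0 so the indices reflect the called community.
Weighting by raw intensity rather than log intensity follows directly from
intensity being the abundance proxy — log intensity would compress true
abundance ratios. For near-even communities the distinction is small: with
log intensities spread like N(7, 0.35²), inverse Simpson sits within ~15% of
richness and J ≈ 0.99, the regime of the published per-sample table.

**Bray–Curtis input.** The dissimilarity is computed on the log-transformed
intensities of all retained taxa (not only present-called cells). Log
fluorescence on the raw array scale is strictly positive, so the Bray–Curtis
denominator is always positive; a non-positive value is rejected as a data
error rather than shifted, because a silent offset would change every
distance. A `raw` path is available by passing the exponentiated matrix
directly to `bray_curtis`.

**UPGMA.** Average linkage with inter-cluster distance defined as the mean of
all cross-pair *original* distances. Ties are broken by the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest member
id). This in-package implementation exists because reproducible dendrograms
require a pinned tie-break; scipy's average linkage is used as an independent
oracle in the tests on tie-free inputs.

## Screens

The differential screen ranks samples by the focal taxon's abundance and
compares the top k with the bottom k (k = 5 by default, matching the study
design of five high vs five low samples out of 16; ranking ties break by
sample id). Each retained taxon gets a two-tailed Welch t-test; significance
requires p ≤ 0.05 and Storey q ≤ 0.057. The correlation screen computes
Pearson r of every other taxon against the focal taxon over all samples, with
p from the exact t transform; significance requires |r| ≥ 0.5 (boundary
inclusive), p < 0.05 and q < 0.15. Zero-variance taxa cannot carry a
statistic; they are flagged `excluded` and withheld from the q-value pool
rather than assigned p = 1, which would distort π₀ estimation.

**Storey q-values.** π₀ is estimated by the smoother method: π₀(λ) =
#{p > λ}/(m(1−λ)) on λ = 0.05, 0.10, …, 0.95, a cubic polynomial fit to the
sequence, evaluated at λ = 1 and clamped to (0, 1] (floored at 1/m).
q-values follow the usual step-up: qᵢ = min over pⱼ ≥ pᵢ of π₀·m·pⱼ/rank(pⱼ).
With π₀ = 1 this is exactly Benjamini–Hochberg, which the tests assert
against statsmodels. The bootstrap π₀ method is not implemented. Fewer than
10 p-values fall back to π₀ = 1 (the smoother is too unstable there).

## Phylogenetic community structure

MPD is the mean patristic distance over all unordered pairs of community
members; MNTD the mean distance from each member to its nearest other member.
Both are unweighted (presence-based): the indices are computed from taxon
richness, so abundance-weighted variants are out of scope. The null model is
a phylogeny shuffle — random permutation of tip labels across the taxon pool
— which for unweighted statistics at fixed community size is equivalent to
drawing random same-size subsets of the pool; it is coded as subset draws for
speed, 999 permutations by default with an explicit seed, and the null SD
uses the n−1 estimator. NRI = −(MPD_obs − mean_null)/sd_null and NTI likewise
from MNTD, so positive values indicate clustering. Degenerate nulls
(community = pool, or sd_null < 1e-12) raise instead of returning ±∞. The
Monte-Carlo null is checked in the tests against exhaustive subset
enumeration on pools of ≤ 8 tips, and observed MPD/MNTD against R picante.

## qPCR concordance

Inverse cycle threshold is 1/Ct (the alternative 40 − Ct convention is
exposed as a `transform` option since either reading is defensible).
Replicate Ct values are averaged per sample before ordinary least squares of
1/Ct on the focal taxon's raw array intensity; Pearson r with its two-tailed
p summarizes concordance. Regression is against raw intensity by default
(log intensity optional by passing a transformed series) for the same
abundance-proxy reason as the diversity weighting.

## Synthetic experiments

The generator emulates the study conditions: 16 samples split 8/8 into
high/low groups, a few hundred taxa on a random phylogeny, probe sets of 24
probes. Per-taxon baseline log intensity μᵢ ~ N(7, 1) on the natural-log
fluorescence scale; within-sample noise N(0, 0.3). The focal taxon gains
log 8 in high-group samples (an 8× intensity boost), a monophyletic clade of
20 taxa (the closest-size subtree within ±25%) gains log 3, and 15 + 3 taxa
are positively/negatively correlated with the focal taxon at target
|r| = 0.7 through a shared latent factor built from the focal taxon's
standardized across-sample profile. Probe positives are
Binomial(24, expit((a − 5)/0.5)): the logistic midpoint two baseline SDs
below the mean keeps typical taxa present while rare ones straddle the pf
threshold, so presence calling is exercised rather than bypassed. Trees use
random-split topology with Exponential(mean 0.05) branch lengths — only tip
distances enter NRI/NTI, so a coalescent would add complexity without
changing what is tested. Defaults were fixed once as plausible study-scale
conditions; the clade promotion effect size has no published value and is a
calibration choice.

What the generator does *not* emulate: probe cross-hybridization, chimeras,
PCR bias, compositional closure, or realistic phylogenetic signal in
baseline abundances. Passing tests therefore demonstrate statistical
correctness and calibration of the machinery under a clean generative model,
not robustness to array artefacts.

**False-discovery accounting.** Correlated taxa inherit the focal taxon's
group shift through the shared factor, so they are genuinely differentially
abundant. The recovery checks count every taxon with a planted effect
(focal, promoted, correlated) as a true positive; empirical FDR counts only
effect-free taxa as false discoveries.

## Problem sizes and numerical choices

Validation uses 200 taxa × 16 samples, 999 permutations and 20 replicate
seeds (200 draws for null calibration; 10 seeds for the dendrogram-clade
frequency check), sizes at which every planted structure is comfortably
detectable and the whole suite runs in a couple of minutes. All simulation
randomness flows through `numpy.random.default_rng` with explicit seeds;
fixing the seed fixes every artifact byte-for-byte. Sorting ties anywhere
(UPGMA merges, sample ranking, output tables) are resolved lexicographically
so reruns and platforms agree. Numeric output is printed with 6 significant
digits.

## Known limitations

- The published per-sample index table is consumed at its printed precision
  (4 decimals for evenness). The evenness group comparison recomputed from
  those rounded values gives Welch p = 0.0414 — it rounds to the reported
  0.041 but knife-edge inequalities at the next decimal are not meaningful at
  that input precision.
- The study's own taxon counts (e.g. the total detected taxa and the sizes of
  its significant sets) depend on raw array data and a 16S tree that were
  never deposited; the package reproduces the *procedures* and validates them
  on ground-truthed simulations instead.
- π₀ estimation by cubic extrapolation is noisy below a few hundred tests;
  for very small screens the BH-equivalent π₀ = 1 fallback is deliberately
  conservative.
- UPGMA is O(n³) as written; it is meant for cohort-scale sample counts
  (tens), not thousands.
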