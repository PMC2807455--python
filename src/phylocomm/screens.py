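"""FDR-controlled per-taxon screens against a focal taxon.

Two screens mirror the study design: (1) a differential-abundance screen
comparing the k samples with the highest focal-taxon abundance to the k with
the lowest (two-tailed Welch t-test, significant at p ≤ 0.05 and Storey
q ≤ 0.057); (2) a correlation screen of every taxon's log abundance against
the focal taxon across all samples (Pearson r, significant at |r| ≥ 0.5,
p < 0.05 and q < 0.15).

Storey q-values estimate the null proportion π₀ with the cubic-smoother
method on the λ grid 0.05, 0.10, …, 0.95 extrapolated to λ = 1; with π₀
forced to 1 they reduce exactly to Benjamini–Hochberg adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import HIGH, LOW, UNASSIGNED, SampleGroups, ScreenResult, TaxonAbundanceMatrix

__all__ = [
    "ScreenThresholds",
    "welch_t",
    "storey_pi0",
    "storey_qvalues",
    "select_extreme_groups",
    "differential_screen",
    "correlation_screen",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Significance gates for the two screens."""

    diff_p: float = 0.05      # inclusive: p ≤ diff_p
    diff_q: float = 0.057     # inclusive: q ≤ diff_q
    corr_r: float = 0.5       # inclusive: |r| ≥ corr_r
    corr_p: float = 0.05      # strict: p < corr_p
    corr_q: float = 0.15      # strict: q < corr_q


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def welch_t(x, y) -> tuple[float, float, float]:
    """Two-tailed Welch's t-test for unequal variances.

    Returns ``(t, df, p)`` with t = (x̄ − ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ), df by
    Welch–Satterthwaite and p from the Student-t survival function. Both
    groups identically constant and equal → t = 0, p = 1; both constant but
    unequal → error (no variance to test against).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t-test needs ≥2 observations per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("Welch's t-test requires finite values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


def storey_pi0(p: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Cubic-smoother estimate of the null proportion π₀.

    π₀(λ) = #{p > λ} / (m (1 − λ)) on the λ grid; a cubic polynomial is fit
    to the sequence and evaluated at λ = 1, then clamped to (0, 1].
    """
    p = _check_pvalues(p)
    if p.size < 10:
        raise ValueError("π₀ smoothing needs at least 10 p-values")
    pi0_lambda = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_lambda, 3)
    pi0 = float(np.polyval(coef, 1.0))
    return min(max(pi0, 1.0 / p.size), 1.0)


def _check_pvalues(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def storey_qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a vector of p-values.

    q_i = min over p_j ≥ p_i of π₀ · m · p_j / rank(p_j); q is monotone
    non-decreasing in p. With ``pi0=1`` this is exactly the
    Benjamini–Hochberg adjustment.
    """
    p = _check_pvalues(p)
    if pi0 is None:
        pi0 = storey_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1) * pi0
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Group selection and screens
# ---------------------------------------------------------------------------

def select_extreme_groups(
    matrix: TaxonAbundanceMatrix, focal_taxon_id: str, k: int = 5
) -> SampleGroups:
    """Label the k samples with the highest focal-taxon abundance ``high`` and
    the k lowest ``low``; ties in abundance break by sample id."""
    if k < 2:
        raise ValueError("group size k must be ≥ 2")
    if 2 * k > len(matrix.sample_ids):
        raise ValueError(f"2k = {2 * k} exceeds the {len(matrix.sample_ids)} samples")
    i = matrix.taxon_index(focal_taxon_id)
    ranked = sorted(
        matrix.sample_ids,
        key=lambda s: (-matrix.abundance[i, matrix.sample_index(s)], s),
    )
    labels = {s: UNASSIGNED for s in matrix.sample_ids}
    for s in ranked[:k]:
        labels[s] = HIGH
    for s in ranked[-k:]:
        labels[s] = LOW
    return SampleGroups(labels)


def differential_screen(
    matrix: TaxonAbundanceMatrix,
    groups: SampleGroups | None = None,
    focal_taxon_id: str | None = None,
    k: int = 5,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[ScreenResult]:
    """Per-taxon two-tailed Welch test of high vs low samples with Storey FDR.

    Groups are either given explicitly or derived by ranking samples on the
    focal taxon's abundance (top k vs bottom k). Taxa with zero variance in
    both groups are flagged ``excluded`` and left out of the q-value pool.
    Significant: p ≤ 0.05 and q ≤ 0.057 (defaults).
    """
    if groups is None:
        if focal_taxon_id is None:
            raise ValueError("provide groups or a focal taxon id to rank on")
        groups = select_extreme_groups(matrix, focal_taxon_id, k)
    groups.require_two_groups()
    hi, lo = groups.high, groups.low
    if set(hi) & set(lo):
        raise ValueError("high and low groups overlap")
    jh = [matrix.sample_index(s) for s in hi]
    jl = [matrix.sample_index(s) for s in lo]
    xh, xl = matrix.abundance[:, jh], matrix.abundance[:, jl]

    results: list[ScreenResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for i, taxon in enumerate(matrix.taxon_ids):
        direction = "up" if xh[i].mean() >= xl[i].mean() else "down"
        if xh[i].var(ddof=1) == 0 and xl[i].var(ddof=1) == 0 and xh[i].mean() != xl[i].mean():
            results.append(ScreenResult(taxon, np.nan, np.nan, np.nan,
                                        direction, False, excluded=True))
            continue
        t, _, p = welch_t(xh[i], xl[i])
        results.append(ScreenResult(taxon, t, p, np.nan, direction, False))
        tested_idx.append(len(results) - 1)
        pvals.append(p)
    _attach_q(results, tested_idx, pvals)
    for r in results:
        if not r.excluded:
            r.significant = bool(r.p <= thresholds.diff_p and r.q <= thresholds.diff_q)
    return results


def correlation_screen(
    matrix: TaxonAbundanceMatrix,
    focal_taxon_id: str,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[ScreenResult]:
    """Pearson correlation of every taxon with the focal taxon, Storey FDR.

    Uses log abundance across all samples; the focal taxon is excluded from
    its own screen, and zero-variance taxa are flagged ``excluded``.
    Significant: |r| ≥ 0.5, p < 0.05 and q < 0.15 (defaults).
    """
    n = len(matrix.sample_ids)
    if n < 4:
        raise ValueError("correlation screen needs ≥4 samples")
    f = matrix.taxon_index(focal_taxon_id)
    focal = matrix.abundance[f]
    if focal.std() == 0:
        raise ValueError("focal taxon has zero variance across samples")

    results: list[ScreenResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for i, taxon in enumerate(matrix.taxon_ids):
        if i == f:
            continue
        x = matrix.abundance[i]
        if x.std() == 0:
            results.append(ScreenResult(taxon, np.nan, np.nan, np.nan,
                                        "positive", False, excluded=True))
            continue
        r, p = stats.pearsonr(x, focal)
        direction = "positive" if r >= 0 else "negative"
        results.append(ScreenResult(taxon, float(r), float(p), np.nan, direction, False))
        tested_idx.append(len(results) - 1)
        pvals.append(float(p))
    if not tested_idx:
        raise ValueError("no taxa with variance to correlate against the focal taxon")
    _attach_q(results, tested_idx, pvals)
    for r in results:
        if not r.excluded:
            r.significant = bool(
                abs(r.statistic) >= thresholds.corr_r
                and r.p < thresholds.corr_p
                and r.q < thresholds.corr_q
            )
    return results


def _attach_q(results: list[ScreenResult], tested_idx: list[int],
              pvals: list[float]) -> None:
    if not tested_idx:
        return
    p = np.asarray(pvals)
    pi0 = storey_pi0(p) if p.size >= 10 else 1.0
    q = storey_qvalues(p, pi0=pi0)
    for idx, qi in zip(tested_idx, q):
        results[idx].q = float(qi)
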