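import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

import phylocomm as pc
from phylocomm.screens import (
    ScreenThresholds,
    correlation_screen,
    differential_screen,
    select_extreme_groups,
    storey_pi0,
    storey_qvalues,
    welch_t,
)
from conftest import make_matrix


def welch_formula(x, y):
    """Brute-force Welch from the defining formulas (independent oracle)."""
    from scipy import stats

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_groups_give_null_result(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_equal_groups(self):
        t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_unequal_groups_error(self):
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0], [3.0, 3.0])

    def test_matches_formula_oracle(self):
        for x, y in [([1, 2, 3], [2, 3, 4]),
                     ([0.1, 0.5, 0.9, 1.3], [2.0, 2.2]),
                     (np.random.default_rng(0).normal(size=6),
                      np.random.default_rng(1).normal(1, 2, size=9))]:
            t, df, p = welch_t(x, y)
            te, dfe, pe = welch_formula(x, y)
            assert t == pytest.approx(te, abs=1e-12)
            assert df == pytest.approx(dfe, abs=1e-9)
            assert p == pytest.approx(pe, abs=1e-12)

    def test_group_swap_flips_t_preserves_p(self):
        x, y = [1.0, 2.0, 4.0], [3.0, 5.0, 8.0]
        t1, _, p1 = welch_t(x, y)
        t2, _, p2 = welch_t(y, x)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_published_evenness_comparison_is_significant(self):
        """Evenness difference between high and low focal-abundance samples."""
        hi = [0.9938, 0.9942, 0.9949, 0.9939, 0.9938]
        lo = [0.9906, 0.9934, 0.9938, 0.9911, 0.9926]
        t, _, p = welch_t(hi, lo)
        assert t > 0
        assert round(p, 3) <= 0.041  # printed-precision agreement


class TestStoreyQ:
    def test_all_ones_stay_one(self):
        q = storey_qvalues(np.ones(20))
        np.testing.assert_allclose(q, 1.0)

    def test_pi0_near_one_under_uniform_null(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=5000)
        assert 0.9 <= storey_pi0(p) <= 1.0

    def test_reduces_to_bh_when_pi0_is_one(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(size=80), rng.uniform(0, 1e-3, size=20)])
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=200)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])


class TestGroupSelection:
    def test_top_bottom_k_by_focal_abundance(self):
        ab = np.array([[5.0, 1.0, 4.0, 2.0, 3.0, 2.5]])
        m = make_matrix(ab, taxa=["f"], samples=list("abcdef"))
        g = select_extreme_groups(m, "f", k=2)
        assert set(g.high) == {"a", "c"}
        assert set(g.low) == {"b", "d"}

    def test_abundance_ties_break_by_sample_id(self):
        ab = np.array([[1.0, 1.0, 1.0, 1.0]])
        m = make_matrix(ab, taxa=["f"], samples=["s3", "s1", "s4", "s2"])
        g = select_extreme_groups(m, "f", k=2)
        assert set(g.high) == {"s1", "s2"}
        assert set(g.low) == {"s3", "s4"}


class TestDifferentialScreen:
    def test_single_taxon_one_record(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(1, 8)))
        g = pc.SampleGroups({s: ("high" if i < 4 else "low")
                             for i, s in enumerate(m.sample_ids)})
        res = differential_screen(m, groups=g)
        assert len(res) == 1 and res[0].taxon_id == "t0"

    def test_planted_effects_recovered_upward(self, default_matrix, default_dataset):
        """All planted hits should be more abundant in the high group."""
        _, _, _, truth = default_dataset
        res = differential_screen(default_matrix,
                                  focal_taxon_id=truth.focal_taxon_id, k=5)
        sig = [r for r in res if r.significant]
        assert sig, "screen found nothing on planted data"
        planted_sig = [r for r in sig if r.taxon_id in truth.effect_taxon_ids
                       and r.taxon_id not in truth.correlated_neg_ids]
        assert all(r.direction == "up" for r in planted_sig)

    def test_row_order_invariance(self, default_matrix, default_dataset):
        _, _, _, truth = default_dataset
        m = default_matrix
        perm = np.random.default_rng(0).permutation(len(m.taxon_ids))
        m2 = pc.TaxonAbundanceMatrix(
            [m.taxon_ids[i] for i in perm], list(m.sample_ids),
            m.abundance[perm], m.present[perm])
        r1 = {r.taxon_id: (r.statistic, r.q, r.significant)
              for r in differential_screen(m, focal_taxon_id=truth.focal_taxon_id)}
        r2 = {r.taxon_id: (r.statistic, r.q, r.significant)
              for r in differential_screen(m2, focal_taxon_id=truth.focal_taxon_id)}
        for t in r1:
            assert r1[t][0] == pytest.approx(r2[t][0], nan_ok=True)
            assert r1[t][2] == r2[t][2]

    def test_undersized_group_rejected(self, default_matrix):
        g = pc.SampleGroups({default_matrix.sample_ids[0]: "high"}
                            | {s: "low" for s in default_matrix.sample_ids[1:4]})
        with pytest.raises(ValueError, match="≥2 samples"):
            differential_screen(default_matrix, groups=g)


class TestCorrelationScreen:
    def test_focal_excluded_from_own_screen(self, default_matrix, default_dataset):
        _, _, _, truth = default_dataset
        res = correlation_screen(default_matrix, truth.focal_taxon_id)
        assert truth.focal_taxon_id not in {r.taxon_id for r in res}

    def test_anticorrelated_taxa_flagged_negative(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=12)
        ab = np.vstack([f, -f + rng.normal(0, 0.1, 12),
                        rng.normal(size=(10, 12))])
        m = make_matrix(ab)
        res = correlation_screen(m, "t0")
        rec = {r.taxon_id: r for r in res}
        assert rec["t1"].direction == "negative"
        assert rec["t1"].statistic < -0.9

    def test_planted_correlations_recovered_with_sign(self):
        """Sign-correct recovery of planted correlations across seeds."""
        sign_ok, total = 0, 0
        for seed in range(1, 11):
            cfg = pc.SimulationConfig(rng_seed=seed)
            _, table, truth = pc.simulate_dataset(cfg)
            m = pc.build_abundance_matrix(
                table, pc.call_presence(pc.positive_fraction(table), 0.9))
            rec = {r.taxon_id: r for r in correlation_screen(m, truth.focal_taxon_id)}
            for t in truth.correlated_pos_ids:
                if t in rec and not rec[t].excluded:
                    total += 1
                    sign_ok += rec[t].statistic > 0
            for t in truth.correlated_neg_ids:
                if t in rec and not rec[t].excluded:
                    total += 1
                    sign_ok += rec[t].statistic < 0
        assert sign_ok / total >= 0.9

    def test_zero_variance_taxon_excluded(self):
        rng = np.random.default_rng(9)
        ab = np.vstack([rng.normal(size=8), np.full(8, 3.0), rng.normal(size=8)])
        m = make_matrix(ab)
        res = correlation_screen(m, "t0")
        rec = {r.taxon_id: r for r in res}
        assert rec["t1"].excluded and not rec["t1"].significant
        assert not rec["t2"].excluded
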