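import itertools
import shutil
import subprocess

import networkx as nx
import numpy as np
import pytest

import phylocomm as pc
from phylocomm.io import tree_from_string
from phylocomm.phylo import (
    NullModelConfig,
    mntd,
    mpd,
    nri_nti,
    patristic_matrix,
    per_sample_phylo_metrics,
)


@pytest.fixture(scope="module")
def five_tip():
    tree = tree_from_string("((A:1,B:2):0.5,(C:0.3,(D:0.7,E:0.2):0.4):1.1);")
    return tree, patristic_matrix(tree)


class TestPatristic:
    def test_two_tip_distance(self):
        d = patristic_matrix(tree_from_string("(A:1,B:2);"))
        assert d.loc["A", "B"] == pytest.approx(3.0)

    def test_star_tree_all_pairs_equal(self):
        b = 0.7
        d = patristic_matrix(tree_from_string(f"(A:{b},B:{b},C:{b},D:{b});"))
        off = d.to_numpy()[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 2 * b)

    def test_matches_shortest_path_oracle(self):
        """Graph shortest-path distances over the tree's edges (networkx)."""
        tree = pc.simulate_tree(50, seed=13)
        g = nx.Graph()
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                g.add_edge(id(node), id(child), weight=child.edge.length)
        label_to_node = {l.taxon.label: id(l) for l in tree.leaf_node_iter()}
        d = patristic_matrix(tree)
        tips = list(d.index)[:15]
        for a, b in itertools.combinations(tips, 2):
            expect = nx.shortest_path_length(
                g, label_to_node[a], label_to_node[b], weight="weight")
            assert d.loc[a, b] == pytest.approx(expect, abs=1e-9)

    def test_unknown_tip_rejected(self, five_tip):
        tree, _ = five_tip
        with pytest.raises(KeyError):
            patristic_matrix(tree, ["A", "Z"])


class TestMpdMntd:
    def test_pair_community_both_equal_distance(self, five_tip):
        _, d = five_tip
        assert mpd(["A", "B"], d) == pytest.approx(d.loc["A", "B"])
        assert mntd(["A", "B"], d) == pytest.approx(d.loc["A", "B"])

    def test_hand_means(self):
        d = patristic_matrix(tree_from_string("((A:1,B:1):1,C:2);"))
        # pairwise: AB=2, AC=4, BC=4 -> MPD (2+4+4)/3; nearest: A->B 2, B->A 2, C->4
        assert mpd(["A", "B", "C"], d) == pytest.approx(10 / 3)
        assert mntd(["A", "B", "C"], d) == pytest.approx((2 + 2 + 4) / 3)

    def test_matches_picante_oracle(self, five_tip, tmp_path):
        """R picante's mpd/mntd on the same tree and community."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the picante cross-check")
        _, d = five_tip
        comm = ["A", "B", "D", "E"]
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(picante))\n'
            'tree <- read.tree(text="((A:1,B:2):0.5,(C:0.3,(D:0.7,E:0.2):0.4):1.1);")\n'
            'comm <- matrix(c(1,1,0,1,1), nrow=1,\n'
            '               dimnames=list("s1", c("A","B","C","D","E")))\n'
            'dd <- cophenetic(tree)\n'
            'cat(sprintf("%.10f %.10f", mpd(comm, dd), mntd(comm, dd)))\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        assert mpd(comm, d) == pytest.approx(float(out[0]), abs=1e-8)
        assert mntd(comm, d) == pytest.approx(float(out[1]), abs=1e-8)

    def test_mntd_never_exceeds_mpd(self):
        tree = pc.simulate_tree(30, seed=21)
        d = patristic_matrix(tree)
        rng = np.random.default_rng(0)
        for _ in range(20):
            comm = list(rng.choice(list(d.index), size=6, replace=False))
            assert mntd(comm, d) <= mpd(comm, d) + 1e-12

    def test_small_community_rejected(self, five_tip):
        _, d = five_tip
        with pytest.raises(ValueError):
            mpd(["A"], d)


class TestNriNti:
    def test_matches_exact_enumeration_oracle(self):
        """Monte-Carlo null moments vs exhaustive same-size subset enumeration."""
        tree = pc.simulate_tree(8, seed=3)
        d = patristic_matrix(tree)
        pool = list(d.index)
        comm = pool[:4]
        # exact null over all C(8,4) subsets
        mpds, mntds = [], []
        for sub in itertools.combinations(pool, 4):
            mpds.append(mpd(list(sub), d))
            mntds.append(mntd(list(sub), d))
        res = nri_nti(comm, d, pool, NullModelConfig(9999, rng_seed=1))
        # exact subset draws are without replacement within a draw but
        # independent across draws, so MC moments converge to the exact ones
        assert res.mpd_null_mean == pytest.approx(
            np.mean(mpds), abs=4 * np.std(mpds) / np.sqrt(9999))
        assert res.mntd_null_mean == pytest.approx(
            np.mean(mntds), abs=4 * np.std(mntds) / np.sqrt(9999))
        assert res.mpd_null_sd == pytest.approx(np.std(mpds, ddof=1), rel=0.1)
        assert res.mntd_null_sd == pytest.approx(np.std(mntds, ddof=1), rel=0.1)
        # z-scores agree with the exact-null z-scores
        z_mpd = -(res.mpd_obs - np.mean(mpds)) / np.std(mpds, ddof=1)
        assert res.nri == pytest.approx(z_mpd, abs=0.15)

    def test_branch_scaling_leaves_z_scores_unchanged(self):
        tree = pc.simulate_tree(30, seed=5)
        d = patristic_matrix(tree)
        comm = list(d.index)[:8]
        cfg = NullModelConfig(299, rng_seed=7)
        r1 = nri_nti(comm, d, list(d.index), cfg)
        r2 = nri_nti(comm, d * 3.0, list(d.index), cfg)
        assert r2.nri == pytest.approx(r1.nri, abs=1e-9)
        assert r2.nti == pytest.approx(r1.nti, abs=1e-9)
        assert r2.mpd_obs == pytest.approx(3 * r1.mpd_obs)
        assert r2.mntd_obs == pytest.approx(3 * r1.mntd_obs)

    def test_clade_community_is_clustered(self):
        # two long-stemmed clades: picking one clade is maximal clustering
        nwk = "((A:0.1,B:0.1,C:0.1,D:0.1):5,(E:0.1,F:0.1,G:0.1,H:0.1):5);"
        d = patristic_matrix(tree_from_string(nwk))
        res = nri_nti(["A", "B", "C", "D"], d, list(d.index),
                      NullModelConfig(999, rng_seed=2))
        assert res.nri > 0
        assert res.nti > 0

    def test_community_equal_to_pool_rejected(self, five_tip):
        _, d = five_tip
        with pytest.raises(ValueError):
            nri_nti(list(d.index), d, list(d.index))

    def test_deterministic_given_seed(self, five_tip):
        _, d = five_tip
        cfg = NullModelConfig(199, rng_seed=42)
        a = nri_nti(["A", "B", "D"], d, list(d.index), cfg)
        b = nri_nti(["A", "B", "D"], d, list(d.index), cfg)
        assert (a.nri, a.nti) == (b.nri, b.nti)


class TestPerSample:
    def test_matrix_taxon_missing_from_tree_is_hard_error(self, default_matrix):
        small = tree_from_string("(A:1,B:1);")
        with pytest.raises(KeyError):
            per_sample_phylo_metrics(default_matrix, small)

    def test_extra_tree_tips_are_pruned(self):
        tree = pc.simulate_tree(40, seed=2)
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        rng = np.random.default_rng(0)
        n_t, n_s = 20, 6
        present = rng.random((n_t, n_s)) < 0.6
        present[:, 0] = True  # every taxon detected somewhere
        m = pc.TaxonAbundanceMatrix(tips[:n_t], [f"s{j}" for j in range(n_s)],
                                    rng.normal(7, 1, (n_t, n_s)), present)
        df = per_sample_phylo_metrics(m, tree, NullModelConfig(99, rng_seed=0))
        assert list(df.index) == m.sample_ids
        finite = df.dropna()
        # random-ish subsets of the pool should rarely leave |z| > 3
        assert (finite[["nri", "nti"]].abs() < 4).all().all()
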