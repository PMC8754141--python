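"""Rarefaction and the four alpha-diversity indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microbiogeo.alpha import (faith_pd, nti, rarefaction_curve, rarefy,
                               richness, shannon)
from microbiogeo.io import read_tree_string
from microbiogeo.simulate import simulate_tree
from microbiogeo.types import OTUTable, ValidationError

from conftest import random_table


class TestRarefy:
    def test_identity_at_exact_depth(self, small_table):
        out = rarefy(small_table, 4, seed=1)
        np.testing.assert_array_equal(out.counts[0], small_table.counts[0])

    def test_depth_one(self, small_table):
        out = rarefy(small_table, 1, seed=2)
        assert (out.sample_totals() == 1).all()
        assert ((out.counts > 0).sum(axis=1) == 1).all()

    def test_rows_sum_exactly_to_depth(self, rng):
        t = random_table(rng, 6, 30, max_count=50)
        depth = int(t.sample_totals().min())
        out = rarefy(t, depth, seed=3)
        assert (out.sample_totals() == depth).all()

    def test_small_samples_dropped_with_warning(self, caplog):
        t = OTUTable(np.array([[10, 10], [1, 0]]), ["big", "small"], ["A", "B"])
        with caplog.at_level("WARNING"):
            out = rarefy(t, 5, seed=4)
        assert out.sample_ids == ["big"]
        assert "small" in caplog.text

    def test_invalid_depth(self, small_table):
        with pytest.raises(ValidationError):
            rarefy(small_table, 0)

    def test_hypergeometric_mean(self):
        """Subsampling (60, 40) to depth 10: mean count of OTU1 is 6."""
        t = OTUTable(np.array([[60, 40]]), ["S"], ["A", "B"])
        draws = np.array([rarefy(t, 10, seed=s).counts[0, 0] for s in range(5000)])
        # hypergeometric: mean 6, var 10*(0.6)*(0.4)*(90/99)
        se = np.sqrt(10 * 0.6 * 0.4 * 90 / 99 / 5000)
        assert abs(draws.mean() - 6.0) < 3 * se


class TestRarefactionCurve:
    def test_full_depth_recovers_observed_richness(self, small_table):
        depth = int(small_table.sample_totals().min())
        curve = rarefaction_curve(small_table, [depth], reps=5, seed=5)
        for i, sid in enumerate(small_table.sample_ids):
            if small_table.sample_totals()[i] == depth:
                assert curve.loc[sid, depth] == richness(small_table.counts[i])

    def test_single_otu_sample_flat_at_one(self):
        t = OTUTable(np.array([[50, 0]]), ["S"], ["A", "B"])
        curve = rarefaction_curve(t, [1, 10, 50], reps=3, seed=6)
        assert (curve.loc["S"] == 1.0).all()

    def test_monotone_and_concave_in_expectation(self, rng):
        t = random_table(rng, 20, 40, max_count=10)
        depths = [5, 10, 20, 40]
        curve = rarefaction_curve(t, depths, reps=20, seed=7).dropna()
        diffs = curve.to_numpy()[:, 1:] - curve.to_numpy()[:, :-1]
        assert (diffs >= -1e-9).all()
        # mean increment per additional read shrinks with depth
        per_read = diffs / np.diff(depths)
        assert per_read[:, 0].mean() > per_read[:, -1].mean()

    def test_excess_depth_reported_missing(self, small_table):
        curve = rarefaction_curve(small_table, [3, 1000], reps=2, seed=8)
        assert curve[1000].isna().all()


class TestRichnessShannon:
    def test_richness_examples(self):
        assert richness([3, 0, 1]) == 2
        assert richness([0, 0]) == 0

    def test_richness_never_increases_under_rarefaction(self, rng):
        for _ in range(20):
            t = random_table(rng, 3, 15, max_count=8)
            depth = max(1, int(t.sample_totals().min()) // 2)
            out = rarefy(t, depth, seed=9)
            for sid in out.sample_ids:
                i, j = out.sample_ids.index(sid), t.sample_ids.index(sid)
                assert richness(out.counts[i]) <= richness(t.counts[j])

    def test_shannon_closed_forms(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(2.0)
        assert shannon([10, 0, 0]) == pytest.approx(0.0)
        assert shannon([1, 1, 2]) == pytest.approx(1.5)
        assert shannon([1, 1], base=np.e) == pytest.approx(np.log(2))

    def test_shannon_all_zero_undefined(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])

    @settings(max_examples=50, deadline=None)
    @given(counts=st.lists(st.integers(0, 100), min_size=1, max_size=20))
    def test_shannon_bounded_by_log_richness(self, counts):
        if sum(counts) == 0:
            return
        h = shannon(counts)
        s = richness(counts)
        assert h <= np.log2(s) + 1e-9
        if s > 0 and len({c for c in counts if c > 0}) == 1:
            assert h == pytest.approx(np.log2(s))


class TestFaithPD:
    def test_worked_example(self, three_tip_tree):
        assert faith_pd([1, 1, 0], ["A", "B", "C"], three_tip_tree) == pytest.approx(3.0)
        assert faith_pd([1, 1, 1], ["A", "B", "C"], three_tip_tree) == pytest.approx(5.0)

    def test_whole_tree_equals_total_branch_length(self):
        tree = simulate_tree(25, seed=10)
        total = sum(e.length or 0.0 for e in tree.tree.preorder_edge_iter()
                    if e.head_node is not tree.tree.seed_node)
        counts = np.ones(25)
        assert faith_pd(counts, tree.tip_labels, tree) == pytest.approx(total)

    def test_monotone_when_adding_taxa(self, rng):
        for rep in range(20):
            tree = simulate_tree(10, seed=100 + rep)
            present = np.zeros(10)
            order = rng.permutation(10)
            last = 0.0
            for k in order[:5]:
                present[k] = 1
                cur = faith_pd(present, tree.tip_labels, tree)
                assert cur >= last - 1e-12
                last = cur

    def test_matches_scikit_bio(self):
        """Independent cross-check against skbio's Faith's PD."""
        from io import StringIO
        from skbio import TreeNode
        from skbio.diversity.alpha import faith_pd as skbio_pd
        tree = simulate_tree(15, seed=11)
        sk_tree = TreeNode.read(StringIO(tree.as_newick()))
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.integers(0, 3, 15)
            if counts.sum() == 0:
                continue
            expected = skbio_pd(counts, taxa=tree.tip_labels, tree=sk_tree)
            assert faith_pd(counts, tree.tip_labels, tree) == pytest.approx(expected)

    def test_missing_otu_rejected(self, three_tip_tree):
        with pytest.raises(ValidationError, match="not in tree"):
            faith_pd([1], ["Z"], three_tip_tree)


class TestNTI:
    def test_two_taxon_mntd_is_their_distance(self, three_tip_tree):
        t = OTUTable(np.array([[1, 0, 1], [1, 1, 0]]), ["S1", "S2"], ["A", "B", "C"])
        res = nti(t, three_tip_tree, n_rand=99, seed=12)
        assert res.loc["S1", "mntd_obs"] == pytest.approx(4.0)  # d(A, C)
        assert res.loc["S2", "mntd_obs"] == pytest.approx(2.0)  # d(A, B)

    def test_full_pool_sample_undefined(self, three_tip_tree):
        t = OTUTable(np.array([[1, 1, 1]]), ["S1"], ["A", "B", "C"])
        res = nti(t, three_tip_tree, n_rand=99, seed=13)
        assert np.isnan(res.loc["S1", "nti"])

    def test_single_taxon_sample_missing(self, three_tip_tree):
        t = OTUTable(np.array([[1, 0, 0]]), ["S1"], ["A", "B", "C"])
        res = nti(t, three_tip_tree, n_rand=99, seed=14)
        assert np.isnan(res.loc["S1", "nti"])

    def test_clustered_sample_scores_positive(self):
        """Taxa confined to one clade are closer than random draws: NTI > 0."""
        tree = simulate_tree(40, seed=15)
        coph = tree.cophenetic()
        # pick the 8 tips closest to tip 0 — a tight phylogenetic cluster
        closest = coph.iloc[0].nsmallest(8).index
        counts = np.array([[1 if o in set(closest) else 0 for o in tree.tip_labels]])
        t = OTUTable(counts, ["S"], tree.tip_labels)
        res = nti(t, tree, n_rand=199, seed=16)
        assert res.loc["S", "nti"] > 2

    def test_random_draws_calibrate_to_zero_mean(self):
        """Communities drawn uniformly from the pool have mean NTI near 0."""
        tree = simulate_tree(30, seed=17)
        rng = np.random.default_rng(18)
        rows = []
        for _ in range(500):
            counts = np.zeros(30, dtype=int)
            counts[rng.choice(30, size=10, replace=False)] = 1
            rows.append(counts)
        t = OTUTable(np.array(rows), [f"S{i}" for i in range(500)], tree.tip_labels)
        res = nti(t, tree, n_rand=199, seed=19)
        assert abs(res["nti"].mean()) < 0.1
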