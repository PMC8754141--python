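"""Bray-Curtis, ordination, and the permutation statistics, with independent
oracles (exhaustive enumeration, scikit-bio, scipy) for each."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microbiogeo.beta import (anosim, bray_curtis, env_pca, mantel, pcoa,
                              procrustes_protest, rank_sum_test,
                              spearman_fdr_matrix)
from microbiogeo.types import DistanceMatrix, OTUTable, ValidationError

from conftest import random_table


def euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    ids = ids or [f"S{i}" for i in range(len(points))]
    return DistanceMatrix(d, ids)


class TestBrayCurtis:
    @pytest.mark.parametrize("x,y,expected", [
        ((1, 0), (0, 1), 1.0),
        ((3, 2), (3, 2), 0.0),
        ((2, 2), (1, 3), 0.25),
    ])
    def test_closed_forms(self, x, y, expected):
        t = OTUTable(np.array([x, y]), ["a", "b"], ["O1", "O2"])
        assert bray_curtis(t).values[0, 1] == pytest.approx(expected)

    def test_all_zero_sample_named(self):
        t = OTUTable(np.array([[1, 1], [0, 0]]), ["ok", "empty"], ["O1", "O2"])
        with pytest.raises(ValidationError, match="empty"):
            bray_curtis(t)

    def test_range_and_symmetry(self, rng):
        t = random_table(rng, 8, 20)
        bc = bray_curtis(t)
        assert ((bc.values >= 0) & (bc.values <= 1)).all()


class TestPCoA:
    def test_collinear_points_have_one_axis(self):
        dm = euclidean_dm([[0.0], [1.0], [2.0]])
        res = pcoa(dm)
        assert res.proportion_explained[0] == pytest.approx(1.0)
        assert res.coordinates.shape[1] == 1

    def test_reconstructs_euclidean_distances(self, rng):
        pts = rng.random((5, 3))
        dm = euclidean_dm(pts)
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d, dm.values, atol=1e-8)

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        res = pcoa(euclidean_dm(pts))
        np.testing.assert_allclose(res.coordinates.iloc[1], res.coordinates.iloc[2],
                                   atol=1e-10)

    def test_matches_scikit_bio_eigenvalues(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.ordination import pcoa as sk_pcoa
        t = random_table(rng, 6, 25)
        bc = bray_curtis(t)
        ours = pcoa(bc)
        theirs = sk_pcoa(SkDM(bc.values, bc.ids), method="eigh")
        np.testing.assert_allclose(np.sort(ours.eigenvalues)[::-1][:5],
                                   np.sort(theirs.eigvals.to_numpy())[::-1][:5],
                                   atol=1e-10)


class TestANOSIM:
    def test_perfect_separation_gives_r_one(self):
        pts = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        dm = euclidean_dm(pts)
        groups = dict(zip(dm.ids, "AAABBB"))
        res = anosim(dm, groups, n_perm=199, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim
        t = random_table(rng, 9, 30)
        bc = bray_curtis(t)
        groups = dict(zip(bc.ids, "AAABBBCCC"))
        ours = anosim(bc, groups, n_perm=99, seed=2)
        theirs = sk_anosim(SkDM(bc.values, bc.ids),
                           [groups[s] for s in bc.ids], permutations=0)
        assert ours.statistic == pytest.approx(theirs["test statistic"])

    def test_null_r_centers_on_zero(self, rng):
        pts = rng.random((10, 3))
        dm = euclidean_dm(pts)
        stats_ = []
        for rep in range(300):
            labels = rng.permutation(list("AAAAABBBBB"))
            res = anosim(dm, dict(zip(dm.ids, labels)), n_perm=99, seed=rep)
            stats_.append(res.statistic)
        assert abs(np.mean(stats_)) < 0.05

    def test_p_matches_exhaustive_enumeration(self, rng):
        """n=6, two groups of 3: all C(6,3)=20 label assignments enumerable."""
        pts = rng.random((6, 2))
        dm = euclidean_dm(pts)
        labels = np.array(list("AAABBB"))
        res = anosim(dm, dict(zip(dm.ids, labels)), n_perm=9999, seed=3)
        # oracle: exhaustive R over all distinct assignments
        iu = np.triu_indices(6, k=1)
        ranks = stats.rankdata(dm.values[iu])
        denom = 6 * 5 / 4

        def r_of(lab):
            within = lab[iu[0]] == lab[iu[1]]
            return (ranks[~within].mean() - ranks[within].mean()) / denom

        obs = r_of(labels)
        null = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["B"] * 6)
            for i in combo:
                lab[i] = "A"
            null.append(r_of(lab))
        exact_p = np.mean([r >= obs - 1e-12 for r in null])
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_group_of_one_rejected(self):
        dm = euclidean_dm(np.random.default_rng(0).random((4, 2)))
        with pytest.raises(ValidationError, match="size 1"):
            anosim(dm, dict(zip(dm.ids, "AAAB")), n_perm=99)

    def test_invariants(self, rng):
        t = random_table(rng, 8, 15)
        res = anosim(bray_curtis(t), dict(zip([f"S{i}" for i in range(8)],
                                              "AAAABBBB")), n_perm=199, seed=4)
        assert -1.0 <= res.statistic <= 1.0
        assert 0.0 < res.p_value <= 1.0


class TestProcrustes:
    def test_transformed_copy_has_zero_residual(self, rng):
        a = rng.random((10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        b = 3.0 * a @ rot + np.array([5.0, -2.0])
        res = procrustes_protest(a, b, n_perm=99, seed=5)
        assert res.statistic <= 1e-12
        assert res.p_value <= 0.05

    def test_independent_configurations_not_significant(self, rng):
        ps = []
        for rep in range(10):
            a = rng.standard_normal((30, 2))
            b = rng.standard_normal((30, 2))
            ps.append(procrustes_protest(a, b, n_perm=199, seed=rep).p_value)
        assert np.median(ps) > 0.05

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.random((12, 2)), rng.random((12, 2))
        m1 = procrustes_protest(a, b, n_perm=99, seed=6).statistic
        m2 = procrustes_protest(b, a, n_perm=99, seed=6).statistic
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_matches_scipy_disparity(self, rng):
        from scipy.spatial import procrustes as scipy_procrustes
        a, b = rng.random((8, 2)), rng.random((8, 2))
        _, _, disparity = scipy_procrustes(a, b)
        ours = procrustes_protest(a, b, n_perm=99, seed=7).statistic
        assert ours == pytest.approx(disparity, rel=1e-9)


class TestMantel:
    def test_proportional_matrices_give_r_one(self, rng):
        d1 = euclidean_dm(rng.random((6, 2)))
        d2 = DistanceMatrix(2.0 * d1.values, d1.ids)
        res = mantel(d1, d2, correlation="pearson", n_perm=99, seed=8)
        assert res.statistic == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration(self, rng):
        """n=6: all 720 joint row/column relabelings enumerable."""
        d1 = euclidean_dm(rng.random((6, 2)))
        d2 = euclidean_dm(rng.random((6, 2)), ids=d1.ids)
        res = mantel(d1, d2, correlation="pearson", n_perm=9999, seed=9)
        iu = np.triu_indices(6, k=1)
        x = d1.values[iu]

        def corr(perm):
            y = d2.values[np.ix_(perm, perm)][iu]
            return np.corrcoef(x, y)[0, 1]

        obs = corr(np.arange(6))
        null = [corr(np.array(p)) for p in itertools.permutations(range(6))]
        exact_p = np.mean([r >= obs - 1e-12 for r in null])
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_statistic_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM, mantel as sk_mantel
        d1 = euclidean_dm(rng.random((8, 3)))
        d2 = euclidean_dm(rng.random((8, 3)), ids=d1.ids)
        for corr in ("pearson", "spearman"):
            ours = mantel(d1, d2, correlation=corr, n_perm=99, seed=10)
            result = sk_mantel(SkDM(d1.values, d1.ids), SkDM(d2.values, d2.ids),
                               method=corr, permutations=0)
            theirs = result[0] if isinstance(result, tuple) else result.statistic
            assert ours.statistic == pytest.approx(float(theirs), rel=1e-9)

    def test_constant_matrix_flagged(self):
        ids = list("abcd")
        ones = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValidationError, match="constant"):
            mantel(DistanceMatrix(ones, ids), DistanceMatrix(ones * 2, ids),
                   correlation="pearson", n_perm=99)


class TestRankSum:
    def test_tiny_exact_case(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res.statistic == 0  # U of first sample
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_matches_enumeration(self, rng):
        """n=m=5: enumerate all C(10,5)=252 group assignments."""
        x = rng.standard_normal(5)
        y = rng.standard_normal(5)
        res = rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs_u = ranks[:5].sum() - 5 * 6 / 2
        null_u = []
        for combo in itertools.combinations(range(10), 5):
            u = ranks[list(combo)].sum() - 5 * 6 / 2
            null_u.append(u)
        null_u = np.array(null_u)
        dev = np.abs(null_u - 12.5)  # |U - n*m/2|
        exact_p = np.mean(dev >= abs(obs_u - 12.5) - 1e-12)
        assert res.p_value == pytest.approx(exact_p, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])

    def test_paired_variant_runs(self):
        res = rank_sum_test([1.0, 2.0, 3.0, 5.0], [2.0, 3.0, 4.0, 7.0], paired=True)
        assert res.statistic_name.startswith("Wilcoxon signed-rank")


class TestSpearmanFDR:
    def test_monotone_pair_has_rho_one(self, rng):
        x = rng.random(20)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        rho, _ = spearman_fdr_matrix(df)
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_bh_closed_form(self):
        from scipy.stats import false_discovery_control
        adj = false_discovery_control([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw(self, rng):
        df = pd.DataFrame(rng.random((15, 5)), columns=list("abcde"))
        rho, padj = spearman_fdr_matrix(df)
        for i, a in enumerate("abcde"):
            for b in "abcde"[i + 1:]:
                raw = stats.spearmanr(df[a], df[b]).pvalue
                assert padj.loc[a, b] >= raw - 1e-12

    def test_constant_variable_flagged_nan(self, rng):
        df = pd.DataFrame({"a": rng.random(10), "b": np.ones(10)})
        rho, padj = spearman_fdr_matrix(df)
        assert np.isnan(rho.loc["a", "b"]) and np.isnan(padj.loc["a", "b"])

    def test_mask_hides_nonsignificant(self, rng):
        df = pd.DataFrame(rng.random((12, 3)), columns=list("abc"))
        rho, padj = spearman_fdr_matrix(df, mask_nonsignificant=True)
        hidden = padj >= 0.05
        assert rho.to_numpy()[hidden.to_numpy()].size == np.isnan(
            rho.to_numpy()[hidden.to_numpy()]).sum()


class TestEnvPCA:
    def test_perfectly_correlated_variables(self, rng):
        x = rng.random(10)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = env_pca(df)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_scores_orthogonal(self, rng):
        df = pd.DataFrame(rng.random((20, 4)), columns=list("abcd"))
        res = env_pca(df)
        scores = res.coordinates.to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_constant_column_named(self, rng):
        df = pd.DataFrame({"a": rng.random(5), "flat": np.ones(5)})
        with pytest.raises(ValidationError, match="flat"):
            env_pca(df)
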