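"""Beta-diversity structure: Bray-Curtis, PCoA, and permutation statistics.

Permutation p-values everywhere follow the vegan convention
``(exceedances + 1) / (n_perm + 1)`` (one-sided for ANOSIM, Mantel, and
PROTEST), so a permutation test never reports exactly zero. Ties in ranks are
handled with average ranks throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .types import (DistanceMatrix, OrdinationResult, OTUTable,
                    PermutationTestResult, ValidationError, permutation_p)

__all__ = ["bray_curtis", "pcoa", "anosim", "procrustes_protest", "mantel",
           "rank_sum_test", "spearman_fdr_matrix", "env_pca"]


def bray_curtis(table: OTUTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValidationError(f"all-zero sample(s): {bad}")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, list(table.sample_ids))


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by Gower centering of -D^2/2.

    Coordinates are eigenvectors scaled by the square root of their (positive)
    eigenvalues; negative eigenvalues are reported in ``eigenvalues`` but are
    not corrected and do not enter ``proportion_explained``.
    """
    d = dm.values
    n = dm.n
    b = -0.5 * d ** 2
    center = np.eye(n) - np.ones((n, n)) / n
    g = center @ b @ center
    evals, evecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12 if evals.max() > 0 else evals > 0
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=cols),
        eigenvalues=evals,
        proportion_explained=prop[: coords.shape[1]],
    )


def _group_masks(ids, groups) -> np.ndarray:
    labels = np.asarray([groups[s] for s in ids])
    return labels


def anosim(dm: DistanceMatrix, groups, n_perm: int = 9999,
           seed: int | None = None) -> PermutationTestResult:
    """Analysis of similarities: R = (rb - rw) / (N(N-1)/4) on ranked distances.

    ``groups`` maps sample id -> label (a mapping or pandas Series). p-value is
    one-sided (greater), permuting group labels.
    """
    labels = _group_masks(dm.ids, groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValidationError(f"group(s) of size 1: {small}")
    n = dm.n
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.values[iu])  # average ranks on ties
    denom = n * (n - 1) / 4.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = r_stat(labels[rng.permutation(n)])
    p = permutation_p(null, observed, alternative="greater")
    return PermutationTestResult(statistic=float(observed), n_permutations=n_perm,
                                 p_value=p, statistic_name="ANOSIM R")


def _procrustes_m2(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Procrustes residual: both centered and unit-trace scaled."""
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(max(1.0 - s.sum() ** 2, 0.0))


def _center_scale(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0)
    norm = np.sqrt((x ** 2).sum())
    if norm == 0:
        raise ValidationError("degenerate configuration (all points identical)")
    return x / norm


def procrustes_protest(coords_a, coords_b, n_perm: int = 999,
                       seed: int | None = None) -> PermutationTestResult:
    """Symmetric Procrustes M^2 with PROTEST permutation significance.

    Both configurations are centered and scaled to unit trace; M^2 is the
    residual sum of squares after optimal rotation/reflection, in [0, 1], and
    is symmetric in its arguments. The p-value permutes the rows of the second
    configuration (one-sided, small M^2 = concordance).
    """
    a_df = isinstance(coords_a, pd.DataFrame)
    b_df = isinstance(coords_b, pd.DataFrame)
    if a_df and b_df:
        if set(coords_a.index) != set(coords_b.index):
            raise ValidationError("configurations cover different samples")
        coords_b = coords_b.loc[coords_a.index]
    a = _center_scale(coords_a.to_numpy() if a_df else coords_a)
    b = _center_scale(coords_b.to_numpy() if b_df else coords_b)
    if a.shape[0] != b.shape[0]:
        raise ValidationError("configurations have different numbers of samples")
    observed = _procrustes_m2(a, b)
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _procrustes_m2(a, b[rng.permutation(n)])
    p = permutation_p(-null, -observed, alternative="greater")
    return PermutationTestResult(statistic=observed, n_permutations=n_perm,
                                 p_value=p, statistic_name="Procrustes M2")


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, correlation: str = "spearman",
           n_perm: int = 9999, seed: int | None = None) -> PermutationTestResult:
    """Mantel correlation between two distance matrices over lower-triangle pairs.

    One-sided (greater) p-value from joint row/column permutations of the
    second matrix. Spearman by default.
    """
    if d1.ids != d2.ids:
        if set(d1.ids) != set(d2.ids):
            raise ValidationError("matrices have different ids")
        d2 = d2.reorder(d1.ids)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    if correlation == "spearman":
        x_r = stats.rankdata(x)
        # ranks of d2's triangle entries, placed back in square form: a joint
        # row/column permutation permutes which entries form the triangle, and
        # the rank of each entry is unchanged, so ranks can be precomputed.
        y_rank_sq = squareform(stats.rankdata(d2.values[iu]))
        y_sq = y_rank_sq
        y = y_rank_sq[iu]
    elif correlation == "pearson":
        x_r = x
        y_sq = d2.values
        y = y_sq[iu]
    else:
        raise ValueError("correlation must be 'spearman' or 'pearson'")
    if np.std(x_r) == 0 or np.std(y) == 0:
        raise ValidationError("constant triangle: Mantel statistic undefined")

    def corr(xv, yv):
        xv = xv - xv.mean()
        yv = yv - yv.mean()
        return float(xv @ yv / np.sqrt((xv @ xv) * (yv @ yv)))

    observed = corr(x_r, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = corr(x_r, y_sq[perm[:, None], perm[None, :]][iu])
    p = permutation_p(null, observed, alternative="greater")
    name = f"Mantel r ({correlation})"
    return PermutationTestResult(statistic=observed, n_permutations=n_perm,
                                 p_value=p, statistic_name=name)


def rank_sum_test(x, y, paired: bool = False) -> PermutationTestResult:
    """Two-sided rank-based comparison of two samples.

    Unpaired by default (Mann-Whitney/Wilcoxon rank-sum, W = U of the first
    sample), exact for small tie-free samples and a tie- and
    continuity-corrected normal approximation otherwise. ``paired=True`` runs
    the Wilcoxon signed-rank test instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("empty input")
    if paired:
        res = stats.wilcoxon(x, y)
        return PermutationTestResult(statistic=float(res.statistic),
                                     n_permutations=0, p_value=float(res.pvalue),
                                     statistic_name="Wilcoxon signed-rank W")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return PermutationTestResult(statistic=float(res.statistic), n_permutations=0,
                                 p_value=float(res.pvalue),
                                 statistic_name="rank-sum W")


def spearman_fdr_matrix(variables: pd.DataFrame, alpha: float = 0.05,
                        mask_nonsignificant: bool = False):
    """Pairwise Spearman rho with Benjamini-Hochberg adjustment across pairs.

    Returns ``(rho, p_adjusted)`` DataFrames. Constant variables give NaN for
    their pairs. With ``mask_nonsignificant``, rho cells whose adjusted p is
    >= ``alpha`` are set to NaN (the heatmap convention).
    """
    cols = list(variables.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    praw = {}
    for i in range(k):
        for j in range(i + 1, k):
            xi = variables[cols[i]].to_numpy(dtype=float)
            yj = variables[cols[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(xi) | np.isnan(yj))
            if ok.sum() < 3 or np.std(xi[ok]) == 0 or np.std(yj[ok]) == 0:
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                praw[(i, j)] = np.nan
                continue
            r, p = stats.spearmanr(xi[ok], yj[ok])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            praw[(i, j)] = p
    pairs = [ij for ij, p in praw.items() if not np.isnan(p)]
    padj_mat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    if pairs:
        adj = stats.false_discovery_control([praw[ij] for ij in pairs], method="bh")
        for (i, j), p in zip(pairs, adj):
            padj_mat.iloc[i, j] = padj_mat.iloc[j, i] = p
    for (i, j), p in praw.items():
        if np.isnan(p):
            padj_mat.iloc[i, j] = padj_mat.iloc[j, i] = np.nan
    if mask_nonsignificant:
        rho = rho.mask(padj_mat >= alpha)
    return rho, padj_mat


def env_pca(env_table: pd.DataFrame) -> OrdinationResult:
    """PCA of Z-score standardized environmental variables (correlation PCA)."""
    if env_table.shape[1] < 2 or env_table.shape[0] < 3:
        raise ValidationError("PCA needs >= 2 variables and >= 3 samples")
    x = env_table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(env_table.columns, sd) if s == 0]
        raise ValidationError(f"constant column(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    evals = s ** 2 / (z.shape[0] - 1)
    scores = u * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(scores, index=env_table.index, columns=cols),
        eigenvalues=evals,
        proportion_explained=evals / evals.sum(),
    )
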