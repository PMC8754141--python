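"""Rarefaction and per-sample diversity: richness, Shannon, Faith's PD, NTI.

Conventions follow the QIIME-1 / picante toolchain this analysis style grew up
with: Shannon in bits (log base 2, configurable), Faith's PD including the
branches that connect the present-taxa subtree to the root (configurable), and
NTI as the negated z-score of mean nearest-taxon distance against ``n_rand``
unconstrained shuffles of tip labels, so phylogenetically clustered samples
score positive. Undefined values propagate as NaN, never as 0.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .types import OTUTable, PhyloTree, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["rarefy", "rarefaction_curve", "richness", "shannon", "faith_pd",
           "nti", "alpha_table"]


def rarefy(table: OTUTable, depth: int, seed: int | None = None,
           prune_empty_otus: bool = False) -> OTUTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped with a logged warning.
    All-zero OTU columns are retained unless ``prune_empty_otus``.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) with < %d reads: %s",
                       len(dropped), depth, dropped)
    if not keep.any():
        raise ValidationError(f"no sample has >= {depth} reads")
    rows = []
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            rows.append(table.counts[i].copy())
        else:
            rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
    counts = np.vstack(rows)
    out = OTUTable(counts, [s for s, k in zip(table.sample_ids, keep) if k],
                   list(table.otu_ids))
    if prune_empty_otus:
        nonzero = out.counts.sum(axis=0) > 0
        out = out.select_otus([o for o, nz in zip(out.otu_ids, nonzero) if nz])
    return out


def rarefaction_curve(table: OTUTable, depths: list[int], reps: int = 10,
                      seed: int | None = None) -> pd.DataFrame:
    """Mean observed richness per sample at each depth over ``reps`` subsamples.

    Depths exceeding a sample's total are reported as NaN for that sample.
    """
    if sorted(depths) != list(depths):
        raise ValidationError("depths must be sorted ascending")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    out = pd.DataFrame(index=table.sample_ids, columns=depths, dtype=float)
    for i, sid in enumerate(table.sample_ids):
        for depth in depths:
            if depth > totals[i]:
                continue  # leaves NaN
            vals = [richness(rng.multivariate_hypergeometric(table.counts[i], depth))
                    for _ in range(reps)]
            out.loc[sid, depth] = float(np.mean(vals))
    return out


def richness(counts) -> int:
    """Number of OTUs with a positive count."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i (0 log 0 := 0)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("Shannon is undefined for an all-zero sample")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _edge_tip_sets(tree: PhyloTree) -> list[tuple[float, frozenset[str]]]:
    """(branch length, set of tip labels below) for every non-root edge."""
    out = []
    for node in tree.tree.postorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        out.append((float(node.edge.length or 0.0), tips))
    return out


def faith_pd(counts, otu_ids: list[str], tree: PhyloTree,
             include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of the taxa with positive counts.

    Sum of branch lengths of the union of root-to-tip paths of the present
    taxa. With ``include_root=False`` only the subtree spanning the present
    taxa (below their most recent common ancestor) is summed.
    """
    c = np.asarray(counts)
    present = {o for o, v in zip(otu_ids, c) if v > 0}
    if not present:
        return 0.0
    missing = present - set(tree.tip_labels)
    if missing:
        raise ValidationError(f"present OTU(s) not in tree: {sorted(missing)}")
    total = 0.0
    for length, tips in _edge_tip_sets(tree):
        k = len(tips & present)
        if k == 0:
            continue
        if not include_root and k == len(present):
            continue  # edge on or above the MRCA of the present taxa
        total += length
    return total


def _mntd_from_sub(sub: np.ndarray, weights: np.ndarray | None) -> float:
    """MNTD given the present-taxa cophenetic submatrix (k x k, k >= 2)."""
    d = sub.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    if weights is None:
        return float(nearest.mean())
    w = weights / weights.sum()
    return float(nearest @ w)


def nti(table: OTUTable, tree: PhyloTree, n_rand: int = 999,
        weighted: bool = False, seed: int | None = None) -> pd.DataFrame:
    """Nearest taxon index per sample against tip-label shuffles.

    NTI = -(MNTD_obs - mean_null) / sd_null; positive values mean the present
    taxa are phylogenetically closer to one another than random draws from the
    taxon pool. Samples with fewer than two present OTUs, or a degenerate null
    (sd = 0, e.g. a sample containing the whole pool), get NaN.
    """
    coph = tree.cophenetic()
    pool = [o for o in table.otu_ids if o in set(tree.tip_labels)]
    if len(pool) != len(table.otu_ids):
        raise ValidationError("table contains OTUs missing from the tree; align first")
    D = coph.loc[pool, pool].to_numpy()
    n = len(pool)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_rand)])

    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        idx = np.flatnonzero(c > 0)
        if idx.size < 2:
            rows.append((sid, np.nan, np.nan, np.nan, np.nan, n_rand))
            continue
        w = c[idx].astype(float) if weighted else None
        obs = _mntd_from_sub(D[np.ix_(idx, idx)], w)
        null = np.empty(n_rand)
        for b in range(n_rand):
            jdx = perms[b][idx]
            null[b] = _mntd_from_sub(D[np.ix_(jdx, jdx)], w)
        mu, sd = null.mean(), null.std(ddof=1)
        degenerate = sd <= 1e-12 * max(abs(mu), 1.0)
        z = np.nan if degenerate else -(obs - mu) / sd
        rows.append((sid, obs, z, mu, sd, n_rand))
    return pd.DataFrame(rows, columns=["sample_id", "mntd_obs", "nti",
                                       "nti_null_mean", "nti_null_sd",
                                       "n_randomizations"]).set_index("sample_id")


def alpha_table(table: OTUTable, tree: PhyloTree | None = None,
                n_rand: int = 999, seed: int | None = None,
                shannon_base: float = 2.0) -> pd.DataFrame:
    """Richness, Shannon, and (when a tree is given) Faith's PD and NTI per sample."""
    rows = {"richness": [], "shannon": []}
    for i in range(table.n_samples):
        rows["richness"].append(richness(table.counts[i]))
        rows["shannon"].append(shannon(table.counts[i], base=shannon_base))
    out = pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample_id"))
    if tree is not None:
        out["pd"] = [faith_pd(table.counts[i], table.otu_ids, tree)
                     for i in range(table.n_samples)]
        out = out.join(nti(table, tree, n_rand=n_rand, seed=seed))
    return out
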