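"""Validation utilities for the null models and permutation tests.

These routines answer two questions a practitioner should ask before trusting
a null-model analysis on real data: (1) do the nulls self-calibrate — data
generated by a null model should exceed that null's own significance threshold
at roughly the nominal rate — and (2) do the permutation tests hold their
type-I error under true null data. They are used by the acceptance checks and
are exported for users who want to rerun them at other problem sizes.

All routines take a single integer seed and are deterministic given it.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .assembly import (beta_nti, classify_pairs, rc_bray, rc_null_communities,
                       summarize_fractions)
from .beta import anosim, bray_curtis, mantel, pcoa, procrustes_protest
from .decay import diff_slope_test, fit_distance_decay, haversine_matrix
from .simulate import ScenarioParams, scenario_preset, simulate_dataset, simulate_tree
from .types import DistanceMatrix, OTUTable


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# null self-calibration
# ---------------------------------------------------------------------------

def bnti_self_calibration(n_reps: int = 200, n_rand: int = 999, n_taxa: int = 32,
                          n_samples: int = 6, sample_richness: int = 10,
                          seed: int = 0) -> float:
    """Fraction of |betaNTI| > 2 for communities random with respect to phylogeny.

    Each replicate simulates a fresh Yule tree and communities whose taxon
    identities are uniform random subsets of the pool (the data-generating
    process the tip-shuffle null assumes). Returns the pooled exceedance rate;
    nominal is ~0.05.
    """
    rngs = _spawn(seed, n_reps)
    hits = total = 0
    for rep, rng in enumerate(rngs):
        tree = simulate_tree(n_taxa, seed=int(rng.integers(2 ** 31)))
        counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
        for k in range(n_samples):
            idx = rng.choice(n_taxa, size=sample_richness, replace=False)
            counts[k, idx] = rng.integers(1, 20, size=sample_richness)
        table = OTUTable(counts, [f"S{k}" for k in range(n_samples)],
                         tree.tip_labels)
        z = beta_nti(table, tree, n_rand=n_rand,
                     seed=int(rng.integers(2 ** 31))).to_numpy()
        iu = np.triu_indices(n_samples, k=1)
        vals = z[iu]
        vals = vals[~np.isnan(vals)]
        hits += int((np.abs(vals) > 2.0).sum())
        total += vals.size
    return hits / total


def rc_self_calibration(n_reps: int = 200, n_rand: int = 999, n_taxa: int = 60,
                        parent_samples: int = 10, community_size: int = 1000,
                        seed: int = 0) -> float:
    """Fraction of |RC_bray| > 0.95 for pairs generated by the Raup-Crick null.

    Each replicate builds a parent table (multinomial samples of a lognormal
    metacommunity) that supplies the occupancy/abundance weights, then draws
    one pair of communities *by the null procedure itself* and scores it with
    those same weights. Nominal exceedance is ~0.05.
    """
    rngs = _spawn(seed, n_reps)
    hits = 0
    for rng in rngs:
        gamma = rng.lognormal(0.0, 1.0, n_taxa)
        gamma /= gamma.sum()
        parent = OTUTable(
            rng.multinomial(community_size, gamma, size=parent_samples),
            [f"P{k}" for k in range(parent_samples)],
            [f"O{j}" for j in range(n_taxa)])
        occ = (parent.counts > 0).sum(axis=0).astype(float)
        ab = parent.relative_abundance().sum(axis=0)
        s_obs = int(np.median((parent.counts > 0).sum(axis=1)))
        pair = rc_null_communities(s_obs, community_size, occ, ab, 2, rng)
        table = OTUTable(pair, ["a", "b"], parent.otu_ids)
        rc = rc_bray(table, n_rand=n_rand, seed=int(rng.integers(2 ** 31)),
                     weights_table=parent)
        if abs(rc.iloc[0, 1]) > 0.95:
            hits += 1
    return hits / n_reps


# ---------------------------------------------------------------------------
# type-I error of the permutation tests
# ---------------------------------------------------------------------------

def _euclid(points: np.ndarray, ids: list[str]) -> DistanceMatrix:
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    return DistanceMatrix(d, ids)


def anosim_type1(n_sims: int = 1000, n_per_group: int = 6, n_perm: int = 199,
                 alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of ANOSIM on structureless data with random labels."""
    rngs = _spawn(seed, n_sims)
    n = 2 * n_per_group
    ids = [f"S{i}" for i in range(n)]
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    rejects = 0
    for rng in rngs:
        dm = _euclid(rng.random((n, 3)), ids)
        res = anosim(dm, dict(zip(ids, labels)), n_perm=n_perm,
                     seed=int(rng.integers(2 ** 31)))
        rejects += res.p_value <= alpha
    return rejects / n_sims


def mantel_type1(n_sims: int = 1000, n: int = 10, n_perm: int = 199,
                 alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the (Spearman) Mantel test on independent matrices."""
    rngs = _spawn(seed, n_sims)
    ids = [f"S{i}" for i in range(n)]
    rejects = 0
    for rng in rngs:
        d1 = _euclid(rng.random((n, 2)), ids)
        d2 = _euclid(rng.random((n, 2)), ids)
        res = mantel(d1, d2, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        rejects += res.p_value <= alpha
    return rejects / n_sims


def protest_type1(n_sims: int = 1000, n: int = 15, n_perm: int = 199,
                  alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of PROTEST on two independent ordinations."""
    rngs = _spawn(seed, n_sims)
    rejects = 0
    for rng in rngs:
        a = rng.standard_normal((n, 2))
        b = rng.standard_normal((n, 2))
        res = procrustes_protest(a, b, n_perm=n_perm,
                                 seed=int(rng.integers(2 ** 31)))
        rejects += res.p_value <= alpha
    return rejects / n_sims


def decay_type1(n_sims: int = 1000, n: int = 10, n_perm: int = 199,
                alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the decay-fit permutation test when community
    dissimilarity is independent of geography."""
    rngs = _spawn(seed, n_sims)
    ids = [f"S{i}" for i in range(n)]
    rejects = 0
    for rng in rngs:
        meta = pd.DataFrame({"latitude": rng.uniform(0, 30, n),
                             "longitude": rng.uniform(120, 180, n),
                             "region": "X"}, index=ids)
        geo = haversine_matrix(meta)
        comm = _euclid(rng.random((n, 2)) * 0.5, ids)
        fit = fit_distance_decay(comm, geo, n_perm=n_perm,
                                 seed=int(rng.integers(2 ** 31)))
        rejects += fit.p_value <= alpha
    return rejects / n_sims


def diffslope_type1(n_sims: int = 1000, n_pairs: int = 60, n_perm: int = 199,
                    alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the slope-difference test when both pair sets come
    from the same linear process."""
    rngs = _spawn(seed, n_sims)
    rejects = 0
    for rng in rngs:
        def draw():
            x = rng.uniform(0, 3000, n_pairs)
            y = 0.8 - 1e-4 * x + rng.normal(0, 0.05, n_pairs)
            return x, y
        res = diff_slope_test(draw(), draw(), n_perm=n_perm,
                              seed=int(rng.integers(2 ** 31)))
        rejects += res.p_value <= alpha
    return rejects / n_sims


# ---------------------------------------------------------------------------
# end-to-end regime recovery and directional checks
# ---------------------------------------------------------------------------

def preset_process_fractions(name: str, seed: int, n_taxa: int = 300,
                             sites_per_region: int = 10,
                             n_rand: int = 999):
    """Run the full classifier on a named preset; returns (fractions, dataset)."""
    rngs = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    ds = scenario_preset(name, seed=int(rngs[0]), n_taxa=n_taxa,
                         n_sites_per_region=(sites_per_region, sites_per_region))
    z = beta_nti(ds.table, ds.tree, n_rand=n_rand, seed=int(rngs[1]))
    rc = rc_bray(ds.table, n_rand=n_rand, seed=int(rngs[2]))
    pairs = classify_pairs(z, rc)
    fractions = summarize_fractions(pairs, groups=ds.metadata["region"])
    return fractions, ds


def dispersal_decay_fit(seed: int, n_taxa: int = 300, sites_per_region: int = 10,
                        n_perm: int = 999):
    """Distance-decay fit of similarity on km for the dispersal-limited preset."""
    rngs = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
    ds = scenario_preset("dispersal_limitation", seed=int(rngs[0]),
                         n_taxa=n_taxa,
                         n_sites_per_region=(sites_per_region, sites_per_region))
    bc = bray_curtis(ds.table)
    geo = haversine_matrix(ds.metadata)
    return fit_distance_decay(bc, geo, n_perm=n_perm, seed=int(rngs[1]))


def selection_region_separation(seed: int, n_taxa: int = 300,
                                sites_per_region: int = 10, n_perm: int = 9999):
    """ANOSIM (and PCoA) by region for the two-region selection preset."""
    rngs = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
    ds = scenario_preset("heterogeneous_selection", seed=int(rngs[0]),
                         n_taxa=n_taxa,
                         n_sites_per_region=(sites_per_region, sites_per_region))
    bc = bray_curtis(ds.table)
    res = anosim(bc, ds.metadata["region"], n_perm=n_perm, seed=int(rngs[1]))
    return res, pcoa(bc), ds


def diversity_drift_contrast(seed: int, n_rand: int = 999) -> dict:
    """Drift fractions of a low-diversity/small-J regime versus a
    high-diversity/large-J spatially structured regime.

    The low-diversity regime is pure drift with a small taxon pool and small
    communities; the high-diversity regime is the dispersal-limitation preset
    (large pool, 10^5 individuals). Mirrors the expectation that demographic
    stochasticity dominates where populations and pools are small.
    """
    rngs = np.random.SeedSequence(seed).generate_state(4) % (2 ** 31)
    low = simulate_dataset(ScenarioParams(
        n_taxa=100, n_sites_per_region=(10, 10), seed=int(rngs[0]),
        selection_sd=math.inf, pool_overlap=1.0, dispersal_lambda=math.inf,
        mixing=0.0, community_size=1200, regime="drift"))
    z = beta_nti(low.table, low.tree, n_rand=n_rand, seed=int(rngs[1]))
    rc = rc_bray(low.table, n_rand=n_rand, seed=int(rngs[2]))
    low_frac = summarize_fractions(classify_pairs(z, rc)).loc["all"]
    high_frac, high = preset_process_fractions(
        "dispersal_limitation", seed=int(rngs[3]), n_rand=n_rand)
    return {
        "low_drift_fraction": float(low_frac["drift"]),
        "high_drift_fraction": float(high_frac.loc["all", "drift"]),
        "low_mean_richness": float((low.table.counts > 0).sum(axis=1).mean()),
        "high_mean_richness": float((high.table.counts > 0).sum(axis=1).mean()),
    }
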