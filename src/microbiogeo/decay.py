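"""Distance-decay of community similarity.

Pairwise great-circle distances, OLS of similarity (1 - Bray-Curtis) on
distance, and a permutation test for differences between decay slopes. Because
the n(n-1)/2 pairwise points share samples, they are not independent; the
regression p-value therefore comes from Mantel-style permutations of sample
identities rather than from OLS t statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import DecayFit, DistanceMatrix, PermutationTestResult, ValidationError, permutation_p

EARTH_RADIUS_KM = 6371.0

__all__ = ["EARTH_RADIUS_KM", "haversine_matrix", "fit_distance_decay",
           "diff_slope_test", "ols_slope"]


def haversine_matrix(meta: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distances (km) between all stations, Earth radius 6371 km."""
    lat = np.radians(meta["latitude"].to_numpy(dtype=float))
    lon = np.radians(meta["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, [str(i) for i in meta.index])


def ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS slope, intercept, and adjusted R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValidationError("distance values are constant; slope undefined")
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(yc @ yc)
    if syy == 0:
        r2 = 1.0
    else:
        ss_res = syy - slope * float(xc @ yc)
        r2 = 1.0 - ss_res / syy
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, intercept, r2_adj


def fit_distance_decay(community_D: DistanceMatrix, geo_D: DistanceMatrix,
                       n_perm: int = 999, seed: int | None = None,
                       response: str = "similarity") -> DecayFit:
    """OLS of pairwise similarity (or dissimilarity) on geographic distance.

    ``response='similarity'`` regresses ``1 - dissimilarity`` (decay gives a
    negative slope); ``'dissimilarity'`` regresses the raw dissimilarities.
    The two-sided p-value permutes sample identities of the community matrix.
    """
    if community_D.ids != geo_D.ids:
        if set(community_D.ids) != set(geo_D.ids):
            raise ValidationError("community and geographic matrices have different ids")
        geo_D = geo_D.reorder(community_D.ids)
    n = community_D.n
    if n < 3:
        raise ValidationError("need at least 3 samples for a decay fit")
    if response not in ("similarity", "dissimilarity"):
        raise ValueError("response must be 'similarity' or 'dissimilarity'")
    iu = np.triu_indices(n, k=1)
    x = geo_D.values[iu]
    comm = community_D.values
    y_full = 1.0 - comm if response == "similarity" else comm
    y = y_full[iu]
    slope, intercept, r2_adj = ols_slope(x, y)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        yb = y_full[perm[:, None], perm[None, :]][iu]
        null[b] = ols_slope(x, yb)[0]
    p = permutation_p(null, slope, alternative="two-sided")
    return DecayFit(slope=slope, intercept=intercept, r2_adj=r2_adj,
                    p_value=p, n_pairs=x.size, response=response)


def diff_slope_test(pairs_a: tuple[np.ndarray, np.ndarray],
                    pairs_b: tuple[np.ndarray, np.ndarray],
                    n_perm: int = 1000, seed: int | None = None) -> PermutationTestResult:
    """Permutation test for a difference between two decay slopes.

    The statistic is ``slope_A - slope_B``; the null exchanges (distance,
    similarity) pairs at random between the two sets, preserving set sizes.
    Antisymmetric in its arguments: swapping A and B flips the sign and leaves
    the p-value unchanged.
    """
    xa, ya = (np.asarray(v, dtype=float) for v in pairs_a)
    xb, yb = (np.asarray(v, dtype=float) for v in pairs_b)
    if xa.size != ya.size or xb.size != yb.size:
        raise ValidationError("x and y lengths differ within a pair set")
    if xa.size < 3 or xb.size < 3:
        raise ValidationError("each pair set needs at least 3 pairs")
    observed = ols_slope(xa, ya)[0] - ols_slope(xb, yb)[0]

    # canonical pool order: the null distribution (and hence the p-value) is
    # then invariant under swapping the two argument sets of equal size
    x_all = np.concatenate([xa, xb])
    y_all = np.concatenate([ya, yb])
    order = np.lexsort((y_all, x_all))
    x_all, y_all = x_all[order], y_all[order]
    na, ntot = xa.size, x_all.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(ntot)
        ia, ib = perm[:na], perm[na:]
        null[b] = ols_slope(x_all[ia], y_all[ia])[0] - ols_slope(x_all[ib], y_all[ib])[0]
    p = permutation_p(null, observed, alternative="two-sided")
    return PermutationTestResult(statistic=observed, n_permutations=n_perm,
                                 p_value=p, statistic_name="slope_difference")


def decay_pairs(community_D: DistanceMatrix, geo_D: DistanceMatrix,
                response: str = "similarity") -> tuple[np.ndarray, np.ndarray]:
    """Extract the (distance, similarity) pair lists a decay fit uses."""
    if community_D.ids != geo_D.ids:
        geo_D = geo_D.reorder(community_D.ids)
    iu = np.triu_indices(community_D.n, k=1)
    y = community_D.values[iu]
    if response == "similarity":
        y = 1.0 - y
    return geo_D.values[iu], y
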