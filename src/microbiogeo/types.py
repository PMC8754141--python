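"""Core containers shared across the pipeline.

Counts live in an :class:`OTUTable` (samples x OTUs), pairwise quantities in a
:class:`DistanceMatrix`, and the phylogeny in a :class:`PhyloTree` wrapping a
rooted dendropy tree with branch lengths. All containers validate their
invariants on construction so downstream code can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "PhyloTree",
    "DistanceMatrix",
    "OrdinationResult",
    "PermutationTestResult",
    "DecayFit",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """An input violated a domain invariant (e.g. latitude out of range)."""


class FormatError(ValueError):
    """A file could not be parsed into the expected structure."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise FormatError(f"duplicate {what} identifier(s): {sorted(set(dups))}")
    return ids


@dataclass
class OTUTable:
    """Integer count matrix with samples as rows and OTUs as columns."""

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.otu_ids = _check_unique(self.otu_ids, "OTU")
        ns, no = self.counts.shape
        if ns != len(self.sample_ids) or no != len(self.otu_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if ns < 1 or no < 1:
            raise ValidationError("table needs at least one sample and one OTU")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        totals = self.sample_totals().astype(float)
        if (totals == 0).any():
            bad = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValidationError(f"all-zero sample(s): {bad}")
        return self.counts / totals[:, None]

    def select_samples(self, sample_ids: Sequence[str]) -> "OTUTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OTUTable(self.counts[idx], list(sample_ids), list(self.otu_ids))

    def select_otus(self, otu_ids: Sequence[str]) -> "OTUTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OTUTable(self.counts[:, idx], list(self.sample_ids), list(otu_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OTUTable":
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])


class PhyloTree:
    """Rooted phylogeny with non-negative branch lengths and unique tip labels."""

    def __init__(self, tree: dendropy.Tree, missing_length: str = "error") -> None:
        if missing_length not in ("error", "zero"):
            raise ValueError("missing_length must be 'error' or 'zero'")
        self.tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise FormatError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        self.tip_labels = _check_unique(labels, "tip")
        if len(self.tip_labels) < 2:
            raise ValidationError("tree needs at least 2 tips")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # root edge may legitimately carry no length
            if edge.length is None:
                if missing_length == "zero":
                    edge.length = 0.0
                else:
                    raise FormatError(
                        "tree has a branch without a length "
                        "(pass missing_length='zero' to substitute 0)"
                    )
            elif edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        self._coph: pd.DataFrame | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def cophenetic(self) -> pd.DataFrame:
        """Patristic (cophenetic) tip-to-tip distance matrix as a DataFrame."""
        if self._coph is None:
            # Root-to-node depths in one preorder pass, then LCA via path sets
            # would be O(n^2 log n); dendropy's PDM is fine at the scales used.
            pdm = self.tree.phylogenetic_distance_matrix()
            labels = self.tip_labels
            taxa = {t.label: t for t in self.tree.taxon_namespace}
            n = len(labels)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            self._coph = pd.DataFrame(d, index=labels, columns=labels)
        return self._coph

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class DistanceMatrix:
    """Square symmetric matrix with zero diagonal and an identifier list."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = _check_unique(self.ids, "matrix")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValidationError("matrix is not symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("matrix diagonal is not zero")
        # exact symmetry simplifies downstream indexing
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in scipy condensed (row-major upper) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in ids]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], list(ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    """Sample scores plus the eigenvalue spectrum of an ordination."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray    # descending; may contain negatives (PCoA)
    proportion_explained: np.ndarray  # over positive eigenvalues only

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.proportion_explained = np.asarray(self.proportion_explained, dtype=float)


@dataclass
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    statistic_name: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


@dataclass
class DecayFit:
    """OLS fit of pairwise community similarity (or dissimilarity) on distance."""

    slope: float
    intercept: float
    r2_adj: float
    p_value: float
    n_pairs: int
    response: str = "similarity"


def permutation_p(null: np.ndarray, observed: float, alternative: str = "greater") -> float:
    """(exceedances + 1) / (n + 1); never returns 0."""
    null = np.asarray(null, dtype=float)
    if alternative == "greater":
        exceed = np.sum(null >= observed)
    elif alternative == "less":
        exceed = np.sum(null <= observed)
    elif alternative == "two-sided":
        exceed = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (exceed + 1) / (null.size + 1)
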