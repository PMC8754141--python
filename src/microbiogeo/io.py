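"""Readers/writers for the tab-delimited formats the pipeline touches.

All tables are UTF-8 TSV with ``#``-prefixed comment lines at the top that
record provenance (tool version, seed, parameters). OTU tables default to the
classic amplicon orientation (OTUs as rows, samples as columns); every reader
and writer takes an ``orientation`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .types import DistanceMatrix, FormatError, OTUTable, PhyloTree, ValidationError
from . import __version__

REQUIRED_METADATA_COLUMNS = ("sample_id", "latitude", "longitude", "region")


def _provenance_header(seed=None, params: dict | None = None) -> str:
    parts = [f"# microbiogeo v{__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if params:
        kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        parts.append(f"# params: {kv}")
    return "\n".join(parts) + "\n"


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc


def read_otu_table(path, orientation: str = "samples_as_columns") -> OTUTable:
    """Read a tab-delimited OTU table; returns samples-as-rows regardless of file layout."""
    if orientation not in ("samples_as_rows", "samples_as_columns"):
        raise ValueError("orientation must be samples_as_rows or samples_as_columns")
    df = _read_tsv(path)
    if orientation == "samples_as_columns":
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        r = mask.any(axis=1).idxmax()
        c = mask.loc[r].idxmax()
        raise FormatError(f"non-numeric count at sample {r!r}, OTU {c!r} in {path}")
    try:
        return OTUTable.from_dataframe(numeric)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_otu_table(table: OTUTable, path, orientation: str = "samples_as_columns",
                    seed=None, params: dict | None = None) -> None:
    df = table.to_dataframe()
    if orientation == "samples_as_columns":
        df = df.T
        df.index.name = "otu_id"
    else:
        df.index.name = "sample_id"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed, params))
        df.to_csv(fh, sep="\t")


def read_tree(path, missing_length: str = "error") -> PhyloTree:
    """Parse a rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"could not parse Newick in {path}: {exc}") from exc
    return PhyloTree(tree, missing_length=missing_length)


def read_tree_string(newick: str, missing_length: str = "error") -> PhyloTree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"could not parse Newick string: {exc}") from exc
    return PhyloTree(tree, missing_length=missing_length)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_newick() + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata; env variables are all numeric non-required columns.

    Returns a DataFrame indexed by sample_id with ``latitude``, ``longitude``,
    ``region`` and one column per environmental variable.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id(s)")
    out = pd.DataFrame(index=df.index.astype(str))
    out["latitude"] = pd.to_numeric(df["latitude"], errors="raise")
    out["longitude"] = pd.to_numeric(df["longitude"], errors="raise")
    out["region"] = df["region"].astype(str)
    if (out["latitude"].abs() > 90).any():
        bad = out.index[out["latitude"].abs() > 90].tolist()
        raise ValidationError(f"latitude outside [-90, 90] for sample(s) {bad}")
    if (out["longitude"].abs() > 180).any():
        bad = out.index[out["longitude"].abs() > 180].tolist()
        raise ValidationError(f"longitude outside [-180, 180] for sample(s) {bad}")
    for col in df.columns:
        if col in ("latitude", "longitude", "region"):
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.notna().all():
            out[col] = vals
    return out


def env_columns(meta: pd.DataFrame) -> list[str]:
    return [c for c in meta.columns if c not in ("latitude", "longitude", "region")]


def write_metadata(meta: pd.DataFrame, path, seed=None, params: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed, params))
        meta.rename_axis("sample_id").to_csv(fh, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = _read_tsv(path).apply(pd.to_numeric, errors="raise")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column identifiers differ")
    return DistanceMatrix(df.to_numpy(), [str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path, seed=None,
                          params: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed, params))
        dm.to_dataframe().to_csv(fh, sep="\t")


@dataclass
class AlignmentReport:
    dropped_samples: list[str] = field(default_factory=list)
    dropped_otus: list[str] = field(default_factory=list)
    dropped_metadata: list[str] = field(default_factory=list)

    def __str__(self) -> str:  # human-readable one-liner for logs
        return (f"dropped {len(self.dropped_samples)} sample(s) "
                f"{self.dropped_samples}, {len(self.dropped_otus)} OTU(s) "
                f"{self.dropped_otus}, {len(self.dropped_metadata)} metadata row(s)")


def align_inputs(table: OTUTable, tree: PhyloTree | None, meta: pd.DataFrame):
    """Restrict table/metadata to their common samples and to OTUs present as tree tips.

    Output ordering is lexicographic, so the result is independent of input
    order and the operation is idempotent. Returns
    ``(table, tree, meta, AlignmentReport)``.
    """
    samples = sorted(set(table.sample_ids) & set(meta.index))
    if not samples:
        raise ValidationError("no samples shared between table and metadata")
    if tree is not None:
        otus = sorted(set(table.otu_ids) & set(tree.tip_labels))
    else:
        otus = sorted(table.otu_ids)
    if not otus:
        raise ValidationError("no OTUs shared between table and tree tips")
    report = AlignmentReport(
        dropped_samples=sorted(set(table.sample_ids) - set(samples)),
        dropped_otus=sorted(set(table.otu_ids) - set(otus)),
        dropped_metadata=sorted(set(meta.index) - set(samples)),
    )
    aligned = table.select_samples(samples).select_otus(otus)
    return aligned, tree, meta.loc[samples], report
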