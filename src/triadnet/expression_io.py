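"""Expression-matrix I/O, validation, MAD-based gene filtering and sample QC.

The pipeline's universal input is a genes x samples matrix of non-negative,
already-normalized expression values (e.g. FPKM) together with a sample
metadata table assigning each sample a condition (breed), a tissue and a
replicate index.  Low-expressed, noise-dominated genes are removed by keeping
the top fraction of genes ranked by the median absolute deviation (MAD) of
their expression across all samples; sample quality is screened by
hierarchical clustering of sample profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist


class ExpressionIOError(ValueError):
    """Raised for malformed expression matrices or metadata."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with ordered, unique identifiers."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate gene id(s): {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate sample id(s): {dups}")
        if v.isna().any().any():
            gene = v.index[v.isna().any(axis=1)][0]
            raise ExpressionIOError(f"missing value in gene {gene!r}")
        if (v.values < 0).any():
            gene = v.index[(v.values < 0).any(axis=1)][0]
            raise ExpressionIOError(f"negative expression value in gene {gene!r}")
        v.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)])


@dataclass
class SampleMetadata:
    """Per-sample condition / tissue / replicate annotations."""

    table: pd.DataFrame  # columns: sample_id, condition, tissue, replicate

    REQUIRED = ("sample_id", "condition", "tissue", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ExpressionIOError(f"metadata missing column(s): {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ExpressionIOError("duplicate sample_id in metadata")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def samples_for(self, condition=None, tissue=None) -> list[str]:
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return list(t["sample_id"])

    def validate_against(self, X: ExpressionMatrix) -> None:
        known = set(self.samples)
        orphans = [s for s in X.samples if s not in known]
        if orphans:
            raise ExpressionIOError(
                f"sample(s) present in matrix but absent from metadata: {orphans}"
            )


@dataclass
class FilterReport:
    n_input_genes: int
    n_kept: int
    keep_fraction: float
    mad: pd.Series = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_input_genes": self.n_input_genes,
            "n_kept": self.n_kept,
            "keep_fraction": self.keep_fraction,
        }


def read_expression(matrix_path, metadata_path) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Read and cross-validate an expression TSV and its metadata TSV.

    The matrix TSV has a ``gene_id`` first column and one column per sample;
    the metadata TSV has columns sample_id, condition, tissue, replicate.
    """
    raw = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "gene_id"
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    if bad.any().any():
        gene = numeric.index[bad.any(axis=1)][0]
        col = numeric.columns[bad.loc[gene]][0]
        raise ExpressionIOError(
            f"non-numeric cell at gene {gene!r}, sample {col!r} in {matrix_path}"
        )
    X = ExpressionMatrix(numeric.astype(float))
    meta = SampleMetadata(pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str}))
    meta.validate_against(X)
    return X, meta


def write_expression(X: ExpressionMatrix, path) -> None:
    X.values.to_csv(path, sep="\t", index_label="gene_id")


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def mad_filter(
    X: ExpressionMatrix, keep_fraction: float = 0.5, log2: bool = False
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep the top ``keep_fraction`` of genes ranked by expression MAD.

    MAD is computed across ALL samples (conditions pooled).  n_kept =
    ceil(keep_fraction * n_genes); ties broken lexicographically by gene id
    (stable).  ``log2`` computes MAD on log2(x+1)-transformed values.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    vals = X.values.values
    if log2:
        vals = np.log2(vals + 1.0)
    med = np.median(vals, axis=1, keepdims=True)
    mad = pd.Series(np.median(np.abs(vals - med), axis=1), index=X.values.index, name="mad")
    n = len(mad)
    n_kept = math.ceil(keep_fraction * n)
    if keep_fraction < 1 and mad.nunique() == 1:
        warnings.warn("all genes have identical MAD; ranking is by gene id only")
    order = pd.DataFrame({"mad": mad, "gene": mad.index}).sort_values(
        ["mad", "gene"], ascending=[False, True], kind="stable"
    )
    kept = list(order["gene"].iloc[:n_kept])
    kept_in_input_order = [g for g in X.gene_ids if g in set(kept)]
    report = FilterReport(n, n_kept, keep_fraction, mad)
    return X.subset_genes(kept_in_input_order), report


def cluster_samples(
    X: ExpressionMatrix, method: str = "average", outlier_z: float = 2.5
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchically cluster samples (Euclidean) and flag outliers.

    Returns the scipy linkage matrix and a boolean Series flagging samples
    whose singleton merge height has a z-score above ``outlier_z`` relative
    to all samples' merge heights.
    """
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples to cluster")
    profiles = X.values.values.T  # samples x genes
    Z = linkage(pdist(profiles, metric="euclidean"), method=method)
    # height at which each original sample is first merged
    merge_height = np.full(n, np.nan)
    for a, b, h, _ in Z:
        for idx in (int(a), int(b)):
            if idx < n and np.isnan(merge_height[idx]):
                merge_height[idx] = h
    mu, sd = merge_height.mean(), merge_height.std()
    if sd == 0:
        flags = np.zeros(n, dtype=bool)
    else:
        flags = (merge_height - mu) / sd > outlier_z
    return Z, pd.Series(flags, index=X.samples, name="is_outlier")
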