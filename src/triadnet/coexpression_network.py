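"""Weighted co-expression network construction and module analysis.

Implements the standard unsigned weighted-network protocol: adjacency
``a_ij = |cor(x_i, x_j)|^beta`` with the soft power chosen by the scale-free
topology fit, topological overlap (TOM), module detection by average-linkage
clustering on TOM dissimilarity with a static branch cut, eigengene-based
module merging, gene significance / module membership / intramodular
connectivity statistics, weighted network concepts (density, mean clustering
coefficient, centralization, heterogeneity), key-module calls with a
Bonferroni-corrected eigengene-tissue correlation test, and hub-gene calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression_io import ExpressionMatrix, SampleMetadata

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# adjacency and TOM


def _safe_corr(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; zero-variance rows correlate 0."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance gene(s); correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(values)
    c = np.nan_to_num(c, nan=0.0)
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return c


def adjacency(X: ExpressionMatrix, beta: int) -> pd.DataFrame:
    """Unsigned adjacency ``|cor|^beta`` (diagonal stored as 1)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    c = _safe_corr(X.values.values)
    a = np.abs(c) ** beta
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0
    return pd.DataFrame(a, index=X.gene_ids, columns=X.gene_ids)


def connectivity(A: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = A.values.copy()
    np.fill_diagonal(a, 0.0)
    return pd.Series(a.sum(axis=1), index=A.index, name="k")


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame  # columns: beta, r2, mean_k
    selected: int
    goal: float


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index for a connectivity vector.

    Bins k into ``n_bins`` equal-width bins and regresses log10(mean
    frequency) on log10(mean k) over non-empty bins; returns
    sign(-slope) * R^2.  Degenerate inputs (a single distinct bin) give 0.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) == 0 or k.max() == k.min():
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3 or len(set(xs)) < 2:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(np.sign(-slope) * r**2)


def pick_soft_threshold(
    X: ExpressionMatrix,
    grid=tuple(range(1, 21)),
    r2_goal: float = 0.85,
) -> SoftThresholdReport:
    """Scan a beta grid and select the soft power.

    The selected beta is the smallest on the grid whose signed fit index
    reaches ``r2_goal``; if none does, the grid argmax is used.
    """
    c = np.abs(_safe_corr(X.values.values))
    np.fill_diagonal(c, 0.0)
    rows = []
    for beta in grid:
        k = (c**beta).sum(axis=1)
        rows.append({"beta": beta, "r2": scale_free_fit(k), "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    hit = table[table["r2"] >= r2_goal]
    selected = int(hit["beta"].iloc[0]) if len(hit) else int(table.loc[table["r2"].idxmax(), "beta"])
    return SoftThresholdReport(table=table, selected=selected, goal=r2_goal)


def tom(A: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    ``w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` (u != i, j) and the diagonal set to 1.
    """
    a = A.values.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    w = (l + a) / denom
    np.fill_diagonal(w, 1.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(w, index=A.index, columns=A.columns)


# ---------------------------------------------------------------------------
# module detection


def detect_modules(
    Omega: pd.DataFrame, min_module_size: int = 30, cut_height: float = 0.99
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static branch cut.

    ``cut_height`` is a fraction of the dendrogram's merge-height range;
    branches below it with at least ``min_module_size`` members become
    modules (labeled M1, M2, ... in decreasing size order), everything else
    is labeled ``unassigned``.
    """
    genes = list(Omega.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    diss = 1.0 - Omega.values
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = linkage(squareform(diss, checks=False), method="average")
    h = Z[:, 2]
    cut = h.min() + cut_height * (h.max() - h.min()) if h.max() > h.min() else h.max()
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    out = pd.Series(UNASSIGNED, index=genes, name="module", dtype=object)
    for rank, cl in enumerate(
        sorted(keep, key=lambda c: (-sizes[c], c)), start=1
    ):
        out[labels == cl] = f"M{rank}"
    return out


def module_eigengenes(
    X: ExpressionMatrix, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component eigengene per module.

    Gene profiles are standardized (mean 0, sd 1 per gene) before the PCA;
    the eigengene (unit-norm sample scores) has its sign aligned so that its
    correlation with the module's mean expression profile is non-negative.
    Returns (eigengenes: samples x modules, variance explained per module).
    """
    mes = {}
    varex = {}
    for mod in sorted(m for m in assignment.unique() if m != UNASSIGNED):
        genes = assignment.index[assignment == mod]
        sub = X.values.loc[genes].values  # genes x samples
        sd = sub.std(axis=1)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        # samples x genes SVD; first left singular vector = PC scores
        u, s, _ = np.linalg.svd(z.T, full_matrices=False)
        me = u[:, 0]
        mean_prof = sub.mean(axis=0)
        if np.corrcoef(me, mean_prof)[0, 1] < 0:
            me = -me
        mes[mod] = me
        varex[mod] = float(s[0] ** 2 / (s**2).sum())
    return (
        pd.DataFrame(mes, index=X.samples),
        pd.Series(varex, name="variance_explained"),
    )


def merge_modules(
    assignment: pd.Series, X: ExpressionMatrix, threshold: float = 0.9
) -> pd.Series:
    """Merge modules whose eigengenes correlate above ``threshold``.

    The most-correlated qualifying pair is merged first (into the larger
    module's label), eigengenes are recomputed, and the process repeats until
    no pair qualifies.  Terminates: the module count strictly decreases.
    """
    assignment = assignment.copy()
    while True:
        mods = sorted(m for m in assignment.unique() if m != UNASSIGNED)
        if len(mods) < 2:
            return assignment
        mes, _ = module_eigengenes(X, assignment)
        corr = mes.corr()
        best, best_r = None, threshold
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                r = corr.loc[a, b]
                if r > best_r:
                    best, best_r = (a, b), r
        if best is None:
            return assignment
        a, b = best
        sizes = assignment.value_counts()
        keep, drop = (a, b) if sizes[a] >= sizes[b] else (b, a)
        assignment[assignment == drop] = keep


# ---------------------------------------------------------------------------
# gene-level statistics


def _corr_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r via the t statistic, n-2 df."""
    if n < 3:
        return 1.0
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def gene_significance(
    X: ExpressionMatrix,
    metadata: SampleMetadata,
    tissue: str,
    signed: bool = False,
) -> pd.Series:
    """GS: correlation of each gene with the focal tissue's binary indicator.

    Computed over the samples of ``X`` (subset to one condition upstream when
    a per-condition network is analyzed); absolute value unless ``signed``.
    Zero-variance genes get GS = 0.
    """
    meta = metadata.table.set_index("sample_id").loc[X.samples]
    indicator = (meta["tissue"] == tissue).astype(float).values
    if indicator.std() == 0:
        raise ValueError(f"tissue {tissue!r} absent (or universal) in samples")
    vals = X.values.values
    sd = vals.std(axis=1)
    centered = vals - vals.mean(axis=1, keepdims=True)
    ind_c = indicator - indicator.mean()
    r = centered @ ind_c / np.where(sd == 0, 1.0, sd * ind_c.std() * len(ind_c))
    r[sd == 0] = 0.0
    r = np.clip(r, -1, 1)
    gs = r if signed else np.abs(r)
    return pd.Series(gs, index=X.gene_ids, name=f"GS_{tissue}")


def gene_module_stats(
    X: ExpressionMatrix,
    metadata: SampleMetadata,
    A: pd.DataFrame,
    assignment: pd.Series,
    mes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene GS (per tissue), MM, kWithin and kTotal table."""
    a = A.values.copy()
    np.fill_diagonal(a, 0.0)
    k_total = a.sum(axis=1)
    stats_df = pd.DataFrame(
        {"module": assignment.loc[A.index].values, "kTotal": k_total}, index=A.index
    )
    k_within = np.zeros(len(A))
    mm = np.zeros(len(A))
    for mod in stats_df["module"].unique():
        sel = (stats_df["module"] == mod).values
        k_within[sel] = a[np.ix_(sel, sel)].sum(axis=1)
        if mod != UNASSIGNED and mod in mes.columns:
            sub = X.values.loc[A.index[sel]].values
            me = mes[mod].values
            sd = sub.std(axis=1)
            centered = sub - sub.mean(axis=1, keepdims=True)
            me_c = me - me.mean()
            r = centered @ me_c / np.where(sd == 0, 1.0, sd * me_c.std() * len(me_c))
            r[sd == 0] = 0.0
            mm[sel] = np.abs(np.clip(r, -1, 1))
    stats_df["kWithin"] = k_within
    stats_df["MM"] = mm
    for tissue in metadata.tissues:
        stats_df[f"GS_{tissue}"] = gene_significance(X, metadata, tissue)
    return stats_df


# ---------------------------------------------------------------------------
# network concepts (weighted, diagonal excluded everywhere)


@dataclass
class NetworkConcepts:
    density: float
    mean_cluster_coef: float
    centralization: float
    heterogeneity: float

    def as_dict(self) -> dict:
        return {
            "DS": self.density,
            "MCC": self.mean_cluster_coef,
            "CL": self.centralization,
            "HG": self.heterogeneity,
        }


def network_concepts(A: pd.DataFrame) -> NetworkConcepts:
    """Fundamental weighted network concepts of one (sub)network.

    With ``k_i = sum_{j != i} a_ij`` and n nodes: density = sum a_ij /
    (n(n-1)); per-node clustering coefficient = (sum_{j != u != i} a_ij a_ju
    a_ui) / ((sum_j a_ij)^2 - sum_j a_ij^2); centralization = n/(n-2) *
    (max k/(n-1) - density); heterogeneity = sqrt(population var(k))/mean(k).
    """
    a = A.values.copy().astype(float)
    n = a.shape[0]
    if n < 3:
        raise ValueError("network concepts need at least 3 nodes")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    density = k.sum() / (n * (n - 1))
    # numerator_i = (a^3)_ii ; denominator_i = k_i^2 - sum_j a_ij^2
    a3_diag = np.einsum("ij,jk,ki->i", a, a, a)
    denom = k**2 - (a**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, a3_diag / denom, 0.0)
    mcc = float(cc.mean())
    centralization = (n / (n - 2)) * (k.max() / (n - 1) - density)
    mean_k = k.mean()
    heterogeneity = float(np.sqrt(k.var()) / mean_k) if mean_k > 0 else 0.0
    return NetworkConcepts(float(density), mcc, float(centralization), heterogeneity)


# ---------------------------------------------------------------------------
# key modules and hub genes


def key_modules(
    mes: pd.DataFrame,
    metadata: SampleMetadata,
    stats_df: pd.DataFrame,
    alpha: float = 0.05,
    median_gs_min: float = 0.8,
) -> pd.DataFrame:
    """Module-tissue association with Bonferroni control plus a GS criterion.

    For every (module, tissue) pair the eigengene is correlated against the
    tissue's binary indicator (two-sided t test, n-2 df).  A pair is key iff
    p < alpha / (n_modules * n_tissues) and the median GS of the module's
    genes for that tissue exceeds ``median_gs_min``.
    """
    samples = list(mes.index)
    meta = metadata.table.set_index("sample_id").loc[samples]
    tissues = metadata.tissues
    m = len(mes.columns) * len(tissues)
    bonferroni = alpha / m
    rows = []
    for mod in mes.columns:
        genes = stats_df.index[stats_df["module"] == mod]
        for tissue in tissues:
            indicator = (meta["tissue"] == tissue).astype(float).values
            r = float(np.corrcoef(mes[mod].values, indicator)[0, 1])
            p = _corr_pvalue(r, len(samples))
            med_gs = float(stats_df.loc[genes, f"GS_{tissue}"].median())
            rows.append(
                {
                    "module": mod,
                    "tissue": tissue,
                    "r": r,
                    "p": p,
                    "bonferroni_threshold": bonferroni,
                    "median_GS": med_gs,
                    "is_key": bool(p < bonferroni and med_gs > median_gs_min),
                }
            )
    return pd.DataFrame(rows)


def hub_genes(
    stats_df: pd.DataFrame,
    module_tissue: dict[str, str],
    gs_min: float = 0.8,
    mm_min: float = 0.95,
    top_k_fraction: float = 0.2,
) -> dict[str, list[str]]:
    """Hub genes per module: GS >= 0.8, MM >= 0.95, kWithin in the top 20%.

    ``module_tissue`` maps each module to its focal tissue (normally the key
    tissue), selecting which GS column applies.  All thresholds inclusive;
    the kWithin rank cutoff is ceil(top_k_fraction * module size), ties
    broken by kWithin then gene id.
    """
    hubs: dict[str, list[str]] = {}
    for mod, tissue in module_tissue.items():
        sub = stats_df[stats_df["module"] == mod].copy()
        if sub.empty:
            hubs[mod] = []
            continue
        n = len(sub)
        cutoff_rank = math.ceil(top_k_fraction * n)
        sub = sub.iloc[np.lexsort((sub.index.astype(str), -sub["kWithin"].values))]
        ranked = sub.index[:cutoff_rank]
        ok = sub.loc[ranked]
        sel = (ok[f"GS_{tissue}"] >= gs_min) & (ok["MM"] >= mm_min)
        hubs[mod] = sorted(ok.index[sel])
    return hubs
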