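"""Multi-tissue expression patterns: fuzzy c-means clustering and the
tissue-specificity index tau.

tau = sum_i (1 - x_i / x_max) / (N - 1) over the N per-tissue mean
expression values of a gene; 0 for a uniform (housekeeping) profile, 1 for
strictly single-tissue expression.  Genes with tau > 0.9 are called
tissue-specific (TS).  Expression patterns across tissues are soft-clustered
with fuzzy c-means on per-gene standardized profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleMetadata

TS_TAU = 0.9


def tissue_means(
    X: ExpressionMatrix, metadata: SampleMetadata, condition: str
) -> pd.DataFrame:
    """Per-gene arithmetic mean over replicates, per tissue, one condition."""
    if condition not in metadata.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cols = {}
    for tissue in metadata.tissues:
        samples = metadata.samples_for(condition=condition, tissue=tissue)
        samples = [s for s in samples if s in set(X.samples)]
        if not samples:
            continue
        cols[tissue] = X.values[samples].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass
class TSIResult:
    table: pd.DataFrame  # columns: tau, is_TS
    excluded: list[str]  # all-zero-profile genes (tau undefined)


def tsi(profile: pd.DataFrame, threshold: float = TS_TAU) -> TSIResult:
    """Tissue-specificity index per gene from a gene x tissue mean profile.

    Genes whose profile is all zero have undefined tau and are excluded
    (reported separately).  ``is_TS`` is strict: tau > threshold.
    """
    if profile.shape[1] < 2:
        raise ValueError("tau needs at least 2 tissues")
    vals = profile.values.astype(float)
    if (vals < 0).any():
        raise ValueError("negative expression in tissue profile")
    xmax = vals.max(axis=1)
    zero = xmax == 0
    n = profile.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - vals / xmax[:, None]).sum(axis=1) / (n - 1)
    table = pd.DataFrame(
        {"tau": tau[~zero], "is_TS": tau[~zero] > threshold},
        index=profile.index[~zero],
    )
    excluded = list(profile.index[zero])
    if excluded:
        warnings.warn(f"{len(excluded)} all-zero gene profile(s) excluded from tau")
    return TSIResult(table=table, excluded=excluded)


def standardize_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization (mean 0, sd 1) across tissues.

    Constant genes cannot be standardized and are dropped with a warning.
    """
    vals = profile.values.astype(float)
    sd = vals.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} constant gene profile(s) dropped")
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=profile.index[keep], columns=profile.columns)


@dataclass
class FuzzyClusteringResult:
    centroids: np.ndarray  # c x n_tissues
    membership: pd.DataFrame  # genes x clusters
    c: int
    m: float
    iterations: int
    converged: bool
    objective_trace: list


def fuzzy_cmeans(
    profile: pd.DataFrame,
    c: int = 8,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> FuzzyClusteringResult:
    """Fuzzy c-means soft clustering of standardized expression profiles.

    Standard alternating iteration: centroids are membership^m-weighted
    means; memberships are ``u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))``.
    A point coincident with a centroid takes membership 1 there (limit
    rule).  Initialization picks c distinct data rows at random (seeded).
    The objective ``sum u^m d^2`` is checked non-increasing every iteration.
    """
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    X = profile.values.astype(float)
    n = X.shape[0]
    if n < c:
        raise ValueError("fewer genes than clusters")
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=c, replace=False)].copy()
    exponent = 2.0 / (m - 1.0)
    objective_trace: list[float] = []
    converged = False
    u = None
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        u = np.zeros((n, c))
        coincident = zero.any(axis=1)
        if coincident.any():
            rows = np.where(coincident)[0]
            for r in rows:
                hits = np.where(zero[r])[0]
                u[r, hits[0]] = 1.0
        free = ~coincident
        if free.any():
            # u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1)), computed via d2^(-1/(m-1))
            w = d2[free] ** (-exponent / 2.0)
            u[free] = w / w.sum(axis=1, keepdims=True)
        obj = float((u**m * d2).sum())
        if objective_trace and obj > objective_trace[-1] + 1e-9 * max(1.0, obj):
            raise AssertionError("fuzzy c-means objective increased")
        objective_trace.append(obj)
        um = u**m
        new_centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    membership = pd.DataFrame(
        u, index=profile.index, columns=[f"C{i + 1}" for i in range(c)]
    )
    return FuzzyClusteringResult(
        centroids=centroids,
        membership=membership,
        c=c,
        m=m,
        iterations=it,
        converged=converged,
        objective_trace=objective_trace,
    )
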