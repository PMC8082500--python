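"""Cross-dataset replication of co-expression relationships.

Candidate gene-gene co-expression edges discovered in one dataset are tested
in an independent dataset by Pearson correlation (two-sided t test, n-2 df);
an edge is confirmed when it is significantly positively correlated.  Pairs
with a gene missing from the replication dataset are untestable and excluded
from the rate's denominator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix


def pairwise_correlation(X: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Pearson r and two-sided p for every unordered gene pair.

    Zero-variance genes are excluded with a warning.  Requires >= 3 samples.
    """
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation tests")
    genes = list(genes) if genes is not None else X.gene_ids
    missing = [g for g in genes if g not in set(X.gene_ids)]
    if missing:
        raise KeyError(f"gene(s) absent from matrix: {missing}")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = X.values.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    dropped = list(sub.index[sd == 0])
    if dropped:
        warnings.warn(f"zero-variance gene(s) excluded: {dropped}")
        sub = sub.loc[sd > 0]
    n = sub.shape[1]
    rows = []
    for a, b in itertools.combinations(sub.index, 2):
        r, p = stats.pearsonr(sub.loc[a].values, sub.loc[b].values)
        rows.append({"gene_a": a, "gene_b": b, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)


def replicate_edges(
    candidates, tests: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Verdict per candidate edge: confirmed iff p < alpha and r > 0.

    ``candidates`` is an iterable of gene pairs.  Pairs without a test (a
    gene absent from the replication data) are marked ``untestable``.
    """
    lookup = {}
    for _, row in tests.iterrows():
        lookup[frozenset((row["gene_a"], row["gene_b"]))] = (row["r"], row["p"])
    rows = []
    for a, b in candidates:
        key = frozenset((a, b))
        if key not in lookup:
            rows.append(
                {"gene_a": a, "gene_b": b, "r": np.nan, "p": np.nan, "verdict": "untestable"}
            )
            continue
        r, p = lookup[key]
        verdict = "confirmed" if (p < alpha and r > 0) else "not_confirmed"
        rows.append({"gene_a": a, "gene_b": b, "r": r, "p": p, "verdict": verdict})
    return pd.DataFrame(rows)


@dataclass
class ReplicationSummary:
    n_candidates: int  # testable candidates (untestable excluded)
    n_confirmed: int
    rate_percent: float  # 100 * confirmed / testable, half-up to 2 decimals

    def as_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_confirmed": self.n_confirmed,
            "rate_percent": self.rate_percent,
        }


def replication_rate(verdicts: pd.DataFrame) -> ReplicationSummary:
    """Fraction of testable candidate edges confirmed, as a percentage."""
    testable = verdicts[verdicts["verdict"] != "untestable"]
    n = len(testable)
    confirmed = int((testable["verdict"] == "confirmed").sum())
    if n == 0:
        rate = 0.0
    else:
        rate = float(
            (Decimal(100 * confirmed) / Decimal(n)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
    return ReplicationSummary(n_candidates=n, n_confirmed=confirmed, rate_percent=rate)


def module_overlap(genes_a, genes_b) -> int:
    """Size of the intersection on case-normalized gene identifiers."""
    return len({str(g).upper() for g in genes_a} & {str(g).upper() for g in genes_b})
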