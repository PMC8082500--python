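"""Composite importance scores for nodes, edges and size-3 subgraphs.

Each node is scored from four components, all mapped to [0, 1]: network
connectivity (min-max-normalized mixed-network degree), condition
differential expression in the focal tissue (min-max-normalized
|log2((m1 + eps) / (m2 + eps))| of replicate means), tissue specificity
(tau) and a TF indicator.  The default composite is the equal-weight sum

    S_node = w_C * C + w_D * D + w_tau * tau + w_TF * 1_TF

(every weight configurable).  Edge scores are the weighted-network adjacency
of the edge's endpoints; motif scores mix mean node and mean edge scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleMetadata
from .grn_assembly import MixedNetwork


@dataclass
class ScoreWeights:
    w_connectivity: float = 0.25
    w_diffexpr: float = 0.25
    w_tsi: float = 0.25
    w_tf: float = 0.25
    alpha: float = 0.5  # motif score: weight on node scores vs edge scores
    epsilon: float = 1.0  # fold-change stabilizer

    def __post_init__(self) -> None:
        w = np.array([self.w_connectivity, self.w_diffexpr, self.w_tsi, self.w_tf])
        if (w < 0).any():
            raise ValueError("node-score weights must be >= 0")
        if w.sum() == 0:
            raise ValueError("at least one node-score weight must be positive")
        w = w / w.sum()
        self.w_connectivity, self.w_diffexpr, self.w_tsi, self.w_tf = map(float, w)
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


def _minmax(values: pd.Series, label: str) -> pd.Series:
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn(f"degenerate {label} component (min == max); set to 0")
        return pd.Series(0.0, index=values.index)
    return (values - lo) / (hi - lo)


def node_scores(
    net: MixedNetwork,
    X: ExpressionMatrix,
    metadata: SampleMetadata,
    focal_tissue: str,
    tsi_table: pd.DataFrame,
    weights: ScoreWeights | None = None,
) -> pd.DataFrame:
    """Composite node scores with the per-component table for audit.

    ``X`` must span both conditions (the differential-expression component
    compares the focal tissue's replicate means between the two conditions).
    Nodes without expression or tau (miRNAs) take 0 for those components.
    """
    weights = weights or ScoreWeights()
    conds = metadata.conditions
    if len(conds) != 2:
        raise ValueError("differential expression needs exactly 2 conditions")
    s1 = [s for s in metadata.samples_for(condition=conds[0], tissue=focal_tissue) if s in set(X.samples)]
    s2 = [s for s in metadata.samples_for(condition=conds[1], tissue=focal_tissue) if s in set(X.samples)]
    if not s1 or not s2:
        raise ValueError(f"no samples for tissue {focal_tissue!r} in both conditions")
    nodes = sorted(net.nodes, key=str)
    expressed = set(X.gene_ids)
    eps = weights.epsilon
    degree = pd.Series({n: net.degree(n) for n in nodes}, dtype=float)
    lfc = {}
    for n in nodes:
        if n in expressed:
            m1 = X.values.loc[n, s1].mean()
            m2 = X.values.loc[n, s2].mean()
            lfc[n] = abs(np.log2((m1 + eps) / (m2 + eps)))
        else:
            lfc[n] = 0.0
    lfc = pd.Series(lfc)
    tau = pd.Series(
        {n: float(tsi_table.loc[n, "tau"]) if n in tsi_table.index else 0.0 for n in nodes}
    )
    is_tf = pd.Series({n: float(bool(net.nodes[n].get("is_tf"))) for n in nodes})
    C = _minmax(degree, "connectivity")
    D = _minmax(lfc, "differential-expression")
    score = (
        weights.w_connectivity * C
        + weights.w_diffexpr * D
        + weights.w_tsi * tau
        + weights.w_tf * is_tf
    )
    return pd.DataFrame(
        {
            "S_node": score,
            "connectivity": C,
            "diffexpr": D,
            "tau": tau,
            "is_tf": is_tf,
            "degree": degree,
            "abs_log2fc": lfc,
        }
    ).rename_axis("node")


def edge_scores(
    net: MixedNetwork, A: pd.DataFrame, mirna_edge_score: float = 0.5
) -> dict:
    """Score per typed edge: the co-expression adjacency of its endpoints.

    Co-expression edges score their stored weight (= a_ij); TF regulation
    arcs between expressed genes score a_ij from the adjacency matrix; miRNA
    arcs (no meaningful adjacency) take a fixed documented constant.
    """
    scores = {}
    idx = set(A.index)
    for (s, t), attrs in net.regulation.items():
        if attrs["edge_type"] == "mirna_regulation":
            scores[("regulation", (s, t))] = mirna_edge_score
        elif s in idx and t in idx:
            scores[("regulation", (s, t))] = float(A.loc[s, t])
        else:
            scores[("regulation", (s, t))] = 0.0
    for pair, w in net.coexpression.items():
        u, v = sorted(pair, key=str)
        scores[("coexpression", (u, v))] = float(w)
    return scores


def motif_scores(
    instances,
    node_table: pd.DataFrame,
    edge_score_map: dict,
    net: MixedNetwork,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """S_motif = alpha * mean(node scores) + (1 - alpha) * mean(edge scores).

    ``instances`` is a list of (class_id, (A, B, C)) tuples; the edges of an
    instance are the distinct mixed-network edges among its three nodes.
    """
    rows = []
    for class_id, triple in instances:
        nodes = list(triple)
        ns = float(np.mean([node_table.loc[n, "S_node"] for n in nodes]))
        edges = net.edges_among(nodes)
        if edges:
            es = float(np.mean([edge_score_map.get((kind, pair), 0.0) for kind, pair, _ in edges]))
        else:
            es = 0.0
        rows.append(
            {
                "class_id": class_id,
                "node_A": nodes[0],
                "node_B": nodes[1],
                "node_C": nodes[2],
                "S_motif": alpha * ns + (1 - alpha) * es,
                "mean_node_score": ns,
                "mean_edge_score": es,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "class_id",
            "node_A",
            "node_B",
            "node_C",
            "S_motif",
            "mean_node_score",
            "mean_edge_score",
        ],
    )
    return df.sort_values(
        ["S_motif", "node_A", "node_B", "node_C"], ascending=[False, True, True, True]
    ).reset_index(drop=True)


def rank_and_select(
    node_table: pd.DataFrame, net: MixedNetwork, fraction: float = 0.25
) -> pd.DataFrame:
    """Top ceil(fraction * n) nodes by S_node, with Hub/TF/TG annotation.

    Descending score, ties broken by node id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    df = node_table.copy()
    df = df.iloc[np.lexsort((df.index.astype(str), -df["S_node"].values))]
    n_keep = int(np.ceil(fraction * len(df)))
    df = df.head(n_keep).copy()
    df["rank"] = np.arange(1, len(df) + 1)

    def node_type(n):
        attrs = net.nodes.get(n, {})
        tags = []
        if attrs.get("is_hub"):
            tags.append("Hub")
        if attrs.get("is_tf"):
            tags.append("TF")
        if attrs.get("is_mirna"):
            tags.append("miRNA")
        return "/".join(tags) if tags else "TG"

    df["type"] = [node_type(n) for n in df.index]
    return df


@dataclass
class ComplexReport:
    regulators: tuple  # the mutual pair (A, B)
    primary_target: object  # C of the top regulating-mutual triad
    score: float
    co_regulated: pd.DataFrame  # target, n_motifs
    n_motifs: int
    members: tuple = field(default=())


def extract_top_complex(motif_table: pd.DataFrame) -> ComplexReport | None:
    """The top regulating-mutual (class 10) triad and its co-regulated targets.

    Selects the highest-S_motif class-10 instance (ties by sorted node ids),
    then groups every size-3 instance in ``motif_table`` sharing at least two
    of its nodes by the remaining node (the co-regulated target).
    """
    c10 = motif_table[motif_table["class_id"] == 10]
    if c10.empty:
        warnings.warn("no regulating-mutual (class 10) instance in the network")
        return None
    c10 = c10.sort_values(
        ["S_motif", "node_A", "node_B", "node_C"], ascending=[False, True, True, True]
    )
    top = c10.iloc[0]
    members = (top["node_A"], top["node_B"], top["node_C"])
    mset = set(members)
    targets: dict = {}
    n_motifs = 0
    for _, row in motif_table.iterrows():
        triple = {row["node_A"], row["node_B"], row["node_C"]}
        if triple == mset:
            continue
        shared = triple & mset
        if len(shared) >= 2:
            outside = triple - mset
            tgt = next(iter(outside)) if outside else None
            if tgt is None:
                continue
            targets[tgt] = targets.get(tgt, 0) + 1
            n_motifs += 1
    co = pd.DataFrame(
        sorted(targets.items(), key=lambda kv: (-kv[1], str(kv[0]))),
        columns=["target", "n_motifs"],
    )
    return ComplexReport(
        regulators=(top["node_A"], top["node_B"]),
        primary_target=top["node_C"],
        score=float(top["S_motif"]),
        co_regulated=co,
        n_motifs=n_motifs,
        members=members,
    )
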