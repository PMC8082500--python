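"""Gene regulatory network assembly.

TF->target arcs come from scanning promoter sequences with position weight
matrices at a relative-score (relScore) threshold of 0.85; miRNA->target
arcs come from miRanda-style records filtered at Tot Score >= 140 and
Tot Energy <= -20 kcal/mol; undirected co-expression edges among module
genes are taken from the weighted adjacency above a cutoff.  The result is a
mixed network of typed directed regulation arcs plus undirected weighted
co-expression edges, with nodes flagged TF / miRNA / hub and labeled by
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix with pseudocounted log-odds scoring.

    ``matrix`` is 4 x L over rows A, C, G, T (counts or probabilities).
    Columns are normalized to probabilities, a pseudocount is added and the
    columns renormalized, then log-odds are taken against the background.
    """

    tf_id: str
    matrix: np.ndarray  # 4 x L
    pseudocount: float = 0.01
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x L")
        if (m < 0).any():
            raise ValueError("PWM entries must be non-negative")
        probs = m / m.sum(axis=0, keepdims=True)
        probs = probs + self.pseudocount
        probs = probs / probs.sum(axis=0, keepdims=True)
        self.probs = probs
        self.log_odds = np.log2(probs / np.asarray(self.background)[:, None])
        self.s_min = float(self.log_odds.min(axis=0).sum())
        self.s_max = float(self.log_odds.max(axis=0).sum())

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    def rel_score(self, window: str) -> float:
        """Min-max normalized log-odds score of one window (forward)."""
        idx = [BASES.index(b) for b in window]
        s = float(self.log_odds[idx, range(self.length)].sum())
        if self.s_max == self.s_min:
            return 1.0
        return (s - self.s_min) / (self.s_max - self.s_min)


def read_jaspar(path) -> list[PWM]:
    """Read PWMs from a JASPAR-format file (via Bio.motifs)."""
    pwms = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            mat = np.array([m.counts[b] for b in BASES], dtype=float)
            pwms.append(PWM(tf_id=m.matrix_id or m.name, matrix=mat))
    return pwms


def write_jaspar(pwms: list[PWM], path) -> None:
    records = []
    for p in pwms:
        counts = {b: list(p.matrix[i]) for i, b in enumerate(BASES)}
        m = bio_motifs.Motif(alphabet="GATC", counts=counts)
        m.matrix_id = p.tf_id
        m.name = p.tf_id
        records.append(m)
    with open(path, "w") as fh:
        fh.write(bio_motifs.write(records, "jaspar"))


def read_promoters(path) -> dict[str, str]:
    """Read promoter sequences (record id = gene id) from FASTA."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_promoters(promoters: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene, seq in promoters.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def pwm_scan(
    pwm: PWM, promoters: dict[str, str], threshold: float = 0.85
) -> pd.DataFrame:
    """Scan promoters on both strands; report windows with relScore >= threshold.

    relScore = (s - s_min) / (s_max - s_min), with s the summed log-odds of
    the window and s_min / s_max the PWM's attainable extremes.  Windows
    containing N are skipped.  Positions are 0-based on the forward strand.
    """
    L = pwm.length
    base_idx = {b: i for i, b in enumerate(BASES)}
    rows = []
    for gene, seq in promoters.items():
        seq = seq.upper()
        if len(seq) < L:
            warnings.warn(f"promoter of {gene!r} shorter than motif; skipped")
            continue
        for strand, s in (("+", seq), ("-", seq.translate(_COMPLEMENT)[::-1])):
            codes = np.array([base_idx.get(b, -1) for b in s], dtype=int)
            for start in range(len(s) - L + 1):
                win = codes[start : start + L]
                if (win < 0).any():
                    continue
                score = float(pwm.log_odds[win, range(L)].sum())
                rel = (
                    1.0
                    if pwm.s_max == pwm.s_min
                    else (score - pwm.s_min) / (pwm.s_max - pwm.s_min)
                )
                if rel >= threshold:
                    pos = start if strand == "+" else len(s) - L - start
                    rows.append(
                        {
                            "tf_id": pwm.tf_id,
                            "gene_id": gene,
                            "position": pos,
                            "strand": strand,
                            "relScore": rel,
                        }
                    )
    return pd.DataFrame(rows, columns=["tf_id", "gene_id", "position", "strand", "relScore"])


def read_mirna_targets(path) -> pd.DataFrame:
    """Read miRNA-target records: 4-column TSV or '>mirna gene score energy' lines.

    TSV columns: mirna_id, gene_id, tot_score, tot_energy.  The summary
    dialect uses lines like ``>mir-1 GENE1 150.0 -21.5``.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line.startswith(">"):
                    continue
                parts = line[1:].split()
                if len(parts) < 4:
                    raise ValueError(f"malformed miRanda summary line: {line!r}")
                rows.append(
                    {
                        "mirna_id": parts[0],
                        "gene_id": parts[1],
                        "tot_score": float(parts[2]),
                        "tot_energy": float(parts[3]),
                    }
                )
        return pd.DataFrame(rows)
    df = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "gene_id", "tot_score", "tot_energy"}
    if not required.issubset(df.columns):
        raise ValueError(f"miRNA target TSV must have columns {sorted(required)}")
    return df


def filter_mirna_targets(
    records: pd.DataFrame, score_min: float = 140.0, energy_max: float = -20.0
) -> pd.DataFrame:
    """Keep records with tot_score >= score_min and tot_energy <= energy_max."""
    keep = (records["tot_score"] >= score_min) & (records["tot_energy"] <= energy_max)
    return records[keep].reset_index(drop=True)


class MixedNetwork:
    """Regulatory arcs (TF / miRNA) plus undirected weighted co-expression edges.

    ``nodes`` maps node id -> attribute dict (is_tf, is_mirna, is_hub,
    module); ``regulation`` maps (source, target) -> {"edge_type", "weight"};
    ``coexpression`` maps frozenset({u, v}) -> weight.
    """

    def __init__(self) -> None:
        self.nodes: dict = {}
        self.regulation: dict = {}
        self.coexpression: dict = {}

    def add_node(self, node, **attrs) -> None:
        base = self.nodes.setdefault(
            node, {"is_tf": False, "is_mirna": False, "is_hub": False, "module": None}
        )
        base.update({k: v for k, v in attrs.items() if v is not None})

    def add_regulation(self, source, target, edge_type: str, weight: float = 1.0) -> None:
        if source == target:
            raise ValueError(f"self-arc on {source!r}")
        src = self.nodes.get(source, {})
        if edge_type == "tf_regulation" and not src.get("is_tf"):
            raise ValueError(f"arc source {source!r} is not flagged TF")
        if edge_type == "mirna_regulation" and not src.get("is_mirna"):
            raise ValueError(f"arc source {source!r} is not flagged miRNA")
        prev = self.regulation.get((source, target))
        if prev is None or weight > prev["weight"]:
            self.regulation[(source, target)] = {"edge_type": edge_type, "weight": weight}

    def add_coexpression(self, u, v, weight: float) -> None:
        if u == v:
            raise ValueError(f"self-edge on {u!r}")
        self.coexpression[frozenset((u, v))] = float(weight)

    def degree(self, node) -> int:
        """Regulation arcs (in + out) plus co-expression edges, each once."""
        d = sum(1 for (s, t) in self.regulation if s == node or t == node)
        d += sum(1 for pair in self.coexpression if node in pair)
        return d

    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges_among(self, triple):
        """Distinct typed edges among a node triple (for motif scoring)."""
        tset = set(triple)
        out = []
        for (s, t), attrs in sorted(self.regulation.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
            if s in tset and t in tset:
                out.append(("regulation", (s, t), attrs["edge_type"]))
        for pair in sorted(self.coexpression, key=lambda p: sorted(map(str, p))):
            if pair <= tset:
                u, v = sorted(pair, key=str)
                out.append(("coexpression", (u, v), "coexpression"))
        return out

    def to_networkx(self) -> nx.MultiDiGraph:
        G = nx.MultiDiGraph()
        for node, attrs in self.nodes.items():
            G.add_node(node, **{k: ("" if v is None else v) for k, v in attrs.items()})
        for (s, t), attrs in self.regulation.items():
            G.add_edge(s, t, edge_type=attrs["edge_type"], weight=attrs["weight"], directed=True)
        for pair, w in self.coexpression.items():
            u, v = sorted(pair, key=str)
            G.add_edge(u, v, edge_type="coexpression", weight=w, directed=False)
        return G

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for (s, t), attrs in sorted(self.regulation.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
            rows.append(
                {"source": s, "target": t, "edge_type": attrs["edge_type"],
                 "weight": attrs["weight"], "directed": True}
            )
        for pair in sorted(self.coexpression, key=lambda p: sorted(map(str, p))):
            u, v = sorted(pair, key=str)
            rows.append(
                {"source": u, "target": v, "edge_type": "coexpression",
                 "weight": self.coexpression[pair], "directed": False}
            )
        return pd.DataFrame(rows, columns=["source", "target", "edge_type", "weight", "directed"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node in sorted(self.nodes, key=str):
            attrs = self.nodes[node]
            rows.append({"gene_id": node, **attrs})
        return pd.DataFrame(rows)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def assemble_network(
    module_genes,
    hubs,
    tf_arcs: pd.DataFrame,
    mirna_arcs: pd.DataFrame,
    A: pd.DataFrame,
    coexpr_cutoff: float = 0.1,
    tf_set=(),
    mirna_set=(),
    modules: pd.Series | None = None,
) -> MixedNetwork:
    """Combine regulation arcs and thresholded co-expression edges.

    ``tf_arcs`` needs columns (tf_id, gene_id) and optionally relScore;
    ``mirna_arcs`` needs (mirna_id, gene_id).  Arc endpoints must be module
    genes (miRNA sources excepted).  A co-expression edge (i, j) is included
    iff ``a_ij >= coexpr_cutoff``.  Isolated nodes are dropped.
    """
    module_genes = list(module_genes)
    gene_set = set(module_genes)
    tf_set, mirna_set, hub_set = set(tf_set), set(mirna_set), set(hubs)
    net = MixedNetwork()

    def ensure(node):
        net.add_node(
            node,
            is_tf=node in tf_set,
            is_mirna=node in mirna_set,
            is_hub=node in hub_set,
            module=(modules.get(node) if modules is not None else None),
        )

    for _, row in tf_arcs.iterrows():
        s, t = row["tf_id"], row["gene_id"]
        if s == t:
            continue
        if s not in gene_set or t not in gene_set:
            raise ValueError(f"TF arc endpoint outside module genes: {s}->{t}")
        ensure(s)
        ensure(t)
        net.add_regulation(s, t, "tf_regulation", float(row.get("relScore", 1.0)))
    for _, row in mirna_arcs.iterrows():
        s, t = row["mirna_id"], row["gene_id"]
        if t not in gene_set:
            raise ValueError(f"miRNA arc target outside module genes: {s}->{t}")
        ensure(s)
        ensure(t)
        net.add_regulation(s, t, "mirna_regulation", 1.0)
    present = [g for g in module_genes if g in set(A.index)]
    a = A.loc[present, present].values
    iu, ju = np.triu_indices(len(present), k=1)
    sel = a[iu, ju] >= coexpr_cutoff
    for i, j in zip(iu[sel], ju[sel]):
        u, v = present[i], present[j]
        ensure(u)
        ensure(v)
        net.add_coexpression(u, v, a[i, j])
    return net
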