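import functools

import numpy as np
import pandas as pd
import pytest

from triadnet import (
    coexpression_network as cx,
    expression_io as eio,
    grn_assembly as grn,
    importance_scoring as sc,
    motif_census as mc,
    profile_analysis as pa,
    synthetic_data as sd,
)


@pytest.fixture
def toy_expression():
    """3 genes x 4 samples with simple metadata (2 tissues, 2 conditions)."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [0.0, 1.0, 0.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "condition": ["A", "A", "B", "B"],
            "tissue": ["lung", "liver", "lung", "liver"],
            "replicate": [1, 1, 1, 1],
        }
    )
    return eio.ExpressionMatrix(values), eio.SampleMetadata(meta)


@functools.lru_cache(maxsize=8)
def recovery_run(seed: int):
    """Full synthetic-recovery pipeline for one seed (cached across tests)."""
    cfg = sd.SimulationConfig(seed=seed)
    X, meta, truth = sd.simulate_expression(cfg)
    Xc = X.subset_samples(meta.samples_for(condition="highland"))
    A = cx.adjacency(Xc, 20)
    assign = cx.merge_modules(cx.detect_modules(cx.tom(A), 30, 0.99), Xc, 0.9)
    mes, _ = cx.module_eigengenes(Xc, assign)
    stats = cx.gene_module_stats(Xc, meta, A, assign, mes)
    keys = cx.key_modules(mes, meta, stats)
    module_genes = [g for g in assign.index if assign[g] != cx.UNASSIGNED]
    arcs = truth.arcs
    tf_arcs = arcs[arcs.edge_type == "tf_regulation"].rename(
        columns={"source": "tf_id", "target": "gene_id"}
    )
    mi_arcs = arcs[arcs.edge_type == "mirna_regulation"].rename(
        columns={"source": "mirna_id", "target": "gene_id"}
    )
    gene_set = set(module_genes)
    tf_arcs = tf_arcs[tf_arcs.tf_id.isin(gene_set) & tf_arcs.gene_id.isin(gene_set)]
    mi_arcs = mi_arcs[mi_arcs.gene_id.isin(gene_set)]
    net = grn.assemble_network(
        module_genes,
        [],
        tf_arcs,
        mi_arcs,
        A,
        coexpr_cutoff=0.1,
        tf_set=truth.tf_set,
        mirna_set=truth.mirna_set,
        modules=assign,
    )
    G = mc.directify(net)
    tsir = pa.tsi(pa.tissue_means(Xc, meta, "highland"))
    node_tab = sc.node_scores(net, X, meta, "lung", tsir.table)
    edge_map = sc.edge_scores(net, A)
    inst = {cid: mc.find_motif_instances(G, cid) for cid in (7, 9, 10)}
    motif_tab = sc.motif_scores(
        [(cid, i) for cid in (7, 9, 10) for i in inst[cid]], node_tab, edge_map, net
    )
    report = sc.extract_top_complex(motif_tab)
    return {
        "X": X,
        "Xc": Xc,
        "meta": meta,
        "truth": truth,
        "A": A,
        "assign": assign,
        "mes": mes,
        "stats": stats,
        "keys": keys,
        "net": net,
        "G": G,
        "tsi": tsir,
        "instances": inst,
        "motif_table": motif_tab,
        "complex": report,
    }


@pytest.fixture(scope="session")
def recovery():
    return recovery_run


def random_digraph(n: int, p: float, seed: int):
    import networkx as nx

    rng = np.random.default_rng(seed)
    M = rng.random((n, n)) < p
    np.fill_diagonal(M, False)
    return nx.from_numpy_array(M.astype(int), create_using=nx.DiGraph)
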