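"""Config-driven orchestration of the full analysis.

Stages (dependency order): filter -> network/modules -> patterns + tsi +
hubs -> regulatory-network assembly -> motif census + significance ->
importance scoring -> optional cross-dataset validation.  Every run writes a
JSON manifest recording parameters, seeds and produced artifacts; reruns
with an identical config are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    coexpression_network as cx,
    expression_io as eio,
    grn_assembly as grn,
    importance_scoring as scoring,
    motif_census as mc,
    profile_analysis as pa,
)

DEFAULTS = {
    "condition": None,
    "keep_fraction": 0.5,
    "log2": False,
    "beta": "auto",
    "beta_grid": list(range(1, 21)),
    "r2_goal": 0.85,
    "min_module_size": 30,
    "cut_height": 0.99,
    "merge_threshold": 0.9,
    "clusters": 8,
    "fuzzifier": 2.0,
    "pattern_seed": 7,
    "coexpr_cutoff": 0.1,
    "relscore_threshold": 0.85,
    "mirna_score_min": 140.0,
    "mirna_energy_max": -20.0,
    "focal_tissue": "lung",
    "n_random": 100,
    "switches_per_arc": 100,
    "seed": 0,
    "score_alpha": 0.5,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: dict, outdir) -> dict:
    """Execute the pipeline per ``config``; returns the manifest dict.

    Required config keys: ``expression`` and ``metadata`` (TSV paths).
    Optional inputs: ``arcs`` (precomputed regulation-arc TSV), ``pwms`` +
    ``promoters`` (JASPAR + FASTA for TF-target scanning), ``mirna_targets``
    (miRanda-style records), ``tf_list`` / ``mirna_list`` (one id per line).
    All other keys override :data:`DEFAULTS`.
    """
    cfg = {**DEFAULTS, **config}
    for key in ("expression", "metadata"):
        if not cfg.get(key):
            raise ValueError(f"config missing required field {key!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {k: v for k, v in cfg.items()}, "artifacts": {}}

    def emit(name, path):
        # stored relative to outdir so reruns elsewhere are byte-identical
        manifest["artifacts"][name] = Path(path).name

    stage = "load"
    try:
        X_full, meta = eio.read_expression(cfg["expression"], cfg["metadata"])
        X = X_full
        if cfg["condition"]:
            X = X.subset_samples(meta.samples_for(condition=cfg["condition"]))

        stage = "filter"
        Xf, report = eio.mad_filter(X, cfg["keep_fraction"], log2=cfg["log2"])
        eio.write_expression(Xf, outdir / "filtered.tsv")
        (outdir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        emit("filtered", outdir / "filtered.tsv")

        stage = "network"
        if cfg["beta"] == "auto":
            st = cx.pick_soft_threshold(Xf, cfg["beta_grid"], cfg["r2_goal"])
            beta = st.selected
            st.table.to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False)
        else:
            beta = int(cfg["beta"])
        manifest["parameters"]["beta_used"] = beta
        A = cx.adjacency(Xf, beta)
        Omega = cx.tom(A)

        stage = "modules"
        assignment = cx.detect_modules(
            Omega, cfg["min_module_size"], cfg["cut_height"]
        )
        assignment = cx.merge_modules(assignment, Xf, cfg["merge_threshold"])
        mes, _ = cx.module_eigengenes(Xf, assignment)
        stats_df = cx.gene_module_stats(Xf, meta, A, assignment, mes)
        keys = cx.key_modules(mes, meta, stats_df)
        assignment.rename("module").to_csv(outdir / "modules.tsv", sep="\t")
        stats_df.to_csv(outdir / "stats.tsv", sep="\t")
        keys.to_csv(outdir / "key_modules.tsv", sep="\t", index=False)
        emit("modules", outdir / "modules.tsv")
        emit("key_modules", outdir / "key_modules.tsv")
        module_tissue = {
            row["module"]: row["tissue"]
            for _, row in keys[keys["is_key"]].iterrows()
        }
        concepts_rows = []
        for mod, tissue in module_tissue.items():
            genes = assignment.index[assignment == mod]
            nc = cx.network_concepts(A.loc[genes, genes])
            concepts_rows.append({"module": mod, "tissue": tissue, **nc.as_dict()})
        pd.DataFrame(
            concepts_rows, columns=["module", "tissue", "DS", "MCC", "CL", "HG"]
        ).to_csv(outdir / "concepts.tsv", sep="\t", index=False)
        hubs = cx.hub_genes(stats_df, module_tissue)
        hub_flat = sorted({g for gs in hubs.values() for g in gs})
        (outdir / "hubs.txt").write_text("\n".join(hub_flat) + "\n")

        stage = "patterns"
        condition = cfg["condition"] or meta.conditions[0]
        key_genes = [g for g in assignment.index if assignment[g] != cx.UNASSIGNED]
        profile = pa.tissue_means(Xf.subset_genes(key_genes), meta, condition)
        std = pa.standardize_profile(profile)
        if len(std) >= cfg["clusters"]:
            fcm = pa.fuzzy_cmeans(
                std, c=cfg["clusters"], m=cfg["fuzzifier"], seed=cfg["pattern_seed"]
            )
            fcm.membership.to_csv(outdir / "memberships.tsv", sep="\t")

        stage = "tsi"
        full_profile = pa.tissue_means(Xf, meta, condition)
        tsi_res = pa.tsi(full_profile)
        tsi_res.table.to_csv(outdir / "tsi.tsv", sep="\t")
        emit("tsi", outdir / "tsi.tsv")

        stage = "grn"
        tf_set = _read_list(cfg.get("tf_list"))
        mirna_set = _read_list(cfg.get("mirna_list"))
        module_genes = key_genes
        gene_set = set(module_genes)
        if cfg.get("arcs"):
            arc_df = pd.read_csv(cfg["arcs"], sep="\t")
            tf_arcs = arc_df[arc_df["edge_type"] == "tf_regulation"].rename(
                columns={"source": "tf_id", "target": "gene_id"}
            )
            mirna_arcs = arc_df[arc_df["edge_type"] == "mirna_regulation"].rename(
                columns={"source": "mirna_id", "target": "gene_id"}
            )
        else:
            hits = []
            if cfg.get("pwms") and cfg.get("promoters"):
                promoters = grn.read_promoters(cfg["promoters"])
                promoters = {g: s for g, s in promoters.items() if g in gene_set}
                for pwm in grn.read_jaspar(cfg["pwms"]):
                    if pwm.tf_id in gene_set:
                        hits.append(
                            grn.pwm_scan(pwm, promoters, cfg["relscore_threshold"])
                        )
            tf_arcs = (
                pd.concat(hits, ignore_index=True)
                if hits
                else pd.DataFrame(columns=["tf_id", "gene_id", "relScore"])
            )
            if not tf_arcs.empty:
                tf_arcs = (
                    tf_arcs.sort_values("relScore", ascending=False)
                    .drop_duplicates(["tf_id", "gene_id"])
                )
                tf_arcs = tf_arcs[tf_arcs["tf_id"] != tf_arcs["gene_id"]]
            if cfg.get("mirna_targets"):
                recs = grn.read_mirna_targets(cfg["mirna_targets"])
                recs = grn.filter_mirna_targets(
                    recs, cfg["mirna_score_min"], cfg["mirna_energy_max"]
                )
                mirna_arcs = recs[["mirna_id", "gene_id"]]
            else:
                mirna_arcs = pd.DataFrame(columns=["mirna_id", "gene_id"])
        tf_arcs = tf_arcs[
            tf_arcs["tf_id"].isin(gene_set) & tf_arcs["gene_id"].isin(gene_set)
        ]
        mirna_arcs = mirna_arcs[mirna_arcs["gene_id"].isin(gene_set)]
        tf_set = (tf_set or set(tf_arcs["tf_id"])) & gene_set
        mirna_set = mirna_set or set(mirna_arcs["mirna_id"])
        net = grn.assemble_network(
            module_genes,
            hub_flat,
            tf_arcs,
            mirna_arcs,
            A,
            coexpr_cutoff=cfg["coexpr_cutoff"],
            tf_set=tf_set,
            mirna_set=mirna_set,
            modules=assignment,
        )
        net.edge_table().to_csv(outdir / "grn_edges.tsv", sep="\t", index=False)
        net.node_table().to_csv(outdir / "grn_nodes.tsv", sep="\t", index=False)
        net.write_graphml(outdir / "grn.graphml")
        emit("grn", outdir / "grn.graphml")

        stage = "motifs"
        G = mc.directify(net)
        counts = mc.triad_census(G)
        ensemble = mc.null_ensemble(
            G,
            n_random=cfg["n_random"],
            switches_per_arc=cfg["switches_per_arc"],
            seed=cfg["seed"],
        )
        sig = mc.significance(counts, ensemble)
        sig.as_table().to_csv(outdir / "motif_significance.tsv", sep="\t", index=False)
        emit("motif_significance", outdir / "motif_significance.tsv")

        stage = "score"
        node_tab = scoring.node_scores(
            net, X_full, meta, cfg["focal_tissue"], tsi_res.table,
        )
        edge_map = scoring.edge_scores(net, A)
        # score the regulator-anchored classes (FFL, regulated/regulating
        # mutual); all-mutual co-expression triangles are not scored
        inst_list = [
            (cid, inst)
            for cid in (7, 9, 10)
            for inst in mc.find_motif_instances(G, cid)
        ]
        motif_tab = scoring.motif_scores(
            inst_list, node_tab, edge_map, net, alpha=cfg["score_alpha"]
        )
        ranked = scoring.rank_and_select(node_tab, net, fraction=0.25)
        node_tab.to_csv(outdir / "scores.tsv", sep="\t")
        motif_tab.to_csv(outdir / "motif_scores.tsv", sep="\t", index=False)
        ranked.to_csv(outdir / "top_nodes.tsv", sep="\t")
        emit("scores", outdir / "scores.tsv")
        report = scoring.extract_top_complex(motif_tab)
        if report is not None:
            (outdir / "complex.json").write_text(
                json.dumps(
                    {
                        "regulators": [str(x) for x in report.regulators],
                        "primary_target": str(report.primary_target),
                        "score": report.score,
                        "n_motifs": report.n_motifs,
                        "co_regulated": report.co_regulated.to_dict("records"),
                    },
                    indent=2,
                )
            )
            emit("complex", outdir / "complex.json")
    except Exception as exc:  # partial outputs are retained on disk
        raise StageError(stage, exc) from exc

    manifest["seeds"] = {"pattern_seed": cfg["pattern_seed"], "seed": cfg["seed"]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _read_list(path) -> set:
    if not path:
        return set()
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_demo_fixtures(outdir, seed: int = 0) -> dict:
    """Simulate a full synthetic study and write every pipeline input."""
    from . import synthetic_data as sd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = sd.SimulationConfig(seed=seed)
    X, meta, truth = sd.simulate_expression(cfg)
    pwms, promoters = sd.simulate_pwm_and_promoters(cfg, truth)
    eio.write_expression(X, outdir / "expression.tsv")
    eio.write_metadata(meta, outdir / "metadata.tsv")
    truth.arcs.to_csv(outdir / "planted_arcs.tsv", sep="\t", index=False)
    grn.write_jaspar(pwms, outdir / "pwms.jaspar")
    grn.write_promoters(promoters, outdir / "promoters.fa")
    (outdir / "tf_list.txt").write_text("\n".join(sorted(truth.tf_set)) + "\n")
    (outdir / "mirna_list.txt").write_text("\n".join(sorted(truth.mirna_set)) + "\n")
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "modules": truth.modules.to_dict(),
                "module_tissue": truth.module_tissue,
                "ts_genes": truth.ts_genes,
                "tf_set": sorted(truth.tf_set),
                "mirna_set": sorted(truth.mirna_set),
                "triads": [
                    {**t, "nodes": list(t["nodes"])} for t in truth.triads
                ],
            },
            indent=2,
        )
    )
    return {
        "expression": str(outdir / "expression.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "arcs": str(outdir / "planted_arcs.tsv"),
        "tf_list": str(outdir / "tf_list.txt"),
        "mirna_list": str(outdir / "mirna_list.txt"),
    }


def demo(outdir, seed: int = 0, n_random: int = 50) -> dict:
    """One-command synthetic end-to-end run (simulate + full pipeline)."""
    outdir = Path(outdir)
    inputs = write_demo_fixtures(outdir / "fixtures", seed=seed)
    config = {
        **inputs,
        "condition": "highland",
        "keep_fraction": 0.5,
        "beta": 20,
        "n_random": n_random,
        "seed": seed,
    }
    return run(config, outdir / "results")
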