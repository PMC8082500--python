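"""Synthetic multi-tissue expression data with planted ground truth.

Emulates the study design the pipeline targets: 2 conditions x 6 tissues x 3
replicates, a few hundred genes, a TF subset, a few miRNAs, planted
tissue-elevated co-expression modules, planted tissue-specific genes and
planted regulatory triads (including one high-importance regulating-mutual
"complex").

Module genes follow a latent-factor model: for gene g in module m,

    x_gs = b_g * max(0, 1 + (F-1)*[tissue(s)=T_m] + lam*z_s + sigma*eps_gs)

with per-gene baseline ``b_g`` (log-normal), module target tissue ``T_m``
and fold change ``F``, a module-shared per-sample latent factor ``z_s`` and
gene-independent noise.  The loading ``lam = sigma * sqrt(rho/(1-rho))``
yields within-module correlation ``rho`` before the (shared) tissue effect,
exactly the correlation structure weighted co-expression module detection
assumes.  Expression is floored at 0 to respect non-negativity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleMetadata
from .motif_census import TRIAD_CLASSES

DEFAULT_TISSUES = ("muscle", "liver", "heart", "spleen", "kidney", "lung")


@dataclass
class ModuleSpec:
    size: int = 60
    target_tissue: str = "lung"
    within_cor: float = 0.9
    fold_change: float = 6.0


@dataclass
class TriadSpec:
    class_id: int  # 1..13
    label: str = ""


@dataclass
class SimulationConfig:
    n_genes: int = 500
    tissues: tuple = DEFAULT_TISSUES
    conditions: tuple = ("highland", "lowland")
    n_replicates: int = 3
    module_specs: list = field(
        default_factory=lambda: [
            ModuleSpec(60, "muscle"),
            ModuleSpec(60, "liver"),
            ModuleSpec(60, "kidney"),
            ModuleSpec(60, "lung"),
        ]
    )
    n_tfs: int = 24
    n_mirnas: int = 3
    ts_genes_per_tissue: int = 3
    ts_fold: float = 30.0
    planted_triads: list = field(
        default_factory=lambda: [
            TriadSpec(7, "ffl"),
            TriadSpec(9, "regulated-mutual"),
            TriadSpec(10, "complex"),
            TriadSpec(13, "clique"),
        ]
    )
    targets_per_tf: int = 2
    complex_extra_targets: int = 6
    complex_module: int = 3  # index into module_specs (default: the lung module)
    complex_condition_fold: float = 3.0
    noise_sd: float = 0.3  # relative (multiplies the gene baseline)
    baseline_log_mean: float = 2.0  # natural-log scale of the log-normal baseline
    baseline_log_sd: float = 0.5
    promoter_length: int = 300
    pwm_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.size for m in self.module_specs) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for m in self.module_specs:
            if m.size < 3:
                raise ValueError("module size must be >= 3 (eigengene undefined)")
            if m.target_tissue not in self.tissues:
                raise ValueError(f"unknown target tissue {m.target_tissue!r}")
        for t in self.planted_triads:
            if t.class_id not in TRIAD_CLASSES:
                raise ValueError(f"unknown triad class {t.class_id}")


@dataclass
class GroundTruth:
    modules: pd.Series  # gene -> module label ("unassigned" for background)
    module_tissue: dict  # module label -> target tissue
    ts_genes: dict  # gene -> dominant tissue
    tf_set: set
    mirna_set: set
    arcs: pd.DataFrame  # source, target, edge_type
    triads: list  # dicts: class_id, label, nodes (A, B, C)
    latent_factors: pd.DataFrame  # samples x modules shared signal

    @property
    def complex_triad(self) -> dict | None:
        for t in self.triads:
            if t["class_id"] == 10:
                return t
        return None


def _sample_ids(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cond in cfg.conditions:
        for tissue in cfg.tissues:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_{tissue}_{rep}",
                        "condition": cond,
                        "tissue": tissue,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_regulatory_truth(cfg: SimulationConfig, rng=None):
    """Plant regulatory arcs and triad instances on the gene roster.

    Returns (gene roster info, arcs DataFrame, triad list).  Triad members
    are placed in distinct co-expression modules so that cross-member
    co-expression stays low and each planted triple keeps its class in the
    assembled network; the regulating-mutual "complex" puts both regulators
    in the same (focal) module so they are strongly co-expressed.  Every
    TF's extra targets are drawn without global replacement, so no two
    regulators share a random target: the planted complex is the unique
    shared-target mutual-regulator triple.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n_mod = len(cfg.module_specs)
    module_labels = [f"PM{i + 1}" for i in range(n_mod)]
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    modules = pd.Series("unassigned", index=genes, dtype=object)
    pos = 0
    module_members: dict[str, list] = {}
    for lab, spec in zip(module_labels, cfg.module_specs):
        members = genes[pos : pos + spec.size]
        modules[members] = lab
        module_members[lab] = members
        pos += spec.size
    background = genes[pos:]

    # TFs: spread over modules (round-robin over the first genes of each);
    # without modules, TFs are taken from the background
    tfs = []
    if n_mod:
        per_mod = -(-cfg.n_tfs // n_mod)
        for lab in module_labels:
            tfs.extend(module_members[lab][:per_mod])
        tfs = tfs[: cfg.n_tfs]
    else:
        if cfg.planted_triads:
            raise ValueError("planted triads require at least one module")
        tfs = background[: cfg.n_tfs]
    tf_set = set(tfs)
    mirnas = [f"mir-{i + 1}" for i in range(cfg.n_mirnas)]

    arcs = []
    triads = []
    used = set()

    def take(module_idx, want_tf):
        lab = module_labels[module_idx % n_mod]
        pool = [
            g
            for g in module_members[lab]
            if g not in used and ((g in tf_set) == want_tf)
        ]
        if not pool and want_tf:
            # promote an unused module gene to TF for this regulator slot
            pool = [g for g in module_members[lab] if g not in used]
        if not pool:
            raise ValueError("module too small to host planted triads/TFs")
        g = pool[0]
        used.add(g)
        if want_tf:
            tf_set.add(g)
        return g

    complex_mod = cfg.complex_module % n_mod if n_mod else 0
    for t in cfg.planted_triads:
        rep_arcs = TRIAD_CLASSES[t.class_id]["arcs"]
        slots_with_out = {a for a, _ in rep_arcs}
        if t.class_id == 10:
            # both regulators co-expressed in the focal module, target elsewhere
            nodes = [
                take(complex_mod, True),
                take(complex_mod, True),
                take(complex_mod + 1, True),
            ]
        else:
            # members in distinct non-focal modules; out-arc slots must be TFs
            offset = complex_mod + 1
            nodes = [take(offset + slot, slot in slots_with_out) for slot in range(3)]
        for a, b in rep_arcs:
            arcs.append(
                {"source": nodes[a], "target": nodes[b], "edge_type": "tf_regulation"}
            )
        tf_set.update(nodes[s] for s in slots_with_out)
        triads.append({"class_id": t.class_id, "label": t.label, "nodes": tuple(nodes)})

    # random extra targets: globally without replacement, never a planted node
    target_pool = [g for g in genes if g not in tf_set and g not in used and modules[g] != "unassigned"]
    target_pool = list(rng.permutation(target_pool))
    complex_nodes = ()
    for t in triads:
        if t["class_id"] == 10:
            complex_nodes = t["nodes"]

    def next_targets(k):
        out = [target_pool.pop() for _ in range(min(k, len(target_pool)))]
        return out

    for tf in sorted(tf_set):
        k = cfg.targets_per_tf
        if complex_nodes and tf in complex_nodes[:2]:
            k += cfg.complex_extra_targets
        for tgt in next_targets(k):
            arcs.append({"source": tf, "target": tgt, "edge_type": "tf_regulation"})
    for mir in mirnas:
        for tgt in next_targets(2):
            arcs.append({"source": mir, "target": tgt, "edge_type": "mirna_regulation"})

    arcs_df = pd.DataFrame(arcs, columns=["source", "target", "edge_type"]).drop_duplicates()
    roster = {
        "genes": genes,
        "modules": modules,
        "module_members": module_members,
        "module_labels": module_labels,
        "background": background,
        "tf_set": tf_set,
        "mirnas": mirnas,
        "complex_nodes": complex_nodes,
    }
    return roster, arcs_df, triads


def simulate_expression(cfg: SimulationConfig):
    """Generate (ExpressionMatrix, SampleMetadata, GroundTruth).

    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    truth_rng = np.random.default_rng(cfg.seed + 1)
    roster, arcs_df, triads = simulate_regulatory_truth(cfg, truth_rng)
    meta_df = _sample_ids(cfg)
    samples = list(meta_df["sample_id"])
    n_samples = len(samples)
    tissue_of = meta_df.set_index("sample_id")["tissue"]
    cond_of = meta_df.set_index("sample_id")["condition"]

    genes = roster["genes"]
    modules = roster["modules"]
    baselines = pd.Series(
        rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(genes)),
        index=genes,
    )

    # tissue-specific genes: drawn from the background pool
    ts_genes: dict[str, str] = {}
    bg = list(roster["background"])
    i = 0
    for tissue in cfg.tissues:
        for _ in range(cfg.ts_genes_per_tissue):
            if i >= len(bg):
                break
            ts_genes[bg[i]] = tissue
            i += 1

    sigma = cfg.noise_sd
    X = np.zeros((len(genes), n_samples))
    tissue_arr = tissue_of.loc[samples].values
    latent = {}
    module_of_label = dict(zip(roster["module_labels"], cfg.module_specs))
    for lab in roster["module_labels"]:
        spec = module_of_label[lab]
        z = rng.standard_normal(n_samples)
        lam = sigma * np.sqrt(spec.within_cor / (1.0 - spec.within_cor))
        shared = (spec.fold_change - 1.0) * (tissue_arr == spec.target_tissue) + lam * z
        latent[lab] = shared
        idx = [genes.index(g) for g in roster["module_members"][lab]]
        eps = rng.standard_normal((len(idx), n_samples))
        rel = 1.0 + shared[None, :] + sigma * eps
        X[idx, :] = baselines.values[idx, None] * np.clip(rel, 0.0, None)
    for g, tissue in ts_genes.items():
        gi = genes.index(g)
        rel = (
            1.0
            + (cfg.ts_fold - 1.0) * (tissue_arr == tissue)
            + sigma * rng.standard_normal(n_samples)
        )
        X[gi, :] = baselines.values[gi] * np.clip(rel, 0.0, None)
    remaining = [
        gi
        for gi, g in enumerate(genes)
        if modules[g] == "unassigned" and g not in ts_genes
    ]
    eps = rng.standard_normal((len(remaining), n_samples))
    X[remaining, :] = baselines.values[remaining, None] * np.clip(
        1.0 + sigma * eps, 0.0, None
    )

    # condition-differential expression on the planted complex (all tissues;
    # the focal-tissue fold change is what downstream scoring measures)
    complex_nodes = roster["complex_nodes"]
    if complex_nodes:
        cond2 = (cond_of.loc[samples].values == cfg.conditions[1])
        for g in complex_nodes:
            X[genes.index(g), cond2] /= cfg.complex_condition_fold

    # miRNAs: background-like expression rows
    mirna_rows = []
    for mir in roster["mirnas"]:
        b = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd)
        mirna_rows.append(
            b * np.clip(1.0 + sigma * rng.standard_normal(n_samples), 0.0, None)
        )
    all_ids = genes + roster["mirnas"]
    values = pd.DataFrame(
        np.vstack([X] + [np.asarray(mirna_rows)]) if mirna_rows else X,
        index=all_ids,
        columns=samples,
    )
    modules_full = modules.reindex(all_ids, fill_value="unassigned")

    truth = GroundTruth(
        modules=modules_full,
        module_tissue={
            lab: spec.target_tissue
            for lab, spec in zip(roster["module_labels"], cfg.module_specs)
        },
        ts_genes=ts_genes,
        tf_set=set(roster["tf_set"]),
        mirna_set=set(roster["mirnas"]),
        arcs=arcs_df,
        triads=triads,
        latent_factors=pd.DataFrame(latent, index=samples),
    )
    return ExpressionMatrix(values), SampleMetadata(meta_df), truth


def simulate_pwm_and_promoters(cfg: SimulationConfig, truth: GroundTruth):
    """PWMs for arc-bearing TFs and promoters with planted consensus sites.

    Each TF with at least one planted TF->target arc gets an informative PWM
    (85% weight on its consensus base per column); the TF's consensus is
    embedded at a random position of each of its targets' promoters, so a
    scan at relScore >= 0.85 recovers every planted site (the consensus
    scores exactly 1.0).  Non-target promoters are i.i.d. background.
    """
    from .grn_assembly import PWM

    rng = np.random.default_rng(cfg.seed + 2)
    tf_arcs = truth.arcs[truth.arcs["edge_type"] == "tf_regulation"]
    promoter_genes = sorted(set(tf_arcs["target"]) | set(tf_arcs["source"]))
    promoters = {
        g: "".join(rng.choice(list("ACGT"), size=cfg.promoter_length))
        for g in promoter_genes
    }
    pwms = []
    for tf in sorted(set(tf_arcs["source"])):
        consensus_idx = rng.integers(0, 4, size=cfg.pwm_length)
        mat = np.full((4, cfg.pwm_length), 5.0)
        mat[consensus_idx, range(cfg.pwm_length)] = 85.0
        pwm = PWM(tf_id=tf, matrix=mat)
        pwms.append(pwm)
        site = pwm.consensus()
        for tgt in sorted(tf_arcs.loc[tf_arcs["source"] == tf, "target"]):
            seq = promoters[tgt]
            start = int(rng.integers(0, len(seq) - cfg.pwm_length + 1))
            promoters[tgt] = seq[:start] + site + seq[start + cfg.pwm_length :]
    return pwms, promoters
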