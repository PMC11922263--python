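"""File-based pipeline stages composing the library into an end-to-end run.

Each stage reads its inputs from ``outdir`` (or the sample manifest), runs
the corresponding library module, and writes plain-text outputs (TSV / JSON /
Matrix Market). Stages are deterministic given the config and seed: the same
run twice produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import classify as _classify
from . import embed as _embed
from . import gating as _gating
from . import io as _io
from . import qc as _qc
from . import repertoire as _rep
from . import simulate as _sim

log = logging.getLogger(__name__)

FLOAT_FMT = "%.8g"


def _jwrite(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _twrite(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def stage_simulate(cfg: dict, outdir: str) -> dict:
    """Generate the synthetic cohort and write per-sample 10x-style inputs."""
    sim_dir = os.path.join(outdir, "sim")
    sc = _sim.SimulationConfig(seed=cfg["seed"], **cfg["simulate"])
    adata, meta, chains, truth = _sim.generate_cohort(sc)
    manifest = _io.write_cohort(adata, chains, sim_dir, truth=truth.cells)
    truth.clones.to_csv(os.path.join(sim_dir, "truth_clones.tsv"), sep="\t")
    _jwrite(manifest, os.path.join(sim_dir, "manifest.json"))
    return manifest


def _manifest(cfg: dict, outdir: str) -> dict:
    if cfg.get("samples"):
        return cfg["samples"]
    path = os.path.join(outdir, "sim", "manifest.json")
    if not os.path.exists(path):
        raise FileNotFoundError("no samples in config and no simulated manifest; run `simulate` first")
    with open(path) as fh:
        return json.load(fh)


def stage_qc(cfg: dict, outdir: str) -> _qc.QCReport:
    """Pool samples, apply cell/gene filters, write counts + lognorm layers."""
    adata, chains = _io.read_cohort(_manifest(cfg, outdir))
    q = cfg["qc"]
    params = _qc.QCParams(
        min_cells_per_gene=q["min_cells_per_gene"],
        min_features=q["min_features"],
        max_features=q["max_features"],
        cd3_gene=q["cd3_gene"],
        housekeeping_genes=tuple(q["housekeeping_genes"]),
        max_mito_fraction=q["max_mito_fraction"],
        mito_prefix=q["mito_prefix"],
    )
    kept, report = _qc.filter_cells(adata, params)
    lognorm = kept.copy()
    lognorm.X = _qc.normalize_cp10k_log(kept.X)

    qdir = os.path.join(outdir, "qc")
    os.makedirs(qdir, exist_ok=True)
    _io.write_matrix(kept, os.path.join(qdir, "counts"))
    _io.write_matrix(lognorm, os.path.join(qdir, "lognorm"))
    _twrite(kept.obs, os.path.join(qdir, "cells.tsv"))
    _io.write_contigs(chains, os.path.join(qdir, "chains.csv"))
    _jwrite(report.as_dict(), os.path.join(qdir, "report.json"))
    return report


def _load_qc(outdir: str):
    qdir = os.path.join(outdir, "qc")
    lognorm = _io.read_matrix(os.path.join(qdir, "lognorm"), integer=False)
    cells = pd.read_csv(os.path.join(qdir, "cells.tsv"), sep="\t", index_col=0)
    lognorm.obs = cells.loc[lognorm.obs_names]
    return lognorm


def stage_embed(cfg: dict, outdir: str) -> np.ndarray:
    """Variable genes + marker-weighted PCA + KNN graph + clustering."""
    lognorm = _load_qc(outdir)
    e = cfg["embed"]
    hvg = _embed.select_variable_genes(
        lognorm.X, lognorm.var_names, min(e["n_variable_genes"], lognorm.n_vars)
    )
    markers = [g for g in e["marker_genes"] if g in lognorm.var_names]
    features = markers + [g for g in hvg if g not in set(markers)]
    sub = lognorm[:, features]
    scaled = _qc.scale_genes(sub.X, max_value=e["scale_clip"])
    weights = {g: e["marker_weight"] for g in markers}
    emb = _embed.weighted_pca(scaled, features, weights, n_pcs=e["n_pcs"])
    graph = _embed.knn_graph(emb.scores, k=e["k_neighbors"])
    labels = _embed.cluster_graph(graph, resolution=e["resolution"], seed=cfg["seed"])

    edir = os.path.join(outdir, "embed")
    os.makedirs(edir, exist_ok=True)
    pcs = pd.DataFrame(
        emb.scores, index=lognorm.obs_names, columns=[f"PC{i + 1}" for i in range(emb.scores.shape[1])]
    )
    _twrite(pcs, os.path.join(edir, "pcs.tsv"))
    _twrite(pd.DataFrame({"cluster": labels}, index=lognorm.obs_names), os.path.join(edir, "clusters.tsv"))
    pb = _embed.pseudobulk(lognorm[:, markers].X, markers, labels)
    _twrite(pb, os.path.join(edir, "pseudobulk_markers.tsv"))
    return labels


def stage_gate(cfg: dict, outdir: str) -> pd.DataFrame:
    """Compartment, Th-subset and phenotype gating on normalized expression."""
    lognorm = _load_qc(outdir)
    g = cfg["gating"]
    spec = _gating.GateSpec(
        mode=g["mode"], fixed_value=g["fixed_value"], cd8_rule=g["cd8_rule"],
        exhaustion_min=g["exhaustion_min"],
    )
    genes = sorted(
        {spec.cd4_gene, *spec.cd8_genes, spec.gd_gene, *spec.th_markers.values(),
         *spec.slec_markers, *spec.exhaustion_markers}
        & set(lognorm.var_names)
    )
    expr = pd.DataFrame(
        np.asarray(lognorm[:, genes].X.todense()), index=lognorm.obs_names, columns=genes
    )
    thresholds = _gating.compute_thresholds(expr, spec)
    comp, _ = _gating.classify_compartments(expr, spec, thresholds)
    th = pd.Series("NA", index=expr.index, name="th_subset", dtype=object)
    eligible = ~comp.isin(("CD8", "DP"))
    if eligible.any():
        th[eligible] = _gating.classify_th_subsets(expr[eligible], comp[eligible], spec, thresholds)
    pheno = _gating.classify_phenotypes(expr, spec, thresholds)
    state = _gating.state_labels(comp, pheno)

    labels = pd.DataFrame(
        {"compartment": comp, "th_subset": th, "SLEC_like": pheno["SLEC_like"],
         "exhausted": pheno["exhausted"], "state": state}
    )
    gdir = os.path.join(outdir, "gate")
    os.makedirs(gdir, exist_ok=True)
    _twrite(labels, os.path.join(gdir, "labels.tsv"))
    _jwrite({k: round(v, 8) for k, v in thresholds.items()}, os.path.join(gdir, "thresholds.json"))
    return labels


def stage_clonotype(cfg: dict, outdir: str):
    """Assign clonotypes among QC-passing cells; summarize expansion."""
    qdir = os.path.join(outdir, "qc")
    chains = _io.read_contigs(os.path.join(qdir, "chains.csv"))
    cells = pd.read_csv(os.path.join(qdir, "cells.tsv"), sep="\t", index_col=0)
    chains = chains[chains["barcode"].isin(cells.index)]
    clonotypes, cell_map = _rep.assign_clonotypes(chains, strict_vj=cfg["repertoire"]["strict_vj"])
    summary = _rep.expansion_summary(clonotypes, cell_map, cells)

    rdir = os.path.join(outdir, "rep")
    os.makedirs(rdir, exist_ok=True)
    _twrite(clonotypes, os.path.join(rdir, "clonotypes.tsv"), index=False)
    _twrite(cell_map, os.path.join(rdir, "cell_map.tsv"), index=False)
    _jwrite(summary, os.path.join(rdir, "expansion.json"))
    if cfg["repertoire"].get("vdjdb"):
        vdjdb = _io.read_vdjdb(cfg["repertoire"]["vdjdb"])
        epi = _rep.annotate_epitopes(clonotypes, vdjdb, cell_map, cells["tissue"])
        _twrite(epi, os.path.join(rdir, "epitopes.tsv"), index=False)
    return clonotypes, cell_map, summary


def _load_rep(outdir: str):
    rdir = os.path.join(outdir, "rep")
    clonotypes = pd.read_csv(os.path.join(rdir, "clonotypes.tsv"), sep="\t").fillna({"alpha": "", "beta": ""})
    cell_map = pd.read_csv(os.path.join(rdir, "cell_map.tsv"), sep="\t")
    cells = pd.read_csv(os.path.join(outdir, "qc", "cells.tsv"), sep="\t", index_col=0)
    return clonotypes, cell_map, cells


def stage_match(cfg: dict, outdir: str) -> pd.Series:
    """Blood<->islet matching; per-cell infiltration flags."""
    clonotypes, cell_map, cells = _load_rep(outdir)
    flags, matched = _rep.match_tissues(clonotypes, cell_map, cells["tissue"])
    rdir = os.path.join(outdir, "rep")
    _twrite(flags.rename("infiltrating").to_frame(), os.path.join(rdir, "infiltration.tsv"))
    _twrite(matched, os.path.join(rdir, "matched_chains.tsv"), index=False)
    return flags


def stage_transitions(cfg: dict, outdir: str) -> _rep.TransitionGraph:
    """Bootstrap within-clone pair-transition graph over gated states."""
    _, cell_map, cells = _load_rep(outdir)
    labels = pd.read_csv(os.path.join(outdir, "gate", "labels.tsv"), sep="\t", index_col=0)
    # transitions run over coarse states; cells dropped by QC have no state
    cell_map = cell_map[cell_map["barcode"].isin(labels.index)]
    states = labels["state"]
    comp_of = {"SLEC": "CD8", "Texh": "mixed"}
    comp_of.update({c: c for c in _gating.COMPARTMENT_LABELS})
    r = cfg["repertoire"]
    nodes = ["naive", "CD4", "CD8", "DN", "DP", "GD", "SLEC", "Pexh", "Texh"]
    graph = _rep.bootstrap_transitions(
        cell_map, states, n_reps=r["n_reps"],
        min_clone_size_exclusive=r["min_clone_size_exclusive"], seed=cfg["seed"],
        nodes=nodes, compartment_of=comp_of,
    )
    exact = _rep.exact_transitions(
        cell_map, states, min_clone_size_exclusive=r["min_clone_size_exclusive"],
        nodes=nodes, compartment_of=comp_of,
    )
    rdir = os.path.join(outdir, "rep")
    _twrite(graph.edges, os.path.join(rdir, "transitions.tsv"), index=False)
    _twrite(exact.edges, os.path.join(rdir, "transitions_exact.tsv"), index=False)

    fate = _rep.classify_clone_fate(_load_rep(outdir)[0], cell_map, states)
    _twrite(fate.to_frame(), os.path.join(rdir, "clone_fates.tsv"))
    return graph


def stage_classify(cfg: dict, outdir: str) -> _classify.ClassifierReport:
    """Lasso-logistic prediction of infiltration in blood CD8 cells."""
    lognorm = _load_qc(outdir)
    labels = pd.read_csv(os.path.join(outdir, "gate", "labels.tsv"), sep="\t", index_col=0)
    flags = pd.read_csv(os.path.join(outdir, "rep", "infiltration.tsv"), sep="\t", index_col=0)["infiltrating"]
    c = cfg["classifier"]
    subset = (
        (lognorm.obs["tissue"] == c["subset_tissue"]).to_numpy()
        & (labels["compartment"].reindex(lognorm.obs_names) == c["subset_compartment"]).to_numpy()
    )
    sub = lognorm[subset]
    y = flags.reindex(sub.obs_names).to_numpy()
    y = np.where(pd.isna(y), False, y).astype(bool)  # cells outside clonal analysis: non-matching
    X = pd.DataFrame(np.asarray(sub.X.todense()), index=sub.obs_names, columns=sub.var_names)
    spec = _classify.ClassifierSpec(C=c["C"], folds=c["folds"], seed=cfg["seed"])
    if c.get("use_batches"):
        spec.gene_batches = _classify.variance_batches(X, c["batch_size"])
    name = f"{c['subset_tissue']} {c['subset_compartment']} cells"
    report = _classify.train_eval(X, y, spec, subset_name=name)
    importance = _classify.feature_importance(report)

    mdir = os.path.join(outdir, "model")
    os.makedirs(mdir, exist_ok=True)
    _jwrite(
        {
            "subset": name,
            "n_cells": int(subset.sum()),
            "n_positive": int(y.sum()),
            "overall_auc": round(report.overall_auc, 6),
            "overall_auprc": round(report.overall_auprc, 6),
            "mean_fold_auc": round(report.mean_fold_auc, 6),
            "fold_aucs": [round(a, 6) for a in report.fold_aucs],
            "batches": report.batch_results,
        },
        os.path.join(mdir, "report.json"),
    )
    _twrite(importance, os.path.join(mdir, "importance.tsv"), index=False)
    _twrite(pd.DataFrame({"fpr": report.roc[0], "tpr": report.roc[1]}), os.path.join(mdir, "roc.tsv"), index=False)
    _twrite(
        pd.DataFrame({"precision": report.pr[0], "recall": report.pr[1]}),
        os.path.join(mdir, "pr.tsv"), index=False,
    )
    return report


def stage_report(cfg: dict, outdir: str) -> dict:
    """Aggregate stage outputs into one JSON run summary."""
    summary = {"seed": cfg["seed"]}
    for rel, key in [
        (("qc", "report.json"), "qc"),
        (("rep", "expansion.json"), "expansion"),
        (("model", "report.json"), "classifier"),
    ]:
        path = os.path.join(outdir, *rel)
        if os.path.exists(path):
            with open(path) as fh:
                summary[key] = json.load(fh)
    for rel, key in [
        (("gate", "labels.tsv"), "compartment_counts"),
    ]:
        path = os.path.join(outdir, *rel)
        if os.path.exists(path):
            lab = pd.read_csv(path, sep="\t", index_col=0)
            summary[key] = lab["compartment"].value_counts().sort_index().to_dict()
    inf_path = os.path.join(outdir, "rep", "infiltration.tsv")
    if os.path.exists(inf_path):
        inf = pd.read_csv(inf_path, sep="\t", index_col=0)["infiltrating"]
        summary["infiltrating_cells"] = int(inf.sum())
    _jwrite(summary, os.path.join(outdir, "summary.json"))
    return summary


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "embed": stage_embed,
    "gate": stage_gate,
    "clonotype": stage_clonotype,
    "match": stage_match,
    "transitions": stage_transitions,
    "classify": stage_classify,
    "report": stage_report,
}

CHAIN = ["simulate", "qc", "embed", "gate", "clonotype", "match", "transitions", "classify", "report"]


def run_all(cfg: dict, outdir: str, stages=None) -> None:
    for name in stages or CHAIN:
        log.info("=== stage %s ===", name)
        STAGES[name](cfg, outdir)
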