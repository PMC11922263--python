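"""Run configuration: defaults, YAML loading, deep-merge of overrides."""

from __future__ import annotations

import copy

import yaml


def default_config() -> dict:
    """Default parameters for every pipeline stage.

    ``samples`` maps sample name -> {matrix, contigs, tissue, disease}; it is
    filled by the ``simulate`` stage or supplied by the user for real data.
    """
    return {
        "seed": 0,
        "outdir": "tcrtrace_out",
        "samples": {},
        "simulate": {
            "n_samples": 6,
            "cells_per_sample": 400,
            "shared_clone_count": 50,
            "marker_fold": 2.0,
        },
        "qc": {
            "min_cells_per_gene": 3,
            "min_features": 200,
            "max_features": 5000,
            "cd3_gene": "Cd3e",
            "housekeeping_genes": ["Actb", "B2m", "Gapdh"],
            "max_mito_fraction": 0.10,
            "mito_prefix": "mt-",
        },
        "embed": {
            "n_variable_genes": 400,
            "n_pcs": 10,
            "k_neighbors": 20,
            "resolution": 1.5,
            "marker_weight": 5.0,
            "marker_genes": [
                "Cd3e", "Cd4", "Cd8a", "Cd8b1", "Trgv2", "Sell", "Ccr7", "Il7r",
                "Ifng", "Tnf", "Klrg1", "Gzma", "Pdcd1", "Tigit", "Ctla4", "Lag3",
                "Havcr2", "Foxp3", "Il17a", "Il4", "Il10",
            ],
            "scale_clip": 10.0,
        },
        "gating": {
            "mode": "median_midpoint",
            "fixed_value": 0.5,
            "cd8_rule": "or",
            "exhaustion_min": 2,
        },
        "repertoire": {
            "strict_vj": False,
            "n_reps": 100,
            "min_clone_size_exclusive": 3,
            "vdjdb": None,  # optional path to a VDJdb-style TSV
        },
        "classifier": {
            "C": 1.0,
            "folds": 5,
            "batch_size": 500,
            "use_batches": False,
            "subset_tissue": "blood",
            "subset_compartment": "CD8",
        },
    }


def merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | None) -> dict:
    """YAML config merged over the defaults; ``path=None`` gives defaults."""
    cfg = default_config()
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = merge(cfg, user)
    return cfg
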