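"""Expression-threshold gating of T cells.

Cells are classified, flow-cytometry style, on normalized RNA expression of a
few co-receptor and cytokine genes: first into compartments
(gamma-delta / CD4 / CD8 / DP / DN), then CD4-like cells into T-helper
subsets, and every cell into SLEC-like and exhaustion phenotype flags.

The per-gene threshold is a "linear gate between the median populations": the
midpoint between the median of the zero-expression population and the median
of the positive-expression population. Because the zero population's median
is 0 by construction, this is half the positive median; when positives are
rare (<1% of cells) or absent, a fixed fallback of 0.5 is used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COMPARTMENT_LABELS = ("CD4", "CD8", "DN", "DP", "GD")
TH_SUBSETS = ("Treg", "Th17", "Th22", "Th1", "Tfh", "Th2", "Th9", "NA")
EXHAUSTION_MARKERS = ("Pdcd1", "Tigit", "Ctla4", "Havcr2", "Lag3")


@dataclass
class GateSpec:
    cd4_gene: str = "Cd4"
    cd8_genes: tuple = ("Cd8a", "Cd8b1")
    gd_gene: str = "Trgv2"
    mode: str = "median_midpoint"  # or "fixed"
    fixed_value: float = 0.5
    min_positive_fraction: float = 0.01
    cd8_rule: str = "or"  # positive on any CD8 gene; "and" for the strict read
    th_markers: dict = field(
        default_factory=lambda: dict(
            ifng="Ifng", tnf="Tnf", il4="Il4", il10="Il10", il17="Il17a", il22="Il22", foxp3="Foxp3"
        )
    )
    slec_markers: tuple = ("Klrg1", "Gzma", "Il7r")
    exhaustion_markers: tuple = EXHAUSTION_MARKERS
    exhaustion_min: int = 2

    def __post_init__(self):
        if self.mode not in ("median_midpoint", "fixed"):
            raise ValueError(f"unknown gate mode {self.mode!r}")
        if self.cd8_rule not in ("or", "and"):
            raise ValueError(f"cd8_rule must be 'or' or 'and', got {self.cd8_rule!r}")


def gate_threshold(values, mode: str = "median_midpoint", fixed_value: float = 0.5,
                   min_positive_fraction: float = 0.01) -> float:
    """Threshold for one gene from its per-cell normalized expression."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("gate_threshold needs at least one cell")
    if mode == "fixed":
        return float(fixed_value)
    pos = v[v > 0]
    if pos.size == 0 or pos.size < min_positive_fraction * v.size:
        return float(fixed_value)
    neg_median = float(np.median(v[v <= 0]) if (v <= 0).any() else 0.0)
    return (neg_median + float(np.median(pos))) / 2.0


def compute_thresholds(expr: pd.DataFrame, spec: GateSpec, genes=None) -> dict:
    """Thresholds for each marker column of ``expr`` (cells x genes)."""
    genes = list(genes) if genes is not None else list(expr.columns)
    return {
        g: gate_threshold(expr[g].to_numpy(), spec.mode, spec.fixed_value, spec.min_positive_fraction)
        for g in genes
    }


def _require(expr: pd.DataFrame, genes) -> None:
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise KeyError(f"marker genes missing from expression table: {missing}")


def classify_compartments(expr: pd.DataFrame, spec: GateSpec | None = None,
                          thresholds: dict | None = None) -> tuple[pd.Series, dict]:
    """Partition cells into GD / CD4 / CD8 / DP / DN.

    The gamma-delta gate (Trgv2) is checked first and is exclusive; the
    remaining cells are split on CD4 and CD8 positivity (CD8 positive on any
    of Cd8a/Cd8b1 under the default ``or`` rule). Every cell receives exactly
    one label.
    """
    spec = spec or GateSpec()
    genes = [spec.cd4_gene, *spec.cd8_genes, spec.gd_gene]
    _require(expr, genes)
    thresholds = thresholds or compute_thresholds(expr, spec, genes)

    gd = expr[spec.gd_gene].to_numpy() > thresholds[spec.gd_gene]
    cd4 = expr[spec.cd4_gene].to_numpy() > thresholds[spec.cd4_gene]
    cd8_calls = np.column_stack([expr[g].to_numpy() > thresholds[g] for g in spec.cd8_genes])
    cd8 = cd8_calls.any(axis=1) if spec.cd8_rule == "or" else cd8_calls.all(axis=1)

    labels = np.where(
        gd, "GD",
        np.where(cd4 & cd8, "DP", np.where(cd4, "CD4", np.where(cd8, "CD8", "DN"))),
    )
    out = pd.Series(labels, index=expr.index, name="compartment")
    log.info("gating: %s", out.value_counts().to_dict())
    return out, thresholds


def classify_th_subsets(expr: pd.DataFrame, compartments: pd.Series,
                        spec: GateSpec | None = None, thresholds: dict | None = None) -> pd.Series:
    """T-helper subset calls for non-CD8 cells.

    Rules (first satisfied wins, fixed precedence):
    Treg (Foxp3+ Il10+), Th17 (Il17+), Th22 (Il22+ Tnf+), Th1 (Ifng+ Tnf+),
    Tfh (Il4+ Il10+), Th2 (Il4+ Il10-), Th9 (Il10+ Ifng- Tnf-); otherwise NA.
    Raises on CD8-positive input cells (the gate presumes lack of CD8).
    """
    spec = spec or GateSpec()
    comp = compartments.reindex(expr.index)
    bad = comp.isin(("CD8", "DP"))
    if bad.any():
        raise ValueError(f"classify_th_subsets called on {int(bad.sum())} CD8-positive cells")
    m = spec.th_markers
    genes = list(m.values())
    _require(expr, genes)
    thresholds = thresholds or compute_thresholds(expr, spec, genes)
    pos = {k: expr[g].to_numpy() > thresholds[g] for k, g in m.items()}

    rules = [
        ("Treg", pos["foxp3"] & pos["il10"]),
        ("Th17", pos["il17"]),
        ("Th22", pos["il22"] & pos["tnf"]),
        ("Th1", pos["ifng"] & pos["tnf"]),
        ("Tfh", pos["il4"] & pos["il10"]),
        ("Th2", pos["il4"] & ~pos["il10"]),
        ("Th9", pos["il10"] & ~pos["ifng"] & ~pos["tnf"]),
    ]
    labels = np.full(len(expr), "NA", dtype=object)
    assigned = np.zeros(len(expr), bool)
    for name, mask in rules:
        take = mask & ~assigned
        labels[take] = name
        assigned |= mask
    return pd.Series(labels, index=expr.index, name="th_subset")


def classify_phenotypes(expr: pd.DataFrame, spec: GateSpec | None = None,
                        thresholds: dict | None = None) -> pd.DataFrame:
    """SLEC-like (Klrg1+ Gzma+ Il7r-) and exhaustion (>= ``exhaustion_min``
    inhibitory receptors above threshold) flags per cell."""
    spec = spec or GateSpec()
    klrg1, gzma, il7r = spec.slec_markers
    genes = [*spec.slec_markers, *spec.exhaustion_markers]
    _require(expr, genes)
    thresholds = thresholds or compute_thresholds(expr, spec, genes)
    above = {g: expr[g].to_numpy() > thresholds[g] for g in genes}
    slec = above[klrg1] & above[gzma] & ~above[il7r]
    n_exh = np.sum([above[g] for g in spec.exhaustion_markers], axis=0)
    return pd.DataFrame(
        {"SLEC_like": slec, "exhausted": n_exh >= spec.exhaustion_min, "n_exhaustion_markers": n_exh},
        index=expr.index,
    )


def state_labels(compartments: pd.Series, phenotypes: pd.DataFrame) -> pd.Series:
    """Coarse per-cell state for clone-fate and transition analysis:
    ``SLEC`` (CD8 SLEC-like), ``Texh`` (exhausted), else the compartment."""
    lab = compartments.astype(object).copy()
    lab[phenotypes["exhausted"].to_numpy()] = "Texh"
    lab[(compartments == "CD8").to_numpy() & phenotypes["SLEC_like"].to_numpy()] = "SLEC"
    return lab.rename("state")
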