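"""Gating rules: thresholds, compartment partition, Th subsets, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tcrtrace import gating, qc, simulate as sim

MARKERS = ["Cd4", "Cd8a", "Cd8b1", "Trgv2"]


def frame(rows, cols=MARKERS):
    return pd.DataFrame(rows, columns=cols, index=[f"c{i}" for i in range(len(rows))])


def test_threshold_all_zero_falls_back_to_fixed():
    assert gating.gate_threshold(np.zeros(100)) == 0.5


def test_threshold_median_midpoint_formula():
    v = np.array([0.0] * 50 + [0.8, 1.0, 1.2] * 20)
    # zero-population median 0, positive median 1.0 -> (0 + 1)/2
    assert gating.gate_threshold(v) == pytest.approx(0.5)
    v2 = np.array([0.0] * 10 + [2.0] * 10)
    assert gating.gate_threshold(v2) == pytest.approx(1.0)


def test_threshold_fixed_mode_and_rare_positive_fallback():
    v = np.array([3.0] * 100)
    assert gating.gate_threshold(v, mode="fixed") == 0.5
    rare = np.array([0.0] * 995 + [4.0] * 5)  # positives < 1% of cells
    assert gating.gate_threshold(rare) == 0.5


@pytest.mark.parametrize(
    "row,expected",
    [
        ([1.2, 0.0, 0.0, 0.0], "CD4"),
        ([0.0, 1.2, 0.0, 0.0], "CD8"),
        ([0.0, 0.0, 1.2, 0.0], "CD8"),  # either CD8 chain suffices
        ([1.2, 1.2, 0.0, 0.0], "DP"),
        ([0.0, 0.0, 0.0, 0.0], "DN"),
        ([1.2, 1.2, 1.2, 1.2], "GD"),  # gamma-delta gate wins, exclusive
    ],
)
def test_compartment_rules(row, expected):
    expr = frame([row])
    labels, _ = gating.classify_compartments(
        expr, gating.GateSpec(mode="fixed"), thresholds={g: 0.5 for g in MARKERS}
    )
    assert labels.iloc[0] == expected


def test_cd8_and_rule_is_stricter():
    expr = frame([[0.0, 1.2, 0.0, 0.0]])
    labels, _ = gating.classify_compartments(
        expr, gating.GateSpec(mode="fixed", cd8_rule="and"), thresholds={g: 0.5 for g in MARKERS}
    )
    assert labels.iloc[0] == "DN"


def test_missing_marker_gene_raises():
    with pytest.raises(KeyError, match="Trgv2"):
        gating.classify_compartments(frame([[1.0, 0.0, 0.0]], cols=MARKERS[:3]))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_partition_property_and_order_invariance(seed):
    rng = np.random.default_rng(seed)
    expr = frame(rng.exponential(0.8, size=(40, 4)) * rng.integers(0, 2, size=(40, 4)))
    labels, _ = gating.classify_compartments(expr)
    assert labels.isin(gating.COMPARTMENT_LABELS).all()
    assert labels.value_counts().sum() == len(expr)  # exactly one label per cell
    perm = rng.permutation(len(expr))
    shuffled, _ = gating.classify_compartments(expr.iloc[perm])
    assert (shuffled.to_numpy() == labels.iloc[perm].to_numpy()).all()


TH = ["Ifng", "Tnf", "Il4", "Il10", "Il17a", "Il22", "Foxp3"]


def th_frame(**pos):
    row = {g: (1.0 if pos.get(g, False) else 0.0) for g in TH}
    return pd.DataFrame([row], index=["c0"])


@pytest.mark.parametrize(
    "pos,expected",
    [
        (dict(Ifng=True, Tnf=True), "Th1"),
        (dict(Il4=True), "Th2"),                      # IL-4 without IL-10
        (dict(Il17a=True), "Th17"),
        (dict(Il22=True, Tnf=True), "Th22"),
        (dict(Il4=True, Il10=True), "Tfh"),
        (dict(Il10=True), "Th9"),                     # IL-10 without Ifng/Tnf
        (dict(Foxp3=True, Il10=True), "Treg"),
        (dict(), "NA"),
    ],
)
def test_th_subset_rules(pos, expected):
    expr = th_frame(**pos)
    comp = pd.Series(["CD4"], index=expr.index)
    out = gating.classify_th_subsets(expr, comp, gating.GateSpec(mode="fixed"),
                                     thresholds={g: 0.5 for g in TH})
    assert out.iloc[0] == expected


def test_th_precedence_treg_beats_tfh_and_th9():
    expr = th_frame(Foxp3=True, Il10=True, Il4=True)
    comp = pd.Series(["CD4"], index=expr.index)
    out = gating.classify_th_subsets(expr, comp, gating.GateSpec(mode="fixed"),
                                     thresholds={g: 0.5 for g in TH})
    assert out.iloc[0] == "Treg"


def test_th_on_cd8_cell_is_precondition_error():
    expr = th_frame(Ifng=True, Tnf=True)
    with pytest.raises(ValueError, match="CD8"):
        gating.classify_th_subsets(expr, pd.Series(["CD8"], index=expr.index),
                                   gating.GateSpec(mode="fixed"), thresholds={g: 0.5 for g in TH})


PHENO = ["Klrg1", "Gzma", "Il7r", "Pdcd1", "Tigit", "Ctla4", "Havcr2", "Lag3"]


@pytest.mark.parametrize(
    "pos,slec,exhausted",
    [
        (["Klrg1", "Gzma"], True, False),
        (["Klrg1", "Gzma", "Il7r"], False, False),  # IL7R+ blocks the SLEC call
        (["Klrg1"], False, False),
        (["Pdcd1", "Tigit"], False, True),          # 2 of 5 inhibitory receptors
        (["Pdcd1"], False, False),
        (["Ctla4", "Havcr2", "Lag3"], False, True),
    ],
)
def test_phenotype_flags(pos, slec, exhausted):
    row = {g: (1.0 if g in pos else 0.0) for g in PHENO}
    expr = pd.DataFrame([row], index=["c0"])
    out = gating.classify_phenotypes(expr, gating.GateSpec(mode="fixed"),
                                     thresholds={g: 0.5 for g in PHENO})
    assert bool(out["SLEC_like"].iloc[0]) is slec
    assert bool(out["exhausted"].iloc[0]) is exhausted


def _gated_dn_error(fold: float, seed: int = 17) -> tuple[float, float]:
    cfg = sim.SimulationConfig(n_samples=4, cells_per_sample=300, marker_fold=fold,
                               shared_clone_count=20, seed=seed)
    adata, meta, _, _ = sim.generate_cohort(cfg)
    ln = qc.normalize_cp10k_log(adata.X)
    idx = [list(adata.var_names).index(g) for g in MARKERS]
    expr = pd.DataFrame(np.asarray(ln[:, idx].todense()), index=adata.obs_names, columns=MARKERS)
    labels, _ = gating.classify_compartments(expr)
    err = abs((labels == "DN").mean() - (meta["compartment"] == "DN").mean())
    mis = (labels.to_numpy() != meta["compartment"].to_numpy()).mean()
    return err, mis


def test_recovery_improves_with_marker_effect_size():
    errs, mis = zip(*(_gated_dn_error(f) for f in (1.5, 2.0, 4.0)))
    assert mis[0] >= mis[1] >= mis[2]  # misclassification monotone in effect
    assert errs[1] < 0.05 and errs[2] < 0.03  # aggregate DN fraction converges
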