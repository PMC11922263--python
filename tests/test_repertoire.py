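"""Clonotypes, matching, fates, transitions, epitopes: rules and oracles."""

import numpy as np
import pandas as pd
import pytest

from tcrtrace import repertoire as rep


def chain_table(rows):
    return pd.DataFrame(rows, columns=["barcode", "locus", "cdr3_aa"])


def test_identical_pairs_merge_into_one_clonotype():
    ct, cm = rep.assign_clonotypes(chain_table([
        ("x", "TRA", "CAVSAF"), ("x", "TRB", "CASSLG"),
        ("y", "TRA", "CAVSAF"), ("y", "TRB", "CASSLG"),
    ]))
    assert len(ct) == 1 and ct.iloc[0]["size"] == 2
    assert set(cm["barcode"]) == {"x", "y"}


def test_single_chain_cells_excluded():
    ct, cm = rep.assign_clonotypes(chain_table([
        ("x", "TRB", "CASSLG"),
        ("y", "TRA", "CAVSAF"), ("y", "TRB", "CASSLG"),
    ]))
    assert list(cm["barcode"]) == ["y"]
    assert len(ct) == 1


def test_different_beta_means_different_clonotype():
    ct, _ = rep.assign_clonotypes(chain_table([
        ("x", "TRA", "CAVSAF"), ("x", "TRB", "CASSLG"),
        ("y", "TRA", "CAVSAF"), ("y", "TRB", "CASSIRF"),
    ]))
    assert len(ct) == 2


def test_multichain_cells_match_only_on_full_set_equality():
    ct, cm = rep.assign_clonotypes(chain_table([
        ("x", "TRA", "CAAF"), ("x", "TRA", "CBBF"), ("x", "TRB", "CCCF"),
        ("y", "TRA", "CBBF"), ("y", "TRA", "CAAF"), ("y", "TRB", "CCCF"),  # same set, other order
        ("z", "TRA", "CAAF"), ("z", "TRB", "CCCF"),                        # subset only
    ]))
    assert len(ct) == 2
    m = dict(zip(cm["barcode"], cm["clonotype_id"]))
    assert m["x"] == m["y"] != m["z"]


def test_gamma_delta_chains_do_not_enter_keys():
    ct, cm = rep.assign_clonotypes(chain_table([
        ("x", "TRA", "CAAF"), ("x", "TRB", "CCCF"), ("x", "TRG", "CGGF"),
        ("y", "TRA", "CAAF"), ("y", "TRB", "CCCF"), ("y", "TRD", "CDDF"),
        ("g", "TRG", "CGGF"), ("g", "TRD", "CDDF"),  # gamma-delta only: excluded
    ]))
    assert len(ct) == 1 and ct.iloc[0]["size"] == 2
    assert "g" not in set(cm["barcode"])


def test_assignment_invariant_to_row_order(small_cohort):
    _, _, _, chains, _ = small_cohort
    ct1, cm1 = rep.assign_clonotypes(chains)
    shuffled = chains.sample(frac=1.0, random_state=9)
    ct2, cm2 = rep.assign_clonotypes(shuffled)
    pd.testing.assert_frame_equal(ct1, ct2)
    pd.testing.assert_frame_equal(
        cm1.sort_values("barcode").reset_index(drop=True),
        cm2.sort_values("barcode").reset_index(drop=True),
    )


def test_clone_sizes_conserve_paired_cells(small_cohort):
    _, _, _, chains, _ = small_cohort
    ct, cm = rep.assign_clonotypes(chains)
    per_cell = chains[chains["chain"].isin(("TRA", "TRB"))].groupby("barcode")["chain"].agg(set)
    n_paired = (per_cell.apply(lambda s: {"TRA", "TRB"} <= s)).sum()
    assert ct["size"].sum() == len(cm) == n_paired


def test_expansion_summary_counts():
    ct = pd.DataFrame({"clonotype_id": ["a", "b", "c", "d"], "alpha": "CAF", "beta": "CBF",
                       "size": [1, 1, 3, 12]})
    s = rep.expansion_summary(ct)
    assert (s["singletons"], s["size_ge3"], s["size_gt10"], s["max_size"]) == (2, 2, 1, 12)
    empty = rep.expansion_summary(ct.iloc[:0])
    assert empty["n_clonotypes"] == 0 and empty["max_size"] == 0


def test_expansion_summary_matches_brute_force(small_cohort):
    _, _, meta, chains, _ = small_cohort
    ct, cm = rep.assign_clonotypes(chains)
    s = rep.expansion_summary(ct, cm, meta)
    sizes = cm.groupby("clonotype_id").size()
    assert s["singletons"] == int((sizes == 1).sum())
    assert s["size_ge3"] == int((sizes >= 3).sum())
    assert s["size_gt10"] == int((sizes > 10).sum())
    df = cm.merge(meta, left_on="barcode", right_index=True)
    expanded = sizes[sizes > 3].index
    grp = df[df["clonotype_id"].isin(expanded)].groupby("clonotype_id")
    assert s["multi_sample_clones"] == int((grp["sample"].nunique() >= 2).sum())
    assert s["cross_disease_clones"] == int((grp["disease"].nunique() >= 2).sum())


def two_tissue_chains():
    return chain_table([
        ("b1", "TRA", "CAVSAF"), ("b1", "TRB", "CASSLG"),
        ("i1", "TRA", "CAVSAF"), ("i1", "TRB", "CASSOTHERF"),  # shares alpha only
        ("b2", "TRA", "CXXXF"), ("b2", "TRB", "CYYYF"),
        ("i2", "TRA", "CZZZF"), ("i2", "TRB", "CWWWF"),
    ])


def test_shared_alpha_across_tissues_flags_both_cells():
    ct, cm = rep.assign_clonotypes(two_tissue_chains())
    tissues = pd.Series({"b1": "blood", "b2": "blood", "i1": "islet", "i2": "islet"})
    flags, matched = rep.match_tissues(ct, cm, tissues)
    assert bool(flags["b1"]) and bool(flags["i1"])
    assert not flags[["b2", "i2"]].any()
    assert list(matched["cdr3_aa"]) == ["CAVSAF"] and list(matched["locus"]) == ["TRA"]
    assert matched.iloc[0]["n_blood"] == 1 and matched.iloc[0]["n_islet"] == 1


def test_single_tissue_input_yields_no_matches():
    ct, cm = rep.assign_clonotypes(two_tissue_chains())
    tissues = pd.Series({k: "blood" for k in ["b1", "b2", "i1", "i2"]})
    flags, matched = rep.match_tissues(ct, cm, tissues)
    assert not flags.any() and matched.empty


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matching_equals_bruteforce_oracle(seed):
    from tcrtrace import simulate as sim
    cfg = sim.SimulationConfig(n_samples=4, cells_per_sample=150, shared_clone_count=15, seed=seed)
    _, meta, chains, truth = sim.generate_cohort(cfg)
    ct, cm = rep.assign_clonotypes(chains)
    flags, _ = rep.match_tissues(ct, cm, meta["tissue"])
    brute = rep.match_tissues_bruteforce(ct, cm, meta["tissue"])
    assert (flags.to_numpy() == brute.to_numpy()).all()
    # planted spanning clones, and only those, are recovered
    assert (flags.to_numpy() == meta.loc[flags.index, "infiltrating"].to_numpy()).all()


def fate_inputs(states_by_cell):
    cells = list(states_by_cell)
    ct = pd.DataFrame({"clonotype_id": ["c1"], "alpha": "CAF", "beta": "CBF", "size": [len(cells)]})
    cm = pd.DataFrame({"barcode": cells, "clonotype_id": "c1"})
    return ct, cm, pd.Series(states_by_cell)


@pytest.mark.parametrize(
    "states,expected",
    [
        ({"a": "effector", "b": "SLEC", "c": "SLEC"}, "SLEC_only"),
        ({"a": "SLEC", "b": "Texh"}, "mixed"),
        ({"a": "naive", "b": "effector"}, "other"),
        ({"a": "Texh"}, "Texh_only"),
    ],
)
def test_clone_fate_rules(states, expected):
    ct, cm, st = fate_inputs(states)
    assert rep.classify_clone_fate(ct, cm, st).iloc[0] == expected


def test_clone_fate_unlabeled_member_errors():
    ct, cm, st = fate_inputs({"a": "SLEC", "b": "SLEC"})
    with pytest.raises(ValueError, match="unlabeled"):
        rep.classify_clone_fate(ct, cm, st.drop("b"))


def trans_inputs(states):
    cells = [f"c{i}" for i in range(len(states))]
    cm = pd.DataFrame({"barcode": cells, "clonotype_id": "k1"})
    return cm, pd.Series(states, index=cells)


def test_exact_transitions_by_enumeration():
    cm, st = trans_inputs(["A", "A", "B"])
    g = rep.exact_transitions(cm, st, min_clone_size_exclusive=2, nodes=["A", "B"])
    e = g.edges.set_index(["state_a", "state_b"])["likelihood"]
    assert e[("A", "B")] == pytest.approx(2 / 3)
    assert e[("A", "A")] == pytest.approx(1 / 3)
    assert g.edges["likelihood"].sum() == pytest.approx(1.0)  # per-clone pairs sum to 1


def test_homogeneous_clone_self_likelihood_one():
    cm, st = trans_inputs(["A"] * 5)
    g = rep.exact_transitions(cm, st, nodes=["A"])
    assert g.edges.iloc[0]["likelihood"] == 1.0 and len(g.edges) == 1
    b = rep.bootstrap_transitions(cm, st, n_reps=50, seed=0, nodes=["A"])
    assert b.edges.iloc[0]["likelihood"] == 1.0


def test_small_clones_are_ineligible_and_warn():
    cm, st = trans_inputs(["A", "B"])  # size 2 <= threshold 3
    with pytest.warns(UserWarning, match="no clone"):
        g = rep.bootstrap_transitions(cm, st, seed=0)
    assert g.n_clones == 0 and g.edges.empty


def test_bootstrap_unbiased_and_converges_to_exact():
    cm, st = trans_inputs(["A", "A", "B", "B"])
    exact = rep.exact_transitions(cm, st, nodes=["A", "B"]).edges
    p = exact.set_index(["state_a", "state_b"])["likelihood"][("A", "B")]
    assert p == pytest.approx(4 / 6)
    ests = [
        rep.bootstrap_transitions(cm, st, n_reps=100, seed=s, nodes=["A", "B"])
        .edges.set_index(["state_a", "state_b"])["likelihood"]
        .get(("A", "B"), 0.0)
        for s in range(200)
    ]
    assert abs(np.mean(ests) - p) < 1e-2  # unbiased
    big = rep.bootstrap_transitions(cm, st, n_reps=10_000, seed=1, nodes=["A", "B"])
    big_p = big.edges.set_index(["state_a", "state_b"])["likelihood"][("A", "B")]
    assert abs(big_p - p) < 0.02  # converges as reps grow


def test_transition_edges_colored_by_compartment():
    cells = [f"c{i}" for i in range(5)]
    cm = pd.DataFrame({"barcode": cells, "clonotype_id": "k1"})
    st = pd.Series(["CD4", "CD4", "DN", "DN", "CD4"], index=cells)
    g = rep.exact_transitions(cm, st, nodes=["CD4", "DN"],
                              compartment_of={"CD4": "CD4", "DN": "DN"})
    e = g.edges.set_index(["state_a", "state_b"])
    assert bool(e.loc[("CD4", "CD4"), "same_compartment"])
    assert not bool(e.loc[("CD4", "DN"), "same_compartment"])


def vdjdb_ref():
    return pd.DataFrame({
        "cdr3_aa": ["CASSIRSSYEQYF", "CASSIRSSYEQYF", "caafnnriff"],
        "locus": ["TRB", "TRB", "TRA"],
        "epitope": ["FLU-PA", "MCMV-M45", "INS-B15"],
        "species": "MusMusculus",
    })


def test_epitope_exact_match_honours_chain_and_case():
    ct = pd.DataFrame({
        "clonotype_id": ["c1", "c2", "c3"],
        "alpha": ["CAAFNNRIFF", "CASSIRSSYEQYF", "CAAFNNRIFX"],  # c2: beta-only seq on alpha
        "beta": ["CASSIRSSYEQYF", "CQQQF", "CZZZF"],
        "size": [2, 1, 1],
    })
    ann = rep.annotate_epitopes(ct, vdjdb_ref())
    got = ann.groupby("clonotype_id")["epitope"].agg(set).to_dict()
    assert got["c1"] == {"FLU-PA", "MCMV-M45", "INS-B15"}  # lowercase ref matched
    assert "c2" not in got  # TRB reference does not match an alpha chain
    assert "c3" not in got  # off-by-one residue is no match
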