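"""Embedding and clustering: SVD oracles, graph geometry, modularity oracle."""

import igraph
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from tcrtrace import embed, qc, simulate as sim


def test_variable_gene_selection_by_variance_and_tiebreak():
    # variances 4, 3, 2, 1, 0 by construction
    cols = [np.array([0, 4.0]), np.array([0, np.sqrt(12)]), np.array([0, 2.0]),
            np.array([0, np.sqrt(2)]), np.array([1.0, 1.0])]
    X = np.column_stack(cols)
    genes = ["a", "b", "c", "d", "e"]
    assert embed.select_variable_genes(X, genes, 2) == ["a", "b"]
    # constant gene never selected while any varying gene remains
    assert "e" not in embed.select_variable_genes(X, genes, 4)
    # exact tie at the boundary: earlier gene order wins
    Xt = np.column_stack([cols[0], cols[0], cols[4]])
    assert embed.select_variable_genes(Xt, ["g1", "g2", "g3"], 1) == ["g1"]
    with pytest.raises(ValueError):
        embed.select_variable_genes(X, genes, 6)


@pytest.fixture(scope="module")
def scaled_matrix():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((60, 12))
    return qc.scale_genes(X)


def test_unit_weights_reduce_to_plain_pca(scaled_matrix):
    genes = [f"g{i}" for i in range(scaled_matrix.shape[1])]
    emb = embed.weighted_pca(scaled_matrix, genes, weights=None, n_pcs=5)
    U, S, Vt = np.linalg.svd(scaled_matrix, full_matrices=False)
    assert np.allclose(emb.singular_values, S[:5], atol=1e-8)
    for k in range(5):
        ref = U[:, k] * S[k]
        agree = min(np.abs(emb.scores[:, k] - ref).max(), np.abs(emb.scores[:, k] + ref).max())
        assert agree < 1e-8


def test_zero_weight_equals_feature_exclusion(scaled_matrix):
    genes = [f"g{i}" for i in range(scaled_matrix.shape[1])]
    with_zero = embed.weighted_pca(scaled_matrix, genes, weights={"g0": 0.0}, n_pcs=4)
    without = embed.weighted_pca(scaled_matrix[:, 1:], genes[1:], n_pcs=4)
    assert np.allclose(with_zero.singular_values, without.singular_values, atol=1e-8)
    for k in range(4):
        d = min(np.abs(with_zero.scores[:, k] - without.scores[:, k]).max(),
                np.abs(with_zero.scores[:, k] + without.scores[:, k]).max())
        assert d < 1e-8


def test_weighting_equals_row_scaling_oracle():
    rng = np.random.default_rng(7)
    X = qc.scale_genes(rng.standard_normal((6, 3)))
    emb = embed.weighted_pca(X, ["f1", "f2", "f3"], weights={"f1": 2.0}, n_pcs=3)
    doubled = X * np.array([2.0, 1.0, 1.0])
    _, S, _ = np.linalg.svd(doubled, full_matrices=False)
    assert np.allclose(emb.singular_values, S[:3], atol=1e-10)


def test_scores_invariant_to_cell_order(scaled_matrix):
    genes = [f"g{i}" for i in range(scaled_matrix.shape[1])]
    emb = embed.weighted_pca(scaled_matrix, genes, n_pcs=3)
    perm = np.random.default_rng(0).permutation(scaled_matrix.shape[0])
    emb_p = embed.weighted_pca(scaled_matrix[perm], genes, n_pcs=3)
    assert np.allclose(emb_p.scores, emb.scores[perm], atol=1e-8)


def test_weighted_pca_rejects_empty_features():
    with pytest.raises(ValueError, match="empty"):
        embed.weighted_pca(np.zeros((3, 0)), [], n_pcs=1)


def test_knn_collinear_duplicates_and_saturation():
    pts = np.array([[0.0], [1.0], [2.0]])
    g = embed.knn_graph(pts, k=1)
    assert g.degree()[1] == 2  # middle point linked both ways after union
    dup = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
    gd = embed.knn_graph(dup, k=1)
    assert gd.are_adjacent(0, 1)  # coincident points are mutual neighbours
    full = embed.knn_graph(np.random.default_rng(1).normal(size=(6, 2)), k=5)
    assert full.ecount() == 15  # k = n-1 -> complete graph
    with pytest.raises(ValueError):
        embed.knn_graph(pts, k=3)


def two_cliques():
    edges = (
        [(i, j) for i in range(4) for j in range(i + 1, 4)]
        + [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        + [(0, 4)]
    )
    return igraph.Graph(n=8, edges=edges)


def test_two_cliques_match_enumerated_modularity_optimum():
    g = two_cliques()
    labels = embed.cluster_graph(g, resolution=1.0, seed=0)
    found = {frozenset(np.flatnonzero(labels == k).tolist()) for k in np.unique(labels)}
    brute = {frozenset(b) for b in embed.modularity_brute_force(g, resolution=1.0)}
    assert found == brute == {frozenset(range(4)), frozenset(range(4, 8))}


def test_single_clique_is_one_cluster_and_labels_size_ordered():
    clique = igraph.Graph.Full(6)
    assert set(embed.cluster_graph(clique, resolution=1.0, seed=0)) == {0}
    # larger community must take label 0
    g = igraph.Graph.Full(8) + igraph.Graph.Full(4)
    labels = embed.cluster_graph(g, resolution=1.0, seed=1)
    assert (labels[:8] == 0).all() and (labels[8:] == 1).all()


def test_clustering_deterministic_given_seed():
    g = two_cliques()
    a = embed.cluster_graph(g, resolution=1.0, seed=42)
    b = embed.cluster_graph(g, resolution=1.0, seed=42)
    assert (a == b).all()
    with pytest.raises(ValueError):
        embed.cluster_graph(igraph.Graph(n=0), seed=0)


def test_compartment_recovery_ari_on_separated_cohort():
    comp = {"CD4": 0.3, "CD8": 0.3, "DN": 0.3, "DP": 0.0, "GD": 0.1}
    states = {c: {"naive": 1.0} for c in comp}
    cfg = sim.SimulationConfig(
        n_samples=2, cells_per_sample=400, compartment_fractions=comp,
        state_fractions_per_compartment=states, marker_fold=4.0,
        shared_clone_count=10, seed=3,
    )
    adata, meta, _, _ = sim.generate_cohort(cfg)
    ln = qc.normalize_cp10k_log(adata.X)
    markers = ["Cd4", "Cd8a", "Cd8b1", "Trgv2"]
    hvg = embed.select_variable_genes(ln, adata.var_names, 400)
    feats = markers + [g for g in hvg if g not in markers]
    idx = [list(adata.var_names).index(g) for g in feats]
    emb = embed.weighted_pca(qc.scale_genes(ln[:, idx]), feats, {g: 5.0 for g in markers}, n_pcs=10)
    labels = embed.cluster_graph(embed.knn_graph(emb.scores, k=20), resolution=0.3, seed=0)
    assert adjusted_rand_score(meta["compartment"], labels) >= 0.8


def test_pseudobulk_equals_group_by_oracle():
    rng = np.random.default_rng(5)
    X = rng.poisson(2.0, size=(30, 4)).astype(float)
    labels = rng.integers(0, 3, size=30)
    pb = embed.pseudobulk(X, ["a", "b", "c", "d"], labels)
    for k in range(3):
        assert np.allclose(pb.loc[k].to_numpy(), X[labels == k].mean(axis=0))
    # cluster of identical cells reproduces the profile; 0 and 2 average to 1
    two = embed.pseudobulk(np.array([[0.0], [2.0]]), ["g"], [0, 0])
    assert two.loc[0, "g"] == 1.0
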