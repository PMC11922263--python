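"""Marker-weighted PCA and modularity clustering.

T cells are transcriptionally similar, so plain PCA of variable genes mixes
compartments. Up-weighting immune markers (5x here) before the SVD makes the
top components follow compartment structure; clusters then recover it.
"""

from sklearn.metrics import adjusted_rand_score

from tcrtrace import SimulationConfig, embed, generate_cohort, qc

comp = {"CD4": 0.3, "CD8": 0.3, "DN": 0.3, "DP": 0.0, "GD": 0.1}
states = {c: {"naive": 1.0} for c in comp}
cfg = SimulationConfig(n_samples=2, cells_per_sample=400, compartment_fractions=comp,
                       state_fractions_per_compartment=states, marker_fold=4.0,
                       shared_clone_count=10, seed=3)
adata, meta, _, _ = generate_cohort(cfg)

ln = qc.normalize_cp10k_log(adata.X)
markers = ["Cd4", "Cd8a", "Cd8b1", "Trgv2"]
hvg = embed.select_variable_genes(ln, adata.var_names, 400)
feats = markers + [g for g in hvg if g not in markers]
idx = [list(adata.var_names).index(g) for g in feats]
scaled = qc.scale_genes(ln[:, idx])

for weight in (1.0, 5.0):
    emb = embed.weighted_pca(scaled, feats, {g: weight for g in markers}, n_pcs=10)
    graph = embed.knn_graph(emb.scores, k=20)
    labels = embed.cluster_graph(graph, resolution=0.3, seed=0)
    ari = adjusted_rand_score(meta["compartment"], labels)
    print(f"marker weight {weight}: {labels.max() + 1} clusters, "
          f"ARI vs planted compartments = {ari:.3f}")
print("Higher marker weight pulls the compartments apart in PC space; "
      "ARI of 1.0 would be perfect recovery.")
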