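"""Predicting infiltration status from expression with lasso logistic CV.

Features with a planted sparse log-odds signal stand in for the infiltration
program; stratified five-fold CV reports pooled held-out ROC AUC / AUPRC and
a coefficient-based importance ranking that should surface the planted genes.
"""

from tcrtrace import classify as cl, planted_logistic

X, y, informative = planted_logistic(n_cells=1500, n_genes=500, n_informative=20,
                                     effect=1.0, seed=0)
report = cl.train_eval(X, y, cl.ClassifierSpec(C=1.0, folds=5, seed=0))
print(f"overall AUC (pooled held-out): {report.overall_auc:.3f}")
print(f"overall AUPRC:                 {report.overall_auprc:.3f}")
print(f"mean per-fold AUC:             {report.mean_fold_auc:.3f}")

imp = cl.feature_importance(report)
top20 = set(imp.head(20)["gene"])
print(f"\nplanted informative genes recovered in top-20 importance: "
      f"{len(top20 & set(informative))}/20")
print(imp.head(5).to_string(index=False))
print("\nImportance is the mean |coefficient| across folds, scaled so the "
      "top gene is 1; L1 shrinkage zeroes most uninformative genes.")
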