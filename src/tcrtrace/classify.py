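"""Sparse logistic classification of infiltration status from expression.

An L1-penalized (lasso) logistic regression with a liblinear-class solver is
trained under stratified five-fold cross-validation to separate infiltrating
(tissue-matching) from non-matching cells; discrimination is reported as ROC
AUC and average precision, both per fold and pooled over held-out
predictions, and feature importance as the mean absolute coefficient across
folds normalized so the top gene equals 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)


@dataclass
class ClassifierSpec:
    C: float = 1.0  # inverse of the L1 regularization strength
    folds: int = 5
    seed: int = 0
    gene_batches: list | None = None  # optional disjoint gene lists
    batch_size: int = 500  # used when batches are derived from variance

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gene_batches:
            seen: set = set()
            for b in self.gene_batches:
                if seen & set(b):
                    raise ValueError("gene batches must be disjoint")
                seen |= set(b)


@dataclass
class ClassifierReport:
    genes: list
    fold_indices: list  # (train_idx, test_idx) per fold
    fold_aucs: list
    fold_auprcs: list
    overall_auc: float
    overall_auprc: float
    mean_fold_auc: float
    roc: tuple  # (fpr, tpr) pooled over held-out predictions
    pr: tuple  # (precision, recall) pooled
    coefs: np.ndarray  # folds x genes, full-feature model
    pooled_scores: np.ndarray
    pooled_truth: np.ndarray
    batch_results: dict = field(default_factory=dict)  # batch name -> summary


def variance_batches(X: pd.DataFrame, batch_size: int = 500) -> list[list[str]]:
    """Contiguous chunks of genes ranked by decreasing variance."""
    order = X.var(axis=0, ddof=1).sort_values(ascending=False, kind="stable").index
    return [list(order[i:i + batch_size]) for i in range(0, len(order), batch_size)]


def _fit(X, y, C, seed):
    # l1_ratio=1.0 is the pure lasso penalty (sklearn >=1.8 spelling of penalty="l1")
    model = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", random_state=seed, max_iter=1000)
    model.fit(X, y)
    return model


def train_eval(X: pd.DataFrame, y, spec: ClassifierSpec | None = None,
               subset_name: str = "cell subset") -> ClassifierReport:
    """Stratified K-fold CV of the lasso-logistic infiltration model.

    ``X`` is cells x genes of log-normalized expression for the analysis
    subset; ``y`` the per-cell infiltration flags. A model is fit per fold on
    the full gene set (and on each gene batch when configured); curves and
    AUCs come only from held-out predictions.
    """
    spec = spec or ClassifierSpec()
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"only one class present in {subset_name}; cannot train")
    if np.bincount(y).min() < spec.folds:
        raise ValueError(f"fewer than {spec.folds} cells in the minority class of {subset_name}")
    genes = list(X.columns)
    Xv = X.to_numpy(dtype=np.float64)

    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(Xv, y))

    def run(feature_idx):
        coefs, scores, truths, aucs, auprcs = [], [], [], [], []
        for train, test in folds:
            model = _fit(Xv[np.ix_(train, feature_idx)], y[train], spec.C, spec.seed)
            s = model.decision_function(Xv[np.ix_(test, feature_idx)])
            coefs.append(model.coef_.ravel())
            scores.append(s)
            truths.append(y[test])
            if len(np.unique(y[test])) == 2:
                aucs.append(float(roc_auc_score(y[test], s)))
                auprcs.append(float(average_precision_score(y[test], s)))
        pooled_s = np.concatenate(scores)
        pooled_y = np.concatenate(truths)
        return np.array(coefs), pooled_s, pooled_y, aucs, auprcs

    all_idx = np.arange(len(genes))
    coefs, pooled_s, pooled_y, aucs, auprcs = run(all_idx)
    fpr, tpr, _ = roc_curve(pooled_y, pooled_s)
    prec, rec, _ = precision_recall_curve(pooled_y, pooled_s)

    batch_results = {}
    if spec.gene_batches:
        gene_pos = {g: i for i, g in enumerate(genes)}
        for bi, batch in enumerate(spec.gene_batches):
            idx = np.array([gene_pos[g] for g in batch if g in gene_pos])
            if idx.size == 0:
                continue
            _, bs, by, b_aucs, b_auprcs = run(idx)
            batch_results[f"batch_{bi}"] = {
                "n_genes": int(idx.size),
                "overall_auc": float(roc_auc_score(by, bs)),
                "overall_auprc": float(average_precision_score(by, bs)),
                "mean_fold_auc": float(np.mean(b_aucs)) if b_aucs else float("nan"),
            }

    report = ClassifierReport(
        genes=genes,
        fold_indices=folds,
        fold_aucs=aucs,
        fold_auprcs=auprcs,
        overall_auc=float(roc_auc_score(pooled_y, pooled_s)),
        overall_auprc=float(average_precision_score(pooled_y, pooled_s)),
        mean_fold_auc=float(np.mean(aucs)) if aucs else float("nan"),
        roc=(fpr, tpr),
        pr=(prec, rec),
        coefs=coefs,
        pooled_scores=pooled_s,
        pooled_truth=pooled_y,
        batch_results=batch_results,
    )
    log.info("classifier: AUC %.3f, AUPRC %.3f (pooled held-out)", report.overall_auc, report.overall_auprc)
    return report


def feature_importance(report: ClassifierReport, top: int | None = None) -> pd.DataFrame:
    """Genes ranked by mean |coefficient| across folds, top gene = 1.

    Returns an empty frame (with a warning) if every coefficient was shrunk
    to zero. Ties rank by gene input order.
    """
    mean_abs = np.abs(report.coefs).mean(axis=0)
    if not np.any(mean_abs > 0):
        warnings.warn("all coefficients are zero; no features to rank")
        return pd.DataFrame(columns=["gene", "importance"])
    order = np.argsort(-mean_abs, kind="stable")
    order = order[mean_abs[order] > 0]
    imp = mean_abs[order] / mean_abs[order[0]]
    df = pd.DataFrame({"gene": [report.genes[i] for i in order], "importance": imp})
    return df.head(top) if top else df


def nonzero_path(X: pd.DataFrame, y, Cs, seed: int = 0) -> list[int]:
    """Number of nonzero coefficients at each C (single fit on all data);
    used to check that sparsity is monotone in the regularization strength."""
    y = np.asarray(y).astype(int)
    out = []
    for C in Cs:
        model = _fit(X.to_numpy(), y, C, seed)
        out.append(int(np.sum(model.coef_ != 0)))
    return out
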