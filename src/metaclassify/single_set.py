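"""Single-cohort biomarker selection baseline.

The contrast case for the meta-analysis: select a small gene signature
from one cohort alone, with feature selection nested inside the outer
CV so the reported AUC is unbiased for *this* cohort.  Genes are ranked
by absolute log2 fold change on the outer training samples only, the
gene count n in {1..10} is chosen by an inner CV of the training
samples, and the resulting SVM predicts the outer test fold.  Signatures
obtained this way tend not to transfer across studies — the motivating
failure mode for the cross-cohort pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .classify import (DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, CVEvaluation,
                       _grid_search_fold, delong_ci, svm_cv_auc)
from .cohort_io import ExpressionCohort
from .ranking import rank_genes

__all__ = ["SingleSetResult", "single_set_select", "signature_genes"]

DEFAULT_SINGLE_GRID = tuple(range(1, 11))


@dataclass
class SingleSetResult:
    """Per-fold selections, cross-fold frequencies and pooled test AUC."""

    cohort_id: str
    selected_genes_per_fold: dict      # fold -> ordered gene list
    n_per_fold: dict                   # fold -> chosen n
    consensus_genes: pd.Series         # gene -> selection frequency in [0, 1]
    test_eval: CVEvaluation

    def to_dict(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "selected_genes_per_fold": {int(k): list(v) for k, v
                                        in self.selected_genes_per_fold.items()},
            "n_per_fold": {int(k): int(v) for k, v in self.n_per_fold.items()},
            "consensus_genes": {g: float(f) for g, f in self.consensus_genes.items()},
            "test_auc": float(self.test_eval.auc),
            "test_auc_ci": [float(v) for v in self.test_eval.auc_ci],
        }


def _train_subcohort(cohort: ExpressionCohort, idx: np.ndarray) -> ExpressionCohort:
    return ExpressionCohort(
        cohort_id=f"{cohort.cohort_id}.train",
        genes=cohort.genes,
        samples=cohort.samples[idx],
        values=cohort.values[:, idx],
        y=cohort.y[idx],
    )


def single_set_select(cohort: ExpressionCohort, folds: int = 10,
                      grid=DEFAULT_SINGLE_GRID, seed: int = 0) -> SingleSetResult:
    """Nested-CV gene selection and evaluation on a single cohort.

    Outer stratified `folds`-fold CV; per outer training split the genes
    are ranked by |log2FC| of the training samples, n is optimized in an
    inner CV of the training samples (identical SVM protocol, 3 folds),
    and the top-n SVM predicts the held-out fold.  Decision values of
    all outer folds pool into one ROC.
    """
    grid = sorted(int(n) for n in grid)
    if not grid or grid[0] < 1 or grid[-1] > cohort.n_genes:
        raise ValueError("invalid gene-count grid for this cohort")
    seed = int(seed) % (2**31 - 1)
    k = min(folds, int(cohort.y.sum()), int((~cohort.y).sum()))
    if k < 2:
        raise ValueError(f"{cohort.cohort_id}: need >= 2 samples per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X = cohort.values.T
    y = cohort.y
    decisions = np.empty(len(y))
    fold_of = np.empty(len(y), dtype=int)
    per_fold, n_fold = {}, {}
    for f, (tr, te) in enumerate(skf.split(X, y)):
        train = _train_subcohort(cohort, tr)
        pos = train.values[:, train.y].mean(axis=1)
        neg = train.values[:, ~train.y].mean(axis=1)
        scores = pd.Series(np.abs(pos - neg), index=train.genes)
        order = rank_genes(scores, "abs_log2fc").sort_values(kind="stable").index
        inner_auc = {}
        for n in grid:
            genes = list(order[:n])
            ev = svm_cv_auc(train, genes, folds=3,
                            seed=(seed + 7907 * (f + 1) + n) % (2**31 - 1))
            inner_auc[n] = ev.auc
        best = max(inner_auc.values())
        n_best = min(n for n, v in inner_auc.items() if v == best)
        genes = list(order[:n_best])
        per_fold[f] = genes
        n_fold[f] = n_best
        gi = cohort.gene_index(genes)
        mu = X[tr][:, gi].mean(axis=0)
        sd = X[tr][:, gi].std(axis=0)
        sd[sd == 0] = 1.0
        decisions[te] = _grid_search_fold(
            (X[tr][:, gi] - mu) / sd, y[tr], (X[te][:, gi] - mu) / sd,
            DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, 3,
            (seed + 104729 * (f + 1)) % (2**31 - 1))
        fold_of[te] = f
    freq = pd.Series(0.0, index=sorted({g for lst in per_fold.values() for g in lst}))
    for lst in per_fold.values():
        freq[lst] += 1.0
    freq = (freq / k).sort_index().sort_values(ascending=False, kind="stable")
    fpr, tpr, _ = roc_curve(y, decisions, drop_intermediate=False)
    auc, ci = delong_ci(y, decisions)
    test_eval = CVEvaluation(
        cohort_id=cohort.cohort_id,
        gene_set=list(freq.index),
        auc=float(auc),
        auc_ci=ci,
        roc_points=np.column_stack([fpr, tpr]),
        fold_assignments={s: int(fv) for s, fv in zip(cohort.samples, fold_of)},
        decision_values={s: float(d) for s, d in zip(cohort.samples, decisions)},
        seed=seed,
        folds=k,
    )
    return SingleSetResult(cohort.cohort_id, per_fold, n_fold, freq, test_eval)


def signature_genes(result: SingleSetResult, n: int | None = None) -> list:
    """Consolidated signature: most frequently selected genes.

    With `n` unset the median of the per-fold gene counts is used.  This
    is the gene list to carry to an independent cohort when probing
    cross-study transferability.
    """
    if n is None:
        n = int(round(float(np.median(list(result.n_per_fold.values())))))
    return list(result.consensus_genes.index[:max(1, n)])
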