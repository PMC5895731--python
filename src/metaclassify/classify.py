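"""Cross-validated SVM evaluation of a gene set on one cohort.

The discriminative value of a candidate gene set is measured by a
Gaussian-kernel (RBF) SVM in a stratified ("balanced") 10-fold CV.
Within each outer training fold the features are z-scored with
training-fold statistics and the SVM hyperparameters (C, gamma) are
chosen by grid search in an inner stratified 3-fold CV that maximizes
inner AUC.  Decision values of all outer test folds are pooled into a
single ROC curve; the AUC is the trapezoid area and its 95% confidence
interval comes from DeLong's asymptotic variance estimate.

A label-permutation control re-runs the complete meta-analysis after
independently shuffling class labels within each cohort; with no true
class structure the mean held-out AUC must be compatible with 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import _svm
from .cohort_io import ExpressionCohort

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "CVEvaluation",
    "svm_cv_auc",
    "permutation_control",
    "auc_mann_whitney",
    "delong_ci",
]

log = logging.getLogger(__name__)

# log2-spaced hyperparameter grid for the inner search
DEFAULT_C_GRID = tuple(2.0 ** e for e in (-3, -1, 1, 3, 5, 7))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in (-7, -5, -3, -1, 1, 3))


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def auc_mann_whitney(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (midranks for ties)."""
    y = np.asarray(y, dtype=bool)
    m = int(y.sum())
    n = int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes present")
    r = _midrank(np.asarray(scores, dtype=float))
    return (r[y].sum() - m * (m + 1) / 2.0) / (m * n)


def delong_ci(y: np.ndarray, scores: np.ndarray, level: float = 0.95):
    """DeLong 95% confidence interval for the AUC of pooled scores.

    Returns (auc, (low, high)); the interval is clipped to [0, 1] and
    collapses onto the point estimate when the DeLong variance is zero
    (e.g. perfectly separated or constant scores).
    """
    from scipy import stats

    y = np.asarray(y, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(s)
    auc = (tz[y].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[y] - tx) / n          # structural components, positives
    v10 = 1.0 - (tz[~y] - ty) / m   # structural components, negatives
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    if var <= 0:
        return auc, (auc, auc)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


@dataclass
class CVEvaluation:
    """Pooled cross-validated ROC/AUC for one (cohort, gene set) pair."""

    cohort_id: str
    gene_set: list
    auc: float
    auc_ci: tuple
    roc_points: np.ndarray          # (k, 2) array of (FPR, TPR)
    fold_assignments: dict          # sample -> outer fold index
    decision_values: dict           # sample -> pooled decision value
    seed: int
    folds: int = 10
    dropped_genes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "gene_set": list(self.gene_set),
            "auc": float(self.auc),
            "auc_ci": [float(self.auc_ci[0]), float(self.auc_ci[1])],
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
            "folds": int(self.folds),
            "seed": int(self.seed),
        }


def _grid_search_fold(X_tr, y_tr, X_te, c_grid, gamma_grid, inner_folds, seed):
    """Tune (C, gamma) on the training fold, return test decision values."""
    n_pos = int(y_tr.sum())
    n_neg = int(len(y_tr) - n_pos)
    k = min(inner_folds, n_pos, n_neg)
    ysvm = np.where(y_tr, 1.0, -1.0)
    if k < 2:
        # too few samples to tune; fall back to the grid midpoint
        best_c, best_g = c_grid[len(c_grid) // 2], gamma_grid[len(gamma_grid) // 2]
        return _svm.svm_decision_values(X_tr, ysvm, X_te, best_c, best_g)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X_tr, y_tr))
    # distance matrix computed once; one kernel per gamma
    D = _svm._sq_dists(np.ascontiguousarray(X_tr), np.ascontiguousarray(X_tr))
    best = (-np.inf, 0)
    best_cg = (c_grid[0], gamma_grid[0])
    for gi, gamma in enumerate(gamma_grid):
        K = np.exp(-gamma * D)
        for ci, C in enumerate(c_grid):
            aucs = []
            for itr, ite in splits:
                Kii = np.ascontiguousarray(K[np.ix_(itr, itr)])
                alpha, b = _svm.smo_solve(Kii, ysvm[itr], C)
                dec = K[np.ix_(ite, itr)] @ (alpha * ysvm[itr]) + b
                aucs.append(auc_mann_whitney(y_tr[ite], dec))
            score = float(np.mean(aucs))
            order = ci * len(gamma_grid) + gi  # C-major grid order for ties
            if score > best[0] or (score == best[0] and order < best[1]):
                best = (score, order)
                best_cg = (C, gamma)
    return _svm.svm_decision_values(X_tr, ysvm, X_te, *best_cg)


def svm_cv_auc(cohort: ExpressionCohort, genes, folds: int = 10, seed: int = 0,
               c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
               inner_folds: int = 3) -> CVEvaluation:
    """Stratified k-fold RBF-SVM evaluation of `genes` on one cohort.

    Raises ``KeyError`` listing any gene absent from the cohort.  If a
    class has fewer samples than `folds`, the fold count is reduced to
    the minority class size (logged).
    """
    genes = list(genes)
    idx = cohort.gene_index(genes)
    X = np.ascontiguousarray(cohort.values[idx].T)
    y = cohort.y
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    k = min(folds, n_pos, n_neg)
    if k < folds:
        log.info("%s: reducing folds from %d to %d (minority class size)",
                 cohort.cohort_id, folds, k)
    if k < 2:
        raise ValueError(f"{cohort.cohort_id}: need >= 2 samples per class")
    seed = int(seed) % (2**31 - 1)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    decisions = np.empty(len(y))
    fold_of = np.empty(len(y), dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        X_tr = (X[tr] - mu) / sd
        X_te = (X[te] - mu) / sd
        inner_seed = (seed + 1000003 * (f + 1)) % (2**31 - 1)
        decisions[te] = _grid_search_fold(X_tr, y[tr], X_te, c_grid,
                                          gamma_grid, inner_folds, inner_seed)
        fold_of[te] = f
    fpr, tpr, _ = roc_curve(y, decisions, drop_intermediate=False)
    auc, ci = delong_ci(y, decisions)
    return CVEvaluation(
        cohort_id=cohort.cohort_id,
        gene_set=genes,
        auc=float(auc),
        auc_ci=ci,
        roc_points=np.column_stack([fpr, tpr]),
        fold_assignments={s: int(f) for s, f in zip(cohort.samples, fold_of)},
        decision_values={s: float(d) for s, d in zip(cohort.samples, decisions)},
        seed=seed,
        folds=k,
    )


def _shuffled_cohort(cohort: ExpressionCohort, rng: np.random.Generator) -> ExpressionCohort:
    return ExpressionCohort(
        cohort_id=cohort.cohort_id,
        genes=cohort.genes.copy(),
        samples=cohort.samples.copy(),
        values=cohort.values.copy(),
        y=rng.permutation(cohort.y),
    )


def permutation_control(cohorts, n_perm: int, seed: int = 0,
                        criterion: str = "abs_log2fc", grid=None,
                        folds: int = 10, identity: bool = False) -> np.ndarray:
    """Null distribution of the pipeline's mean held-out AUC.

    For each permutation the class labels are shuffled independently
    within each cohort (class counts preserved) and the complete
    leave-one-cohort-out meta-analysis is re-run; the mean held-out test
    AUC is recorded.  With ``identity=True`` the labels are left
    untouched, which must reproduce the unpermuted pipeline result.
    """
    from .meta_select import run_meta_analysis

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(cohorts) < 2:
        raise ValueError("permutation control needs >= 2 cohorts")
    out = np.empty(n_perm)
    for p in range(n_perm):
        rng = np.random.default_rng([int(seed) % 2**31, p])
        if identity:
            shuffled = list(cohorts)
        else:
            shuffled = [_shuffled_cohort(c, rng) for c in cohorts]
        res = run_meta_analysis(shuffled, criterion=criterion, grid=grid,
                                seed=(int(seed) + 7919 * p) % (2**31 - 1),
                                folds=folds)
        out[p] = res.mean_test_auc
    return out
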