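"""Leave-one-cohort-out meta-analysis orchestration.

Each cohort in turn is held out for testing while the remaining cohorts
drive feature selection: genes are ranked within each training cohort,
the normalized ranks are aggregated, and the number of genes n taken
from the top of the combined ranking is optimized in an *inner*
leave-one-cohort-out loop over the training cohorts (n in {5,10,...,50}
by default, ties resolved toward the smallest n).  The top-n genes are
then evaluated on the held-out cohort with the cross-validated SVM.
Held-out data never enters ranking or the choice of n.

The per-holdout gene sets combine into the union ("classifier genes")
and the intersection ("core genes" — those selected in every holdout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import CVEvaluation, svm_cv_auc
from .cohort_io import ExpressionCohort
from .ranking import build_ranking_table

__all__ = [
    "DEFAULT_N_GRID",
    "SelectionResult",
    "MetaResult",
    "optimize_n",
    "run_meta_analysis",
    "core_genes",
]

DEFAULT_N_GRID = tuple(range(5, 51, 5))


@dataclass
class SelectionResult:
    """Outcome of one outer holdout round."""

    held_out_cohort: str
    n_selected: int
    selected_genes: list
    test_eval: CVEvaluation
    inner_scores: dict          # n -> mean inner AUC

    def to_dict(self) -> dict:
        return {
            "held_out_cohort": self.held_out_cohort,
            "n_selected": int(self.n_selected),
            "selected_genes": list(self.selected_genes),
            "test_auc": float(self.test_eval.auc),
            "test_auc_ci": [float(v) for v in self.test_eval.auc_ci],
            "inner_scores": {int(k): float(v) for k, v in self.inner_scores.items()},
        }


@dataclass
class MetaResult:
    """Full leave-one-cohort-out result."""

    per_holdout: list
    union_genes: list
    core_genes: list
    mean_test_auc: float
    criterion: str = "abs_log2fc"

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "mean_test_auc": float(self.mean_test_auc),
            "union_genes": list(self.union_genes),
            "core_genes": list(self.core_genes),
            "per_holdout": [r.to_dict() for r in self.per_holdout],
        }


def _derive_seed(seed: int, *keys: int) -> int:
    s = int(seed) % (2**31 - 1)
    for k in keys:
        s = (s * 1000003 + int(k) + 1) % (2**31 - 1)
    return s


def _candidates_for(aggregated, cohort: ExpressionCohort) -> list:
    """Aggregated ranking restricted to genes the evaluation cohort measures.

    Gene universes differ across platforms, so a top-ranked training gene
    can be absent from the cohort it is evaluated on; such genes are
    skipped (the next-ranked measurable gene moves up).
    """
    present = set(cohort.genes)
    return [g for g in aggregated.index if g in present]


def optimize_n(training: list, criterion: str = "abs_log2fc",
               grid=DEFAULT_N_GRID, seed: int = 0, folds: int = 10):
    """Pick the gene count n by an inner leave-one-cohort-out loop.

    For every candidate n and every inner held-out training cohort, the
    rankings of the *remaining* training cohorts are aggregated, the top
    n genes taken, and their cross-validated SVM AUC measured on the
    inner held-out cohort.  The inner score of n is the mean AUC over
    inner holdouts; the smallest n attaining the maximum wins.
    """
    if len(training) < 2:
        raise ValueError("inner LOOCV needs >= 2 training cohorts")
    grid = sorted(int(n) for n in grid)
    if not grid or grid[0] < 1:
        raise ValueError("empty or invalid gene-count grid")
    universe = set(training[0].genes)
    for c in training[1:]:
        universe &= set(c.genes)
    if grid[-1] > len(universe):
        raise ValueError(
            f"grid maximum {grid[-1]} exceeds the {len(universe)} genes "
            "shared by all training cohorts"
        )
    scores = {n: [] for n in grid}
    for d_idx, inner_holdout in enumerate(training):
        rest = [c for i, c in enumerate(training) if i != d_idx]
        table = build_ranking_table(rest, criterion)
        candidates = _candidates_for(table.aggregated, inner_holdout)
        for n in grid:
            genes = candidates[:n]
            ev = svm_cv_auc(inner_holdout, genes, folds=folds,
                            seed=_derive_seed(seed, d_idx, n))
            scores[n].append(ev.auc)
    inner_scores = {n: float(np.mean(v)) for n, v in scores.items()}
    best = max(inner_scores.values())
    n_best = min(n for n, v in inner_scores.items() if v == best)
    return n_best, inner_scores


def run_meta_analysis(cohorts: list, criterion: str = "abs_log2fc",
                      grid=None, seed: int = 0, folds: int = 10) -> MetaResult:
    """Complete leave-one-cohort-out meta-analysis over >= 3 cohorts."""
    if grid is None:
        grid = DEFAULT_N_GRID
    if len(cohorts) < 3:
        raise ValueError("meta-analysis needs >= 3 cohorts "
                         "(one holdout plus >= 2 for the inner LOOCV)")
    ids = [c.cohort_id for c in cohorts]
    if len(set(ids)) != len(ids):
        raise ValueError("cohort identifiers must be unique")
    for c in cohorts:
        c.validate()
    per_holdout = []
    for h_idx, holdout in enumerate(cohorts):
        training = [c for i, c in enumerate(cohorts) if i != h_idx]
        n_best, inner_scores = optimize_n(training, criterion, grid,
                                          seed=_derive_seed(seed, h_idx),
                                          folds=folds)
        table = build_ranking_table(training, criterion)
        selected = _candidates_for(table.aggregated, holdout)[:n_best]
        test_eval = svm_cv_auc(holdout, selected, folds=folds,
                               seed=_derive_seed(seed, h_idx, 999331))
        per_holdout.append(SelectionResult(
            held_out_cohort=holdout.cohort_id,
            n_selected=n_best,
            selected_genes=selected,
            test_eval=test_eval,
            inner_scores=inner_scores,
        ))
    sets = [set(r.selected_genes) for r in per_holdout]
    union = sorted(set.union(*sets))
    core = sorted(set.intersection(*sets))
    mean_auc = float(np.mean([r.test_eval.auc for r in per_holdout]))
    return MetaResult(per_holdout, union, core, mean_auc, criterion)


def core_genes(meta: MetaResult, survival_keep=None) -> list:
    """Genes selected in every holdout, optionally filtered further.

    `survival_keep` restricts the core to genes whose clusters showed a
    survival association (the route by which the robust classifier is
    narrowed to a prognostic subset).
    """
    sets = [set(r.selected_genes) for r in meta.per_holdout]
    core = set.intersection(*sets) if sets else set()
    if survival_keep is not None:
        core &= set(survival_keep)
    return sorted(core)
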