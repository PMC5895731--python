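"""Within-cohort gene scoring, ranking, rank normalization and
cross-cohort aggregation.

Genes are ranked within each cohort so that rank 1 is the most
informative gene.  Because cohorts measure different numbers of genes,
ranks are normalized to [0, 1] by

    normR = (R - 1) / (max(R) - 1)

and aggregated across cohorts as the arithmetic mean of normalized
ranks, yielding one combined ranking (smaller = better) from which the
top-n biomarker candidates are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionCohort

__all__ = [
    "CRITERIA",
    "RankingTable",
    "score_genes",
    "rank_genes",
    "normalize_ranks",
    "aggregate_ranks",
    "build_ranking_table",
]

CRITERIA = ("abs_log2fc", "pvalue", "svm_weight")


def score_genes(cohort: ExpressionCohort, criterion: str = "abs_log2fc") -> pd.Series:
    """Score every gene of a cohort by its tumor/non-tumor contrast.

    abs_log2fc : |mean(log2 expr | positive) - mean(log2 expr | negative)|
    pvalue     : two-sided Welch t-test p-value (smaller = better)
    svm_weight : |weight| of a linear SVM trained on the z-scored cohort
    """
    pos = cohort.values[:, cohort.y]
    neg = cohort.values[:, ~cohort.y]
    if criterion == "abs_log2fc":
        scores = np.abs(pos.mean(axis=1) - neg.mean(axis=1))
    elif criterion == "pvalue":
        scores = stats.ttest_ind(pos, neg, axis=1, equal_var=False).pvalue
        scores = np.where(np.isfinite(scores), scores, 1.0)
    elif criterion == "svm_weight":
        from sklearn.svm import SVC

        X = cohort.values.T
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=1.0)
        clf.fit((X - mu) / sd, cohort.y.astype(int))
        scores = np.abs(clf.coef_.ravel())
    else:
        raise ValueError(f"unknown ranking criterion {criterion!r}; "
                         f"expected one of {CRITERIA}")
    return pd.Series(scores, index=cohort.genes, name=criterion)


def rank_genes(scores: pd.Series, criterion: str = "abs_log2fc") -> pd.Series:
    """Integer ranks 1..G, rank 1 = most informative.

    For `pvalue` smaller scores rank first; otherwise larger scores rank
    first.  Ties are broken lexicographically by gene identifier so the
    ranking is deterministic.
    """
    if len(scores) == 0:
        raise ValueError("cannot rank an empty score table")
    if criterion not in CRITERIA:
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    ascending = criterion == "pvalue"
    df = pd.DataFrame({"score": scores})
    df = df.sort_index().sort_values("score", ascending=ascending, kind="stable")
    ranks = pd.Series(np.arange(1, len(df) + 1), index=df.index, name="rank")
    return ranks.reindex(scores.index)


def normalize_ranks(ranks: pd.Series) -> pd.Series:
    """Map within-cohort ranks to [0, 1] via (R - 1) / (max(R) - 1)."""
    max_rank = int(ranks.max())
    if len(ranks) < 2 or max_rank < 2:
        raise ValueError("rank normalization needs at least 2 ranked genes")
    return (ranks - 1) / (max_rank - 1)


def aggregate_ranks(normalized: list[pd.Series]) -> pd.Series:
    """Mean normalized rank per gene across cohorts, best first.

    Aggregation is restricted to genes present in every supplied
    ranking, keeping the arithmetic mean well defined when cohort gene
    universes differ.  The result is sorted ascending with gene-ID
    tie-break.
    """
    if not normalized:
        raise ValueError("no rankings supplied")
    common = normalized[0].index
    for r in normalized[1:]:
        common = common.intersection(r.index)
    if len(common) == 0:
        raise ValueError("gene universes of the supplied rankings are disjoint")
    mat = np.column_stack([r.loc[common].to_numpy() for r in normalized])
    ave = pd.Series(mat.mean(axis=1), index=common, name="aveR")
    return ave.sort_index().sort_values(kind="stable")


@dataclass
class RankingTable:
    """Per-cohort scores/ranks and the aggregated cross-cohort ranking."""

    criterion: str
    per_cohort_scores: dict
    per_cohort_ranks: dict
    normalized_ranks: dict
    aggregated: pd.Series

    def top_n(self, n: int) -> list[str]:
        return list(self.aggregated.index[:n])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"aveR": self.aggregated})
        for cid, nr in self.normalized_ranks.items():
            df[f"normR_{cid}"] = nr.reindex(df.index)
        return df

    def export(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def build_ranking_table(cohorts: list[ExpressionCohort],
                        criterion: str = "abs_log2fc") -> RankingTable:
    """Score, rank, normalize and aggregate a set of training cohorts."""
    scores, ranks, normed = {}, {}, {}
    for c in cohorts:
        s = score_genes(c, criterion)
        r = rank_genes(s, criterion)
        scores[c.cohort_id] = s
        ranks[c.cohort_id] = r
        normed[c.cohort_id] = normalize_ranks(r)
    agg = aggregate_ranks(list(normed.values()))
    return RankingTable(criterion, scores, ranks, normed, agg)
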