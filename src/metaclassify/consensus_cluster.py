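"""Subsample-based consensus clustering of classifier genes.

Genes are clustered by co-expression: for each of many random sample
subsets, pairwise Spearman correlation between genes is turned into a
distance (1 - rho), Ward-linked, and cut at k.  The consensus matrix
records how often each gene pair lands in the same cluster; a final
Ward cut on (1 - consensus) yields the reported assignment.  The
cluster count is selected from the empirical CDF of consensus values:
the area under the CDF grows as k increases, and k is taken as the
largest value whose relative area gain is still substantial.

Expression from several cohorts is combined by z-scoring each gene
within each cohort and concatenating samples, which removes platform
scale without ever comparing raw intensities across studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "ConsensusResult",
    "SelectKResult",
    "combine_cohorts_zscore",
    "consensus_cluster",
    "select_k",
]


def combine_cohorts_zscore(cohorts, genes) -> pd.DataFrame:
    """Within-cohort z-scored expression of `genes`, samples concatenated.

    Only genes measured in every cohort can be combined; missing genes
    raise so the caller can prune the gene list explicitly.
    """
    genes = list(genes)
    blocks = []
    for c in cohorts:
        idx = c.gene_index(genes)
        vals = c.values[idx]
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        blocks.append(pd.DataFrame((vals - mu) / sd, index=genes, columns=c.samples))
    return pd.concat(blocks, axis=1)


@dataclass
class ConsensusResult:
    k: int
    consensus_matrix: pd.DataFrame     # gene x gene co-clustering frequency
    assignments: dict                  # gene -> cluster id 1..k
    cdf_area: float
    n_resamples: int
    subsample_frac: float
    seed: int
    ambiguity: float = 0.0             # fraction of off-diag entries in (0.1, 0.9)

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "assignments": {g: int(c) for g, c in self.assignments.items()},
            "cdf_area": float(self.cdf_area),
            "ambiguity": float(self.ambiguity),
            "n_resamples": int(self.n_resamples),
            "subsample_frac": float(self.subsample_frac),
        }


def _ward_cut(dist_condensed: np.ndarray, k: int) -> np.ndarray:
    return fcluster(linkage(dist_condensed, method="ward"), k, criterion="maxclust")


def _spearman_distance(sub: np.ndarray) -> np.ndarray:
    rho = spearmanr(sub, axis=1).statistic
    if np.isscalar(rho):                       # two genes
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    mapping, nxt = {}, 1
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def consensus_cluster(expr: pd.DataFrame, k: int, n_resamples: int = 250,
                      subsample_frac: float = 0.8, seed: int = 0) -> ConsensusResult:
    """Consensus clustering of the rows of `expr` (genes x samples).

    Each resample draws ceil(frac * S) sample columns without
    replacement, computes 1 - Spearman correlation between genes over
    those columns, Ward-links and cuts at k.  The consensus matrix is
    the co-clustering frequency over all resamples (samples are
    resampled, genes never are, so the denominator is n_resamples).
    """
    genes = expr.index.to_numpy()
    X = expr.to_numpy(dtype=float)
    if len(genes) < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} genes, got {len(genes)}")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    const = np.where(X.std(axis=1) == 0)[0]
    if len(const):
        raise ValueError(
            f"gene {genes[const[0]]!r} is constant across samples; "
            "Spearman correlation is undefined"
        )
    n_samp = X.shape[1]
    n_draw = math.ceil(subsample_frac * n_samp)
    consensus = np.zeros((len(genes), len(genes)))
    for r in range(n_resamples):
        rng = np.random.default_rng([int(seed) % 2**31, r])
        cols = rng.choice(n_samp, size=n_draw, replace=False)
        d = _spearman_distance(X[:, cols])
        labels = _ward_cut(squareform(d, checks=False), k)
        consensus += labels[:, None] == labels[None, :]
    consensus /= n_resamples
    np.fill_diagonal(consensus, 1.0)
    final = _ward_cut(squareform(1.0 - consensus, checks=False), k)
    final = _relabel_by_first_occurrence(final)
    tri = consensus[np.triu_indices(len(genes), 1)]
    return ConsensusResult(
        k=k,
        consensus_matrix=pd.DataFrame(consensus, index=genes, columns=genes),
        assignments={g: int(c) for g, c in zip(genes, final)},
        cdf_area=_cdf_area(tri),
        n_resamples=n_resamples,
        subsample_frac=subsample_frac,
        seed=int(seed),
        ambiguity=float(np.mean((tri > 0.1) & (tri < 0.9))) if len(tri) else 0.0,
    )


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus values on [0, 1]."""
    if len(values) == 0:
        return 0.0
    xs = np.sort(values)
    grid = np.concatenate([[0.0], xs, [1.0]])
    cdf = np.searchsorted(xs, grid, side="right") / len(xs)
    return float(np.sum(np.diff(grid) * cdf[:-1]))


@dataclass
class SelectKResult:
    k_best: int
    results: dict                      # k -> ConsensusResult
    cdf_area: dict                     # k -> area under consensus CDF
    delta_area: dict                   # k -> relative change
    unstable: bool = False
    ambiguity_threshold: float = 0.3

    def to_dict(self) -> dict:
        return {
            "k_best": int(self.k_best),
            "cdf_area": {int(k): float(v) for k, v in self.cdf_area.items()},
            "delta_area": {int(k): float(v) for k, v in self.delta_area.items()},
            "unstable": bool(self.unstable),
            "per_k": {int(k): r.to_dict() for k, r in self.results.items()},
        }


def select_k(expr: pd.DataFrame, k_range=range(2, 7), n_resamples: int = 250,
             subsample_frac: float = 0.8, seed: int = 0,
             delta_threshold: float = 0.1,
             ambiguity_threshold: float = 0.3) -> SelectKResult:
    """Choose the cluster count from consensus CDFs.

    Delta(2) = A(2) and Delta(k) = (A(k) - A(k-1)) / A(k-1) for k > 2;
    k_best is the largest k whose Delta exceeds `delta_threshold`.  The
    same resampled column sets are reused for every k so the CDFs are
    comparable.  If the chosen clustering leaves a large fraction of
    gene pairs with ambiguous consensus (strictly between 0.1 and 0.9),
    the result is flagged unstable — no k gives a reproducible split.
    """
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("empty k range")
    results, areas = {}, {}
    for k in ks:
        res = consensus_cluster(expr, k, n_resamples, subsample_frac, seed)
        results[k] = res
        areas[k] = res.cdf_area
    deltas = {}
    prev = None
    for k in ks:
        if prev is None:
            deltas[k] = areas[k]
        else:
            deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k
    above = [k for k in ks if deltas[k] > delta_threshold]
    k_best = max(above) if above else ks[0]
    unstable = results[k_best].ambiguity > ambiguity_threshold
    return SelectKResult(k_best, results, areas, deltas, unstable,
                         ambiguity_threshold)
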