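import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaclassify.cohort_io import ExpressionCohort
from metaclassify.ranking import (aggregate_ranks, build_ranking_table,
                                  normalize_ranks, rank_genes, score_genes)
from tests.conftest import make_cohort


def _two_by_four(values_pos, values_neg):
    vals = np.array([values_pos + values_neg], dtype=float)
    return ExpressionCohort("c", ["g"], ["a", "b", "c", "d"], vals,
                            [True, True, False, False])


def test_abs_log2fc_constant_groups():
    c = _two_by_four([5.0, 5.0], [3.0, 3.0])
    assert score_genes(c, "abs_log2fc")["g"] == pytest.approx(2.0)
    c = _two_by_four([4.0, 6.0], [4.0, 6.0])
    assert score_genes(c, "abs_log2fc")["g"] == pytest.approx(0.0)


def test_abs_log2fc_matches_direct_recomputation():
    c = make_cohort(n_genes=20, n_per_class=8, seed=2)
    s = score_genes(c, "abs_log2fc")
    for i, g in enumerate(c.genes):
        expected = abs(c.values[i, c.y].mean() - c.values[i, ~c.y].mean())
        assert s[g] == pytest.approx(expected, abs=1e-12)


def test_pvalue_criterion_is_welch_t():
    from scipy import stats
    c = make_cohort(n_genes=10, n_per_class=6, seed=3)
    s = score_genes(c, "pvalue")
    i = 4
    ref = stats.ttest_ind(c.values[i, c.y], c.values[i, ~c.y], equal_var=False)
    assert s[c.genes[i]] == pytest.approx(ref.pvalue)


def test_svm_weight_scores_planted_gene_highest():
    c = make_cohort(n_genes=15, n_per_class=10, seed=4, planted=(3,), effect=5.0)
    s = score_genes(c, "svm_weight")
    assert s.idxmax() == c.genes[3]


def test_unknown_criterion_rejected(noise_cohort):
    with pytest.raises(ValueError, match="criterion"):
        score_genes(noise_cohort, "entropy")


def test_rank_examples():
    r = rank_genes(pd.Series({"a": 3.0, "b": 1.0, "c": 2.0}), "abs_log2fc")
    assert r.to_dict() == {"a": 1, "c": 2, "b": 3}
    # smaller p-values rank first
    r = rank_genes(pd.Series({"a": 0.5, "b": 0.001}), "pvalue")
    assert r.to_dict() == {"b": 1, "a": 2}


def test_rank_ties_follow_gene_id_order():
    r = rank_genes(pd.Series({"z": 1.0, "a": 1.0, "m": 1.0}), "abs_log2fc")
    assert r.to_dict() == {"a": 1, "m": 2, "z": 3}


def test_rank_matches_argsort_oracle():
    rng = np.random.default_rng(9)
    scores = pd.Series(rng.normal(size=200),
                       index=[f"g{i:03d}" for i in range(200)])
    r = rank_genes(scores, "abs_log2fc")
    order = scores.sort_values(ascending=False).index
    assert list(r.sort_values().index) == list(order)
    assert sorted(r) == list(range(1, 201))


def test_normalize_rank_formula():
    ranks = pd.Series(np.arange(1, 101), index=[f"g{i}" for i in range(100)])
    nr = normalize_ranks(ranks)
    assert nr.iloc[0] == 0.0
    assert nr.iloc[99] == 1.0
    assert normalize_ranks(pd.Series({"a": 3, "b": 1, "c": 5, "d": 2, "e": 4}))["a"] \
        == pytest.approx(0.5)


def test_normalize_single_gene_undefined():
    with pytest.raises(ValueError):
        normalize_ranks(pd.Series({"a": 1}))


def test_aggregate_mean_and_order():
    a = pd.Series({"x": 0.0, "y": 1.0})
    b = pd.Series({"x": 1.0, "y": 0.0})
    agg = aggregate_ranks([a, b])
    assert agg["x"] == pytest.approx(0.5)
    assert agg["y"] == pytest.approx(0.5)
    # identical rankings aggregate to the same order
    r = pd.Series({"a": 0.0, "b": 0.5, "c": 1.0})
    agg = aggregate_ranks([r, r, r])
    assert list(agg.index) == ["a", "b", "c"]


def test_aggregate_matches_brute_force_mean():
    rng = np.random.default_rng(0)
    genes = [f"g{i:03d}" for i in range(100)]
    rankings = []
    for _ in range(5):
        perm = rng.permutation(100) + 1
        rankings.append((pd.Series(perm, index=genes) - 1) / 99.0)
    agg = aggregate_ranks(rankings)
    for g in genes:
        brute = sum(r[g] for r in rankings) / 5.0
        assert abs(agg[g] - brute) < 1e-12


def test_aggregate_invariant_to_cohort_order():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(30)]
    rankings = [pd.Series(rng.random(30), index=genes) for _ in range(4)]
    a = aggregate_ranks(rankings)
    b = aggregate_ranks(rankings[::-1])
    pd.testing.assert_series_equal(a, b)


def test_aggregate_disjoint_universes_error():
    with pytest.raises(ValueError, match="disjoint"):
        aggregate_ranks([pd.Series({"a": 0.0}), pd.Series({"b": 0.0})])


def test_aggregate_restricted_to_shared_genes():
    a = pd.Series({"x": 0.0, "y": 0.5, "only_a": 1.0})
    b = pd.Series({"x": 0.2, "y": 0.8})
    agg = aggregate_ranks([a, b])
    assert set(agg.index) == {"x", "y"}


@settings(deadline=None, max_examples=25, derandomize=True)
@given(shift=st.floats(-50, 50, allow_nan=False))
def test_abs_log2fc_invariant_to_constant_shift(shift):
    c = make_cohort(n_genes=8, n_per_class=5, seed=6)
    shifted = ExpressionCohort(c.cohort_id, c.genes, c.samples,
                               c.values + shift, c.y)
    pd.testing.assert_series_equal(score_genes(c, "abs_log2fc"),
                                   score_genes(shifted, "abs_log2fc"))


def test_adding_agreeing_cohort_preserves_top_n():
    cohorts = [make_cohort(f"c{i}", n_genes=40, n_per_class=8, seed=i,
                           planted=(0, 1, 2), effect=4.0) for i in range(3)]
    table = build_ranking_table(cohorts)
    agg = table.aggregated
    # a new "cohort" ranked exactly like the aggregate
    clone = pd.Series(np.linspace(0, 1, len(agg)), index=agg.index)
    combined = aggregate_ranks(
        [table.normalized_ranks[c.cohort_id] for c in cohorts] + [clone])
    for n in (1, 5, 10, 20):
        assert set(agg.index[:n]) == set(combined.index[:n])
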