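import numpy as np
import pandas as pd
import pytest

from metaclassify.survival import (five_year_rate, km_estimate, logrank_test,
                                   stratify_and_test, stratify_patients)


def _table(times, events, prefix="s"):
    idx = [f"{prefix}{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=idx)


def test_km_two_subject_hand_example():
    st = _table([1.0, 2.0], [1, 1])
    curve = km_estimate(st)
    assert curve.loc[1.0, "S"] == pytest.approx(0.5)   # (1 - 1/2)
    assert curve.loc[2.0, "S"] == pytest.approx(0.0)   # (1 - 1/2)(1 - 1/1)


def test_km_all_censored_stays_at_one():
    st = _table([3.0, 5.0, 9.0], [0, 0, 0])
    curve = km_estimate(st)
    assert (curve["S"] == 1.0).all()


def _brute_force_km(times, events, t):
    """Product-limit over event times <= t, computed from first principles."""
    s = 1.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        d = np.sum((times == u) & (events == 1))
        at_risk = np.sum(times >= u)
        s *= 1.0 - d / at_risk
    return s


def test_km_matches_brute_force_oracle_on_random_subjects():
    rng = np.random.default_rng(10)
    times = np.round(rng.exponential(5.0, size=50), 1) + 0.1
    events = (rng.random(50) < 0.7).astype(int)
    st = _table(times, events)
    curve = km_estimate(st)
    for t in sorted(set(times[events == 1])):
        assert curve.loc[t, "S"] == pytest.approx(
            _brute_force_km(times, events, t), abs=1e-12)


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(11)
    times = rng.exponential(2.0, size=40)
    st = _table(times, np.ones(40, int))
    curve = km_estimate(st)
    for t in times:
        assert curve.loc[t, "S"] == pytest.approx(np.mean(times > t), abs=1e-12)


def test_logrank_identical_groups_chi2_zero():
    times = [1.0, 2.0, 3.0, 4.0]
    events = [1, 0, 1, 1]
    st = pd.concat([_table(times, events, "a"), _table(times, events, "b")])
    groups = {s: ("A" if s.startswith("a") else "B") for s in st.index}
    chi2, p = logrank_test(st, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_detects_hazard_ratio_four():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(200 + seed)
        t1 = rng.exponential(1.0, 100)
        t2 = rng.exponential(4.0, 100)
        st = pd.concat([_table(t1, np.ones(100, int), "a"),
                        _table(t2, np.ones(100, int), "b")])
        groups = {s: s[0] for s in st.index}
        _, p = logrank_test(st, groups)
        hits += p < 0.01
    assert hits >= 9


def test_logrank_null_p_roughly_uniform():
    ps = []
    for seed in range(50):
        rng = np.random.default_rng(300 + seed)
        t = rng.exponential(2.0, 60)
        st = _table(t, np.ones(60, int))
        groups = {s: f"G{i % 3}" for i, s in enumerate(st.index)}
        ps.append(logrank_test(st, groups)[1])
    assert 0.3 <= np.mean(ps) <= 0.7


def test_logrank_invariant_to_consistent_relabeling():
    rng = np.random.default_rng(42)
    st = _table(rng.exponential(1, 30), (rng.random(30) < 0.8).astype(int))
    g1 = {s: ("x" if i < 15 else "y") for i, s in enumerate(st.index)}
    g2 = {s: ("y" if v == "x" else "x") for s, v in g1.items()}
    assert logrank_test(st, g1)[0] == pytest.approx(logrank_test(st, g2)[0])


def test_five_year_rate_readout():
    curve = pd.DataFrame({"S": [1.0, 1.0]}, index=[0.0, 6.0 * 365.25])
    rate = five_year_rate(curve, time_unit="days")
    assert rate.rate == 1.0 and not rate.truncated
    curve = pd.DataFrame({"S": [1.0, 0.5]}, index=[0.0, 3.0])
    rate = five_year_rate(curve, time_unit="years")
    assert rate.rate == 0.5 and rate.truncated  # follow-up ends at year 3


def test_five_year_rate_matches_exponential_closed_form():
    rng = np.random.default_rng(13)
    lam = 0.1
    times = rng.exponential(1 / lam, size=4000)
    st = _table(times, np.ones(len(times), int))
    rate = five_year_rate(km_estimate(st), time_unit="years")
    assert rate.rate == pytest.approx(np.exp(-lam * 5), abs=0.03)


# -- stratification ----------------------------------------------------

def _three_level_expr(seed=0, n_per=8, n_genes=5):
    rng = np.random.default_rng(seed)
    cols, data = [], []
    for level, mu in (("lo", -3.0), ("mid", 0.0), ("hi", 3.0)):
        for i in range(n_per):
            cols.append(f"{level}{i}")
            data.append(mu + rng.normal(0, 0.3, n_genes))
    return pd.DataFrame(np.array(data).T,
                        index=[f"g{i}" for i in range(n_genes)], columns=cols)


def test_stratification_follows_planted_levels():
    expr = _three_level_expr()
    groups = stratify_patients(expr)
    for p, g in groups.items():
        expected = {"lo": "low", "mid": "intermediate", "hi": "high"}[p[:2]
                    if p[:2] in ("lo", "hi") else "mid"]
        assert g == expected


def test_stratification_invariant_to_gene_row_order():
    expr = _three_level_expr(seed=2)
    a = stratify_patients(expr)
    b = stratify_patients(expr.iloc[::-1])
    assert a == b


def test_identical_patients_refuse_three_split():
    expr = pd.DataFrame(np.ones((4, 6)), index=[f"g{i}" for i in range(4)],
                        columns=[f"p{i}" for i in range(6)])
    with pytest.raises(ValueError, match="distinct"):
        stratify_patients(expr)


def test_stratify_and_test_pipeline():
    expr = _three_level_expr(seed=5, n_per=12)
    rng = np.random.default_rng(5)
    # hazard rises with the planted expression level
    lam = {"lo": 0.05, "mi": 0.2, "hi": 0.8}
    times = [rng.exponential(1 / lam[p[:2]]) for p in expr.columns]
    st = pd.DataFrame({"time": times, "event": 1}, index=expr.columns)
    res = stratify_and_test(expr, st, time_unit="years")
    assert res.logrank_p < 0.01
    assert res.five_year["low"].rate >= res.five_year["high"].rate
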