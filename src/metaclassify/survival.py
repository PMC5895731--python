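"""Survival stratification by gene-cluster expression.

Patients are divided into low / intermediate / high expression groups by
Ward's hierarchical clustering (Euclidean distance on per-gene z-scored
profiles, cut at three), the groups' survival is summarized by
Kaplan-Meier product-limit curves, compared by the k-group log-rank
test, and read out as the 5-year survival rate.

Kaplan-Meier estimation and the log-rank statistic are delegated to
lifelines; this module owns the stratification rule, group naming and
the fixed-horizon readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "GROUP_NAMES",
    "DAYS_PER_YEAR",
    "StratificationResult",
    "stratify_patients",
    "km_estimate",
    "logrank_test",
    "five_year_rate",
    "stratify_and_test",
]

GROUP_NAMES = ("low", "intermediate", "high")
DAYS_PER_YEAR = 365.25


def stratify_patients(expr: pd.DataFrame) -> dict:
    """Three expression groups from Ward/Euclidean patient clustering.

    `expr` is a cluster-gene x patient matrix.  Each gene is z-scored
    across patients (so high-variance genes do not dominate the
    distance), patients are Ward-linked on Euclidean distance and cut at
    three clusters, and the clusters are named low / intermediate / high
    by ascending mean z-scored expression.  Fewer than three distinct
    patient profiles raise instead of silently forcing a 3-split.
    """
    if expr.shape[1] < 3:
        raise ValueError("patient stratification needs >= 3 patients")
    z = expr.sub(expr.mean(axis=1), axis=0)
    sd = expr.std(axis=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    profiles = z.to_numpy().T                      # patients x genes
    if len(np.unique(profiles, axis=0)) < 3:
        raise ValueError(
            "fewer than 3 distinct patient expression profiles; "
            "cannot form low/intermediate/high groups"
        )
    labels = fcluster(linkage(profiles, method="ward"), 3, criterion="maxclust")
    means = {c: profiles[labels == c].mean() for c in np.unique(labels)}
    order = sorted(means, key=lambda c: means[c])
    name_of = {c: GROUP_NAMES[i] for i, c in enumerate(order)}
    return {p: name_of[c] for p, c in zip(expr.columns, labels)}


def km_estimate(st: pd.DataFrame, group_members=None) -> pd.DataFrame:
    """Product-limit survival curve for a set of subjects.

    `st` is a survival table indexed by sample with columns time and
    event; `group_members` restricts to a subset (default: everyone).
    Returns a DataFrame indexed by time (starting at 0) with column "S".
    """
    if group_members is not None:
        members = [m for m in group_members]
        if not members:
            raise ValueError("empty group")
        st = st.loc[members]
    kmf = KaplanMeierFitter()
    kmf.fit(st["time"], st["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"S": sf.iloc[:, 0].to_numpy()}, index=sf.index.to_numpy())


def logrank_test(st: pd.DataFrame, groups: dict):
    """k-group log-rank test; returns (chi2, p) with k-1 df."""
    samples = [s for s in st.index if s in groups]
    if len(samples) < len(st.index):
        missing = set(st.index) - set(samples)
        raise ValueError(f"samples without a group assignment: {sorted(missing)[:5]}")
    labels = pd.Series({s: groups[s] for s in samples})
    if labels.nunique() < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    res = multivariate_logrank_test(st.loc[samples, "time"], labels,
                                    st.loc[samples, "event"])
    return float(res.test_statistic), float(res.p_value)


class FiveYearRate(NamedTuple):
    rate: float
    truncated: bool       # follow-up ended before the 5-year horizon


def five_year_rate(km_curve: pd.DataFrame, time_unit: str = "days") -> FiveYearRate:
    """KM survival probability at the 5-year horizon.

    The curve value at the last step at or before 5 years is returned;
    if follow-up ends earlier, the rate at the last observed time is
    returned with the truncation flag set.
    """
    horizon = 5.0 * (DAYS_PER_YEAR if time_unit == "days" else 1.0)
    times = np.asarray(km_curve.index, dtype=float)
    s = km_curve["S"].to_numpy()
    truncated = times.max() < horizon
    at = times[times <= horizon]
    if len(at) == 0:
        return FiveYearRate(1.0, truncated)
    return FiveYearRate(float(s[len(at) - 1]), truncated)


@dataclass
class StratificationResult:
    groups: dict                      # sample -> low/intermediate/high
    km_curves: dict                   # group -> KM DataFrame
    logrank_chi2: float
    logrank_p: float
    five_year: dict                   # group -> FiveYearRate

    def to_dict(self) -> dict:
        return {
            "groups": dict(self.groups),
            "logrank_chi2": float(self.logrank_chi2),
            "logrank_p": float(self.logrank_p),
            "five_year_rate": {g: float(r.rate) for g, r in self.five_year.items()},
            "five_year_truncated": {g: bool(r.truncated) for g, r in self.five_year.items()},
            "km_curves": {g: [[float(t), float(sv)] for t, sv in zip(c.index, c["S"])]
                          for g, c in self.km_curves.items()},
        }


def stratify_and_test(expr: pd.DataFrame, st: pd.DataFrame,
                      time_unit: str = "days") -> StratificationResult:
    """Full stratification readout for one gene cluster.

    Clusters the patients shared by `expr` (genes x patients) and the
    survival table, estimates per-group KM curves, tests group equality
    by log-rank, and extracts per-group 5-year rates.
    """
    shared = [p for p in expr.columns if p in st.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 patients with both expression and survival")
    groups = stratify_patients(expr[shared])
    stx = st.loc[shared]
    curves, rates = {}, {}
    for name in GROUP_NAMES:
        members = [p for p, g in groups.items() if g == name]
        if not members:
            continue
        curve = km_estimate(stx, members)
        curves[name] = curve
        rates[name] = five_year_rate(curve, time_unit)
    chi2, p = logrank_test(stx, groups)
    return StratificationResult(groups, curves, chi2, p, rates)
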