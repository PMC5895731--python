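"""Relative transcript quantification by the comparative Ct method.

For a target gene, the threshold cycle Ct is normalized against the
mean Ct of one or more reference genes (dCt = Ct_target - mean Ct_ref),
compared between a sample and a calibrator (ddCt = dCt_sample -
dCt_calibrator), and expressed as fold change 2^-ddCt.  This module
returns the log2 fold change (-ddCt) directly.  Amplification
efficiencies are assumed ideal (exactly 2 per cycle); no standard-curve
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CtRecord", "ddct_log2fc", "ddct_table", "elevation_test"]


@dataclass
class CtRecord:
    """Threshold cycles of one target gene in one sample."""

    sample: str
    gene: str
    ct: float
    reference_cts: dict = field(default_factory=dict)   # reference gene -> Ct

    def __post_init__(self) -> None:
        vals = [self.ct, *self.reference_cts.values()]
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError(f"{self.sample}/{self.gene}: Ct values must be "
                             "positive and finite")


def ddct_log2fc(sample: CtRecord, calibrator: CtRecord) -> float:
    """log2 fold change of `sample` vs `calibrator` (fold = 2**result).

    dCt is formed against the arithmetic mean Ct of the reference genes
    shared by both records; disjoint reference sets are an error because
    the normalizations would not be comparable.
    """
    if sample.gene != calibrator.gene:
        raise ValueError(
            f"gene mismatch: {sample.gene!r} vs {calibrator.gene!r}")
    shared = sorted(set(sample.reference_cts) & set(calibrator.reference_cts))
    if not shared:
        raise ValueError("sample and calibrator share no reference genes")
    d_sample = sample.ct - np.mean([sample.reference_cts[g] for g in shared])
    d_cal = calibrator.ct - np.mean([calibrator.reference_cts[g] for g in shared])
    return float(-(d_sample - d_cal))


def ddct_table(ct: pd.DataFrame, reference_genes, calibrator: str) -> pd.DataFrame:
    """log2 fold changes for a long-format Ct table.

    `ct` has columns sample, gene, ct; `calibrator` names the reference
    sample every other sample is compared to.  Returns a gene x sample
    DataFrame of log2 fold changes (calibrator column = 0 by identity).
    """
    reference_genes = list(reference_genes)
    wide = ct.pivot_table(index="gene", columns="sample", values="ct")
    missing_ref = [g for g in reference_genes if g not in wide.index]
    if missing_ref:
        raise ValueError(f"reference genes absent from Ct table: {missing_ref}")
    if calibrator not in wide.columns:
        raise ValueError(f"calibrator sample {calibrator!r} not in Ct table")
    targets = [g for g in wide.index if g not in reference_genes]
    out = {}
    for s in wide.columns:
        refs_s = {g: wide.loc[g, s] for g in reference_genes}
        refs_c = {g: wide.loc[g, calibrator] for g in reference_genes}
        col = {}
        for g in targets:
            if np.isnan(wide.loc[g, s]) or np.isnan(wide.loc[g, calibrator]):
                col[g] = np.nan
                continue
            col[g] = ddct_log2fc(
                CtRecord(s, g, wide.loc[g, s], refs_s),
                CtRecord(calibrator, g, wide.loc[g, calibrator], refs_c))
        out[s] = col
    return pd.DataFrame(out).loc[targets]


def elevation_test(log2fcs) -> tuple:
    """One-sided t-test that log2 fold changes exceed zero: (t, p)."""
    arr = np.asarray(list(log2fcs), dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 2:
        raise ValueError("need >= 2 finite log2 fold changes")
    res = stats.ttest_1samp(arr, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)
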