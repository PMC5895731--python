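"""Reading, validation and harmonization of per-cohort expression data.

A *cohort* is one study's log2 expression matrix (genes x samples) with a
binary tumor/non-tumor label per sample.  Cohorts from different studies
are never merged at the sample level; every downstream computation is
performed within a cohort and only rank-level summaries cross cohort
boundaries.

Inputs are assumed to be already normalized and on log2 scale; raw array
processing (background correction, quantile normalization, log transform)
is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "ProbeMatrix",
    "load_cohort",
    "load_labels",
    "load_survival_table",
    "write_cohort",
    "collapse_probes_by_iqr",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class ExpressionCohort:
    """One study's log2 expression matrix with binary class labels.

    Attributes
    ----------
    cohort_id : str
        Short identifier for the study.
    genes : np.ndarray of str
        Unique gene identifiers, ordered as in the matrix rows.
    samples : np.ndarray of str
        Unique sample identifiers, ordered as in the matrix columns.
    values : np.ndarray, shape (n_genes, n_samples)
        log2 expression values.
    y : np.ndarray of bool
        Per-sample class; ``True`` marks the positive (tumor) class.
    """

    cohort_id: str
    genes: np.ndarray
    samples: np.ndarray
    values: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=str)
        self.samples = np.asarray(self.samples, dtype=str)
        self.values = np.asarray(self.values, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError(f"{self.cohort_id}: expression matrix must be 2-D")
        ng, ns = self.values.shape
        if len(self.genes) != ng or len(self.samples) != ns or len(self.y) != ns:
            raise ValueError(
                f"{self.cohort_id}: matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes / {len(self.samples)} samples / {len(self.y)} labels"
            )
        if len(np.unique(self.genes)) != ng:
            dup = pd.Index(self.genes)[pd.Index(self.genes).duplicated()][0]
            raise ValueError(f"{self.cohort_id}: duplicate gene identifier {dup!r}")
        if len(np.unique(self.samples)) != ns:
            dup = pd.Index(self.samples)[pd.Index(self.samples).duplicated()][0]
            raise ValueError(f"{self.cohort_id}: duplicate sample identifier {dup!r}")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"{self.cohort_id}: non-finite value at gene {self.genes[g]!r}, "
                f"sample {self.samples[s]!r}"
            )
        n_pos = int(self.y.sum())
        n_neg = int((~self.y).sum())
        if n_pos < 2 or n_neg < 2:
            raise ValueError(
                f"{self.cohort_id}: need at least 2 samples per class "
                f"(got {n_pos} positive / {n_neg} negative)"
            )

    # -- convenience ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        """Per-sample class as {positive, negative} strings."""
        return np.where(self.y, POSITIVE, NEGATIVE)

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of `genes`; raises listing any missing genes."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(
                f"{self.cohort_id}: genes not in cohort: {sorted(missing)}"
            )
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset(self, genes) -> "ExpressionCohort":
        idx = self.gene_index(genes)
        return ExpressionCohort(
            cohort_id=self.cohort_id,
            genes=self.genes[idx],
            samples=self.samples.copy(),
            values=self.values[idx],
            y=self.y.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class ProbeMatrix:
    """Probe-level expression with a (possibly many-to-one) probe->gene map.

    Probes without a mapping entry (or mapped to an empty string) are
    treated as unmapped and dropped during collapsing.
    """

    probes: np.ndarray
    values: np.ndarray
    probe_to_gene: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probes = np.asarray(self.probes, dtype=str)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.probes):
            raise ValueError("probe count does not match matrix rows")


def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ValueError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            )
    return df.astype(float)


def load_labels(path: Path, positive: str = "tumor", negative: str = "normal") -> dict:
    """Two-column TSV sample_id<TAB>label -> {sample: bool(positive)}.

    Label matching is case-insensitive against the configured pair.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    out = {}
    for sample, label in zip(df["sample"], df["label"]):
        low = str(label).strip().lower()
        if low == positive.lower():
            out[sample] = True
        elif low == negative.lower():
            out[sample] = False
        else:
            raise ValueError(
                f"{path}: unknown label {label!r} for sample {sample!r} "
                f"(expected {positive!r} or {negative!r})"
            )
    return out


def load_cohort(matrix_path, labels_path, cohort_id: str | None = None,
                positive: str = "tumor", negative: str = "normal") -> ExpressionCohort:
    """Load a TSV expression matrix and its label sidecar.

    The matrix header row holds sample IDs, the first column gene IDs.
    Every sample in the matrix must appear in the labels file; gene and
    sample order is preserved from the file.
    """
    matrix_path = Path(matrix_path)
    df = _read_matrix(matrix_path)
    labels = load_labels(labels_path, positive=positive, negative=negative)
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise ValueError(
            f"{labels_path}: samples missing from labels file: {missing}"
        )
    y = np.array([labels[s] for s in df.columns], dtype=bool)
    return ExpressionCohort(
        cohort_id=cohort_id or matrix_path.stem,
        genes=df.index.to_numpy(dtype=str),
        samples=df.columns.to_numpy(dtype=str),
        values=df.to_numpy(),
        y=y,
    )


def write_cohort(cohort: ExpressionCohort, matrix_path, labels_path,
                 positive: str = "tumor", negative: str = "normal") -> None:
    """Write a cohort back to the TSV matrix + label sidecar format."""
    cohort.to_frame().to_csv(matrix_path, sep="\t", index_label="gene_id")
    lab = np.where(cohort.y, positive, negative)
    pd.DataFrame({"sample": cohort.samples, "label": lab}).to_csv(
        labels_path, sep="\t", header=False, index=False
    )


def load_survival_table(path: Path) -> pd.DataFrame:
    """Survival sidecar sample_id<TAB>time<TAB>event(0/1) -> DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["sample", "time", "event"],
                     dtype={"sample": str})
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event indicator must be 0/1")
    return df.set_index("sample")


def collapse_probes_by_iqr(pm: ProbeMatrix) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    For genes measured by several probes the probe with the largest
    inter-quartile range (Q3 - Q1, linear-interpolation quantiles) across
    samples is retained; the others are discarded.  Unmapped probes are
    dropped.  Ties in IQR are broken by file order of the probes, so the
    result is deterministic.

    Returns a gene x sample DataFrame with genes in first-appearance order.
    """
    mapped = [(i, p, pm.probe_to_gene.get(p)) for i, p in enumerate(pm.probes)]
    mapped = [(i, p, g) for i, p, g in mapped if g]
    if not mapped:
        raise ValueError("all probes are unmapped; nothing to collapse")
    q1, q3 = np.percentile(pm.values, [25, 75], axis=1)
    iqr = q3 - q1
    best: dict[str, int] = {}
    order: list[str] = []
    for i, _probe, gene in mapped:
        if gene not in best:
            best[gene] = i
            order.append(gene)
        elif iqr[i] > iqr[best[gene]]:
            best[gene] = i
    rows = np.array([best[g] for g in order], dtype=int)
    return pd.DataFrame(pm.values[rows], index=order)
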