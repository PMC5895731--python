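"""Synthetic multi-cohort expression data with known ground truth.

The generator emulates the data regime the pipeline is designed for:
several independent normalized log2 expression studies that share a set
of truly differential ("planted") genes whose effect sizes vary from
study to study, overlaid with cohort-specific batch offsets, partially
overlapping gene universes, blocks of co-expressed genes, and survival
times tied to the expression of a gene subset.  Noise is Gaussian on
the log2 scale, matching normalized microarray data; count-based noise
models and platform artifacts (probe cross-hybridization, dye effects)
are deliberately not simulated.

Every quantity is drawn from a single seeded generator, so the same
seed reproduces the data bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import ExpressionCohort

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_multicohort",
    "generate_survival",
]


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the simulator.

    Defaults describe a mid-sized multi-study microarray compendium:
    log2 baselines ~ N(7, 2), unit log2 noise, planted tumor effects of
    two log2 units on average with cross-study spread, mild batch
    offsets, four co-expression blocks, and exponential survival on a
    years scale.
    """

    n_cohorts: int = 4
    genes_per_cohort: int = 1000
    overlap_fraction: float = 0.9     # expected pairwise universe overlap
    samples_per_class: int = 30
    n_planted: int = 10
    effect_mean: float = 2.0          # log2 units, positive-class shift
    effect_sd: float = 0.5            # cross-cohort effect heterogeneity
    noise_sd: float = 1.0             # log2 units
    batch_sd: float = 0.5             # per cohort x gene offset
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    n_blocks: int = 4
    block_size: int = 15
    block_rho: float = 0.7            # within-block gene-gene correlation
    disjoint_planted: bool = False    # per-cohort private signal genes
    baseline_hazard: float = 0.1      # events per year at z = 0
    censoring_rate: float = 0.05      # exponential censoring rate per year
    survival_beta: float = 0.8        # hazard coefficient on block-1 genes

    def validate(self) -> None:
        if min(self.n_cohorts, self.genes_per_cohort, self.samples_per_class) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_forced = self.n_planted * (self.n_cohorts if self.disjoint_planted else 1)
        n_forced += self.n_blocks * self.block_size
        if n_forced > self.genes_per_cohort:
            raise ValueError("planted + block genes exceed genes_per_cohort")


@dataclass
class SyntheticTruth:
    """Ground truth backing one simulated multi-cohort dataset."""

    planted_genes: list
    effects: dict                     # cohort -> {gene: log2 effect}
    block_structure: dict             # block id -> gene list
    block_rho: float
    cohort_batch_offsets: dict        # cohort -> pd.Series gene -> shift
    survival_beta: dict               # gene -> hazard coefficient
    seed: int
    planted_per_cohort: dict = field(default_factory=dict)


def _gene_names(n: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n)])


def generate_multicohort(cfg: GeneratorConfig, seed: int = 0):
    """Draw a list of ExpressionCohorts plus their SyntheticTruth.

    Planted genes are shifted by a cohort-specific effect
    ~ N(effect_mean, effect_sd) in positive-class samples; block genes
    share a per-sample latent factor inducing pairwise correlation
    block_rho; each cohort's gene universe is a random subset of a
    common universe sized so pairwise overlap matches overlap_fraction.
    With ``disjoint_planted`` every cohort receives its own private set
    of signal genes (emulating non-transferable single-study markers).
    """
    cfg.validate()
    rng = np.random.default_rng(int(seed) % 2**31)
    universe_size = max(cfg.genes_per_cohort,
                        int(round(cfg.genes_per_cohort / cfg.overlap_fraction)))
    genes = _gene_names(universe_size)
    baseline = pd.Series(rng.normal(cfg.baseline_mean, cfg.baseline_sd, universe_size),
                         index=genes)

    # reserve planted and block genes; they appear in every cohort so that
    # cross-cohort selection and clustering have a well-defined truth
    n_priv = cfg.n_cohorts if cfg.disjoint_planted else 1
    n_reserved = cfg.n_planted * n_priv + cfg.n_blocks * cfg.block_size
    reserved = rng.choice(universe_size, size=n_reserved, replace=False)
    pos = 0
    planted_per_cohort = {}
    cohort_ids = [f"C{i + 1}" for i in range(cfg.n_cohorts)]
    if cfg.disjoint_planted:
        for cid in cohort_ids:
            planted_per_cohort[cid] = sorted(genes[reserved[pos:pos + cfg.n_planted]])
            pos += cfg.n_planted
        planted_all = sorted(g for lst in planted_per_cohort.values() for g in lst)
    else:
        shared = sorted(genes[reserved[pos:pos + cfg.n_planted]])
        pos += cfg.n_planted
        planted_per_cohort = {cid: shared for cid in cohort_ids}
        planted_all = shared
    blocks = {}
    for b in range(cfg.n_blocks):
        blocks[b + 1] = sorted(genes[reserved[pos:pos + cfg.block_size]])
        pos += cfg.block_size
    forced = np.unique(reserved)

    free = np.setdiff1d(np.arange(universe_size), forced)
    n_fill = cfg.genes_per_cohort - len(forced)
    block_of = {}
    for b, gl in blocks.items():
        for g in gl:
            block_of[g] = b

    gene_pos = {g: i for i, g in enumerate(genes)}
    cohorts = []
    effects = {}
    offsets = {}
    n = cfg.samples_per_class
    for cid in cohort_ids:
        fill = rng.choice(free, size=n_fill, replace=False)
        uni_idx = np.sort(np.concatenate([forced, fill]))
        cg = genes[uni_idx]
        ns = 2 * n
        y = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        samples = np.array([f"{cid}_T{i + 1:03d}" for i in range(n)]
                           + [f"{cid}_N{i + 1:03d}" for i in range(n)])
        batch = rng.normal(0.0, cfg.batch_sd, len(cg))
        vals = (baseline.to_numpy()[uni_idx][:, None]
                + batch[:, None]
                + rng.normal(0.0, cfg.noise_sd, (len(cg), ns)))
        # correlated blocks: shared latent factor per block and sample
        factors = rng.normal(0.0, 1.0, (cfg.n_blocks, ns))
        sq_r, sq_1mr = np.sqrt(cfg.block_rho), np.sqrt(1 - cfg.block_rho)
        row_of = {g: i for i, g in enumerate(cg)}
        for b, gl in blocks.items():
            rows = np.array([row_of[g] for g in gl])
            eps = rng.normal(0.0, 1.0, (len(rows), ns))
            noise = cfg.noise_sd * (sq_r * factors[b - 1] + sq_1mr * eps)
            vals[rows] = (baseline.to_numpy()[uni_idx][rows][:, None]
                          + batch[rows][:, None] + noise)
        eff = {}
        for g in planted_per_cohort[cid]:
            e = rng.normal(cfg.effect_mean, cfg.effect_sd)
            eff[g] = float(e)
            vals[row_of[g], y] += e
        effects[cid] = eff
        offsets[cid] = pd.Series(batch, index=cg)
        cohorts.append(ExpressionCohort(cohort_id=cid, genes=cg,
                                        samples=samples, values=vals, y=y))

    beta = {g: cfg.survival_beta for g in blocks.get(1, [])}
    truth = SyntheticTruth(
        planted_genes=planted_all,
        effects=effects,
        block_structure=blocks,
        block_rho=cfg.block_rho,
        cohort_batch_offsets=offsets,
        survival_beta=beta,
        seed=int(seed),
        planted_per_cohort=planted_per_cohort,
    )
    return cohorts, truth


def generate_survival(truth: SyntheticTruth, expr: pd.DataFrame,
                      cfg: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Exponential survival times linked to expression.

    Patient i gets hazard  lambda_i = baseline_hazard * exp(sum_g beta_g z_ig)
    over the genes carrying a nonzero coefficient in the truth (z is the
    per-gene z-score of `expr`, genes x patients).  Censoring times are
    independent exponentials with rate `censoring_rate`; a zero rate
    yields fully observed events.  Returns a DataFrame indexed by
    patient with columns time and event, matching the survival sidecar.
    """
    rng = np.random.default_rng([int(seed) % 2**31, 77])
    genes = [g for g in truth.survival_beta if g in expr.index]
    missing = set(truth.survival_beta) - set(genes)
    if missing and not genes:
        raise ValueError("no survival-linked genes present in expression matrix")
    z = expr.loc[genes]
    z = z.sub(z.mean(axis=1), axis=0).div(z.std(axis=1).replace(0, 1.0), axis=0)
    beta = np.array([truth.survival_beta[g] for g in genes])
    lam = cfg.baseline_hazard * np.exp(beta @ z.to_numpy())
    t_event = rng.exponential(1.0 / lam)
    if cfg.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=len(lam))
    else:
        t_cens = np.full(len(lam), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=expr.columns)
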