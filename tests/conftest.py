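import numpy as np
import pytest

from metaclassify.cohort_io import ExpressionCohort


def make_cohort(cohort_id="C", n_genes=20, n_per_class=10, seed=0,
                planted=(), effect=3.0, noise_sd=1.0):
    """Small hand-rolled cohort: Gaussian noise plus optional planted shift."""
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:03d}" for i in range(n_genes)])
    n = 2 * n_per_class
    y = np.concatenate([np.ones(n_per_class, bool), np.zeros(n_per_class, bool)])
    vals = 7.0 + rng.normal(0, noise_sd, (n_genes, n))
    for gi in planted:
        vals[gi, y] += effect
    samples = np.array([f"{cohort_id}s{i:03d}" for i in range(n)])
    return ExpressionCohort(cohort_id=cohort_id, genes=genes, samples=samples,
                            values=vals, y=y)


@pytest.fixture
def noise_cohort():
    return make_cohort("noise", n_genes=30, n_per_class=15, seed=11)


@pytest.fixture
def separable_cohort():
    return make_cohort("sep", n_genes=10, n_per_class=10, seed=5,
                       planted=(0, 1), effect=10.0, noise_sd=0.3)
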