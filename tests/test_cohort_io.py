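import numpy as np
import pandas as pd
import pytest

from metaclassify.cohort_io import (ExpressionCohort, ProbeMatrix,
                                    collapse_probes_by_iqr, load_cohort,
                                    load_survival_table, write_cohort)
from metaclassify.synthetic import GeneratorConfig, generate_multicohort

MATRIX = "gene_id\ts1\ts2\ts3\ts4\ng1\t1.0\t2.0\t3.0\t4.0\ng2\t5\t6\t7\t8\ng3\t0.1\t0.2\t0.3\t0.4\n"
LABELS = "s1\ttumor\ns2\tTumor\ns3\tnormal\ns4\tNORMAL\n"


def _write(tmp_path, matrix=MATRIX, labels=LABELS):
    mp = tmp_path / "m.tsv"
    lp = tmp_path / "m.labels.tsv"
    mp.write_text(matrix)
    lp.write_text(labels)
    return mp, lp


def test_load_cohort_round_trip_small(tmp_path):
    mp, lp = _write(tmp_path)
    c = load_cohort(mp, lp)
    assert c.values.shape == (3, 4)
    assert list(c.genes) == ["g1", "g2", "g3"]
    assert list(c.samples) == ["s1", "s2", "s3", "s4"]
    # case-insensitive labels, order preserved
    assert c.y.tolist() == [True, True, False, False]


def test_missing_label_names_sample(tmp_path):
    mp, lp = _write(tmp_path, labels="s1\ttumor\ns2\ttumor\ns3\tnormal\n")
    with pytest.raises(ValueError, match="s4"):
        load_cohort(mp, lp)


def test_duplicate_gene_rejected(tmp_path):
    bad = MATRIX.replace("g3", "g1")
    mp, lp = _write(tmp_path, matrix=bad)
    with pytest.raises(ValueError, match="g1"):
        load_cohort(mp, lp)


def test_non_numeric_cell_names_row_and_column(tmp_path):
    bad = MATRIX.replace("7", "seven")
    mp, lp = _write(tmp_path, matrix=bad)
    with pytest.raises(ValueError) as exc:
        load_cohort(mp, lp)
    assert "g2" in str(exc.value) and "s3" in str(exc.value)


def test_write_then_load_synthetic_cohort_identical(tmp_path):
    cohorts, _ = generate_multicohort(
        GeneratorConfig(n_cohorts=1, genes_per_cohort=80, samples_per_class=5,
                        n_planted=3, n_blocks=1, block_size=5), seed=4)
    c = cohorts[0]
    write_cohort(c, tmp_path / "c.tsv", tmp_path / "c.labels.tsv")
    back = load_cohort(tmp_path / "c.tsv", tmp_path / "c.labels.tsv")
    assert list(back.genes) == list(c.genes)
    assert list(back.samples) == list(c.samples)
    np.testing.assert_allclose(back.values, c.values, atol=1e-9)
    assert (back.y == c.y).all()


def test_cohort_invariants_enforced():
    with pytest.raises(ValueError, match="2 samples per class"):
        ExpressionCohort("x", ["g1"], ["a", "b", "c"],
                         np.zeros((1, 3)), [True, False, False])
    with pytest.raises(ValueError, match="non-finite"):
        ExpressionCohort("x", ["g1"], ["a", "b", "c", "d"],
                         np.array([[1.0, np.nan, 2.0, 3.0]]),
                         [True, True, False, False])


def test_survival_sidecar(tmp_path):
    p = tmp_path / "s.tsv"
    p.write_text("a\t10\t1\nb\t20.5\t0\n")
    st = load_survival_table(p)
    assert st.loc["b", "time"] == 20.5
    assert st.loc["a", "event"] == 1
    p.write_text("a\t-1\t1\n")
    with pytest.raises(ValueError, match="negative"):
        load_survival_table(p)


# -- probe collapsing --------------------------------------------------

def test_collapse_keeps_largest_iqr_probe():
    pm = ProbeMatrix(
        probes=["p1", "p2"],
        values=np.array([[0.0, 2.0, 4.0, 6.0], [1.0, 1.0, 1.0, 1.0]]),
        probe_to_gene={"p1": "G", "p2": "G"},
    )
    out = collapse_probes_by_iqr(pm)
    assert list(out.index) == ["G"]
    np.testing.assert_array_equal(out.loc["G"].to_numpy(), [0.0, 2.0, 4.0, 6.0])


def test_collapse_identity_when_one_probe_per_gene():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(5, 6))
    pm = ProbeMatrix(probes=[f"p{i}" for i in range(5)], values=vals,
                     probe_to_gene={f"p{i}": f"g{i}" for i in range(5)})
    out = collapse_probes_by_iqr(pm)
    np.testing.assert_allclose(out.to_numpy(), vals)


def test_collapse_matches_brute_force_scan():
    rng = np.random.default_rng(7)
    n_probes, n_genes = 50, 20
    vals = rng.normal(size=(n_probes, 8))
    mapping = {f"p{i}": f"g{rng.integers(n_genes)}" for i in range(n_probes)}
    pm = ProbeMatrix(probes=[f"p{i}" for i in range(n_probes)], values=vals,
                     probe_to_gene=mapping)
    out = collapse_probes_by_iqr(pm)

    def iqr(v):
        q1, q3 = np.percentile(v, [25, 75])
        return q3 - q1

    for gene in out.index:
        rows = [i for i in range(n_probes) if mapping[f"p{i}"] == gene]
        best = max(rows, key=lambda i: (iqr(vals[i]), -i))
        np.testing.assert_allclose(out.loc[gene].to_numpy(), vals[best])
    assert len(out) == len(set(mapping.values()))


def test_collapse_idempotent():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(6, 5))
    pm = ProbeMatrix(probes=[f"g{i}" for i in range(6)], values=vals,
                     probe_to_gene={f"g{i}": f"g{i}" for i in range(6)})
    once = collapse_probes_by_iqr(pm)
    pm2 = ProbeMatrix(probes=list(once.index), values=once.to_numpy(),
                      probe_to_gene={g: g for g in once.index})
    twice = collapse_probes_by_iqr(pm2)
    pd.testing.assert_frame_equal(once, twice)


def test_collapse_all_unmapped_errors():
    pm = ProbeMatrix(probes=["p1"], values=np.ones((1, 4)), probe_to_gene={})
    with pytest.raises(ValueError, match="unmapped"):
        collapse_probes_by_iqr(pm)
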