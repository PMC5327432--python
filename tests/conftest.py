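import numpy as np
import pytest

import acscreen as ac


def study_spec(seed: int, de_fraction: float = 0.05) -> ac.SimulationSpec:
    """The validation-scale generator settings: 5,000 genes, four 1e6
    libraries, every gene's baseline expected count >= ~100, a 4-fold
    planted effect, Poisson noise."""
    return ac.SimulationSpec(
        n_genes=5000,
        library_totals=(1_000_000,) * 4,
        length_law=(2000.0, 2000.0),
        baseline_law=(np.log(100.0), 0.2),
        de_fraction=de_fraction,
        effect_log2=2.0,
        seed=seed,
    )


GROUPS = ac.ScreenConfig(group_a=("A1", "A2"), group_b=("B1", "B2"))


def run_screen(table, config=GROUPS):
    expr = ac.compute_fpkm(table)
    results = {pair: ac.test_pair(table, expr, *pair) for pair in config.pairs}
    return expr, results, ac.consensus_screen(results, config)


@pytest.fixture(scope="session")
def study_run():
    """One full pipeline run under the validation-scale settings."""
    table, truth = ac.simulate_counts(study_spec(seed=1))
    expr, results, calls = run_screen(table)
    return {
        "table": table,
        "truth": truth,
        "expr": expr,
        "results": results,
        "calls": calls,
        "metrics": ac.evaluate_recovery(calls, truth),
    }


@pytest.fixture(scope="session")
def null_pvalues():
    """Exact-test p-values for 10,000 null genes: both counts Poisson with
    rates proportional to unequal library sizes (no true effect)."""
    rng = np.random.default_rng(20)
    n1, n2 = 1_000_000, 2_000_000
    base = rng.lognormal(np.log(80.0), 0.6, size=10_000)
    x = rng.poisson(base)
    y = rng.poisson(base * (n2 / n1))
    return np.array(
        [ac.ac_pvalue(int(a), int(b), n1, n2) for a, b in zip(x, y)]
    )


@pytest.fixture
def tiny_tables(tmp_path):
    """Write the 3-gene, 2-sample TSV trio used by the I/O tests."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene_id\ts1\ts2\n"
        "g1\t5\t0\n"
        "g2\t0\t0\n"
        "g3\t10\t7\n"
    )
    lengths = tmp_path / "lengths.tsv"
    lengths.write_text(
        "gene_id\tlength_bases\ng1\t1000\ng2\t500\ng3\t2000\n"
    )
    totals = tmp_path / "totals.tsv"
    totals.write_text("sample_id\ttotal_fragments\ns1\t1000\ns2\t1000\n")
    return {"counts": counts, "lengths": lengths, "totals": totals,
            "dir": tmp_path}
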