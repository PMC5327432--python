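"""Full screen on a synthetic four-library dataset with planted effects.

Generates counts for 2,000 genes in two groups of two single-replicate
libraries, with 5% of genes planted at a 4-fold shift, then runs
FPKM -> exact test -> BH FDR -> consensus screen and scores the calls
against the planted truth.
"""

import numpy as np

import acscreen as ac

spec = ac.SimulationSpec(
    n_genes=2000,
    length_law=(2000.0, 2000.0),
    baseline_law=(np.log(100.0), 0.2),  # baseline counts ~90-300
    de_fraction=0.05,
    effect_log2=2.0,                    # planted 4-fold shift
    seed=11,
)
table, truth = ac.simulate_counts(spec)
print(f"simulated {spec.n_genes} genes, realized library sizes "
      f"{table.totals.tolist()}")

expr = ac.compute_fpkm(table)
config = ac.ScreenConfig(group_a=("A1", "A2"), group_b=("B1", "B2"))
results = {pair: ac.test_pair(table, expr, *pair) for pair in config.pairs}
calls = ac.consensus_screen(results, config)

a_high, b_high, uncalled = ac.count_directions(calls)
print(f"calls: {a_high} A-high, {b_high} B-high, {uncalled} uncalled")

m = ac.evaluate_recovery(calls, truth)
print(f"sensitivity {m.sensitivity:.3f}  (of {m.n_planted} planted genes)")
print(f"false discovery proportion {m.fdp:.3f}  (of {m.n_called} calls)")
# With >=90 expected fragments per gene and a 4-fold effect the screen
# recovers essentially all planted genes with no false calls: the
# thresholds (2-fold in all four comparisons, FDR <= 0.001) are strict.
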