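# Methods

## The statistical model

Each library is a pool of *N* uniquely aligned fragments. For a transcript
taking a small fraction of the pool, its fragment count is well
approximated as Poisson. Comparing one gene across two libraries with
totals *N1*, *N2* and counts *x*, *y*, the test conditions on *x*: under
equal expression per fragment, the count in library 2 follows

p(i|x) = (N2/N1)^i (x+i)! / (x! i!) (1+N2/N1)^-(x+i+1),

which is exactly the negative-binomial distribution with r = x+1
successes and success probability N1/(N1+N2), evaluated at i failures
(the marginal of a Gamma(x+1)-mixed Poisson — i.e. the posterior
predictive of library 2's count under a flat prior on the common rate).
The two-sided p-value is the doubled smaller tail, capped at 1; the tail
containing y is chosen by comparing the per-fragment rates x/N1 and y/N2.
An alternative two-sided construction (summing all outcomes with
probability ≤ the observed one) would fit behind the same interface; the
doubled-tail form is the standard one for this family and is what the
package implements.

Assumptions worth stating plainly: one library per condition means
biological variability is not modelled at all. The Poisson assumption
makes the test anti-conservative whenever true biological dispersion
exceeds shot noise — which it essentially always does between biological
replicates. The screen therefore treats p-values as a ranking/filtering
device, not calibrated inference; the consensus requirement across two
independent strains per genotype is the design's substitute for
replication.

## Numerical evaluation of the exact test

The point mass is evaluated in the negative-binomial form
log C(x+i, i) + i·log q + (x+1)·log p. A naive lgamma-difference
evaluation loses ~5 significant digits by cancellation once x+i is large;
instead, the binomial coefficient is summed as Σ log over the smaller
index in 80-bit extended precision whenever min(x, i) ≤ 20,000 (relative
error ~1e-15 against 60-digit arithmetic), falling back to lgamma beyond
that, where relative error ~1e-10 is irrelevant to any screening
decision. Tail sums run chunk-wise in log space (logsumexp), moving away
from the distribution's mode, and terminate once a chunk's largest term
falls 50 nats below the running sum or underflows; when the requested
tail contains the mode (mass ≥ ~1/2) the complement of the opposite tail
is used instead. This keeps p-values exact to double precision at counts
of order 10^6–10^7 without special-function shortcuts.

Benjamini–Hochberg is the standard step-up: q(k) = min over j ≥ k of
m·p(j)/j, capped at 1, mapped back to input order; it is applied within
each pairwise comparison's full gene list, not pooled across the four
comparisons — the test is defined "between two samples", and pooling
would couple comparisons that the design treats as independent screens.

## FPKM

FPKM = 10^9·C/(N·L). By default N is the column sum of the supplied
table (complete-table assumption); a totals sidecar overrides this for
subset tables, since whether N counts fragments mapped to the full
assembly or to the tabulated subset is a choice the data provider has to
make. Zero counts give FPKM exactly 0, which the screen's zero-expression
rule depends on. Reports round FPKM and folds to 2 decimals; all internal
computation is full precision — the bundled published table shows why
rounding inputs matters: fold values recomputed from 2-decimal FPKM
inputs reproduce the printed cells exactly for well-expressed genes but
drift by up to ~0.8 log2 units when the denominator is printed as 0.01.

## The consensus screen

A gene is A-high iff every a-vs-b comparison (|group A| × |group B| of
them, four in the standard 2×2 design) satisfies: log2 fold ≥ 1 (2-fold),
or fold = +inf under the zero rule; and q ≤ 0.001 in every comparison
where both counts are positive. B-high symmetrically. The FDR gate is
waived for zero-count comparisons because the exact test has no power
there while the on/off pattern itself is the evidence. Mixed-sign
infinite folds leave a gene uncalled: consensus means agreement. Genes
with no expression anywhere are uncalled. The threshold pair
(2-fold, FDR ≤ 0.001) is the screen's default and deliberately strict;
both are configurable.

The "at least 2-fold between the two Red strains compared to the two
White strains" criterion is implemented as *all four* pairwise
comparisons rather than a group-mean ratio: the published gene tables
print exactly the four pairwise fold columns and every printed value
clears the threshold, which is what the all-pairs reading predicts.

## The synthetic generator

The generator emulates the four-library, single-replicate design: gene
lengths log-uniform on [200, 10,000] bases; baseline per-gene FPKM
log-normal (default median 80, σ = 0.5 in natural log); a `de_fraction`
of genes (default 5%) shifted in the high group by a factor
2^`effect_log2` (default 2.0, i.e. 4-fold — the high group moves up, the
low group stays at baseline, so the planted log2 ratio equals
`effect_log2`); 90% of planted genes A-high by default, mirroring the
strong asymmetry such screens can produce. Expected counts are
FPKM·N·L/10^9 with target depths N = 10^6; the defaults are calibrated so
the expected realized library size matches the target (the generator is
self-consistent) and a typical gene receives ~100–240 fragments. Counts
are Poisson by default; a negative-binomial mode (Var = μ + φμ²) exists
to demonstrate — not repair — the anti-conservativeness of the
no-replicate Poisson test under overdispersion. Each sample draws from
its own PCG64 stream keyed (seed, sample index, replicate), so adding
samples or re-drawing noise never perturbs existing columns, and gene-
level quantities come from a separate stream.

What the generator does not emulate: isoform structure, positional or GC
bias, mapping ambiguity, library-preparation batch effects, and — under
the Poisson default — biological dispersion. Passing recovery tests
therefore shows the pipeline implements its stated method correctly, not
that the method's error rates transfer to real between-organism
comparisons.

## Validation-scale choices

The recovery benchmark uses 5,000 genes, four 10^6-fragment libraries,
fixed 2,000-base lengths and baseline FPKM log-normal(ln 100, 0.2), which
puts every gene's baseline expectation at ≥ ~93 counts; with a 4-fold
planted effect the screen attains sensitivity 1.0 and FDP 0 across seeds.
Under the broader desk-scale defaults (length and expression spread as
above), sensitivity is ~0.95–0.98: the loss is concentrated in the ~2% of
genes whose baseline expectation falls below ~10 fragments, where the
q ≤ 0.001 consensus cannot be met — the expected behaviour of the method,
not an implementation artifact. Null calibration uses 10,000 genes at a
2:1 depth ratio; empirical fractions at α ∈ {0.05, 0.01, 0.001} sit at or
just below nominal (the doubled-tail construction is mildly conservative
at small counts). The null-screen control repeats the full pipeline on 20
effect-free simulations and requires silence in at least 19.

## Known limitations

- No replicate handling, by design: this reproduces a screening method,
  with its inaccuracies, rather than improving on it (use a
  dispersion-aware model for inference).
- FDR is controlled per comparison; the consensus intersection of four
  gated comparisons has no single controlled error rate.
- The zero-expression rule admits genes on a 0-vs-low pattern without a
  significance gate; at very shallow depth this admits noise (the
  published tables show such rows with denominators of 0.01–0.02 FPKM).
- Report rounding is cosmetic only, but round-tripping a report through
  reading code will not recover full-precision folds.
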