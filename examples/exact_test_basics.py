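"""The two-library exact test on raw counts.

Computes the conditional point mass p(i|x) and two-sided p-values for a
few count pairs at different library depths, showing how depth imbalance
enters the test without any explicit normalization step.
"""

from acscreen import ac_probability, ac_pvalue

# With equal libraries and no counts at all there is no evidence either
# way: the point mass at zero is 1/2 and the p-value is 1.
print("p(0|0), equal depths:   ", ac_probability(0, 0, 1_000_000, 1_000_000))
print("p-value x=0, y=0:       ", ac_pvalue(0, 0, 1_000_000, 1_000_000))

# 20 vs 60 fragments at equal depth: a 3-fold difference backed by few
# fragments is already convincing.
print("p-value x=20, y=60:     ", ac_pvalue(20, 60, 1_000_000, 1_000_000))

# The same counts with the second library sequenced 3x deeper: now 60
# fragments is exactly what equal expression predicts.
print("p-value, 3x deeper lib2:", ac_pvalue(20, 60, 1_000_000, 3_000_000))

# Counts of order 10^5 with a 1% rate difference: tiny effects become
# detectable at depth (this is a screen, not an effect-size filter).
print("p-value x=100000, y=101000:",
      ac_pvalue(100_000, 101_000, 10_000_000, 10_000_000))
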