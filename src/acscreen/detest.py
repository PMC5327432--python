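"""Exact test for equal expression of a gene between two count libraries.

For a transcript taking a small fraction of each library, the fragment
count is modelled as Poisson.  Conditional on ``x`` fragments in library 1
(total N1), the count ``i`` in library 2 (total N2) under equal expression
follows

    p(i | x) = (N2/N1)^i * (x+i)! / (x! i!) / (1 + N2/N1)^(x+i+1),

which is the negative-binomial law with ``x+1`` successes and success
probability N1/(N1+N2), evaluated at ``i`` failures.  The two-sided
p-value doubles the smaller tail of this distribution (capped at 1), the
tail being chosen by comparing the per-fragment rates x/N1 and y/N2.
Everything is evaluated in log space so counts of order 10^7 are safe.

No replicates, no dispersion: this is the classical two-library digital
expression test, suitable for screening, not inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .expression import ExpressionMatrix
from .tables_io import CountTable

__all__ = [
    "ac_probability",
    "ac_pvalue",
    "bh_fdr",
    "test_pair",
    "PairwiseDEResult",
    "UNDEFINED",
]

#: Sentinel log2 fold where both FPKM values are 0 (ratio undefined).
UNDEFINED = float("nan")

# Stop extending a tail window once a chunk's largest term is this many
# nats below the running tail (relative contribution < ~2e-22) or once
# terms underflow double precision entirely.
_LOG_REL_STOP = 50.0
_LOG_ABS_STOP = -745.0
_CHUNK = 512


def _log_pmf(x: int, i: np.ndarray, log_ratio: float, log1p_ratio: float) -> np.ndarray:
    """log p(i|x) for an array of i, with ratio = N2/N1 precomputed in logs."""
    i = np.asarray(i, dtype=np.float64)
    return (
        i * log_ratio
        + gammaln(x + i + 1.0)
        - gammaln(x + 1.0)
        - gammaln(i + 1.0)
        - (x + i + 1.0) * log1p_ratio
    )


def ac_probability(x: int, i: int, n1: int, n2: int) -> float:
    """p(i|x): probability of i fragments in library 2 given x in library 1
    under equal expression, for library totals n1 and n2.

    Evaluated in the negative-binomial form log C(x+i, i) + i*log q +
    (x+1)*log p with q = N2/(N1+N2), p = N1/(N1+N2).  The binomial term is
    summed directly over the smaller index in extended precision, which
    avoids the cancellation a plain lgamma difference suffers once x + i
    is large; beyond that regime the lgamma form takes over."""
    if x < 0 or i < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    ld = np.longdouble
    a, b = (x, i) if x <= i else (i, x)
    if a <= 20_000:
        log_binom = (
            np.log(np.arange(b + 1, b + a + 1, dtype=ld)).sum()
            - np.log(np.arange(2, a + 1, dtype=ld)).sum()
        )
    else:
        log_binom = ld(gammaln(x + i + 1.0) - gammaln(x + 1.0)
                       - gammaln(i + 1.0))
    denom = ld(n1) + ld(n2)
    log_q = np.log(ld(n2) / denom)
    log_p = np.log(ld(n1) / denom)
    return float(np.exp(log_binom + ld(i) * log_q + ld(x + 1) * log_p))


def _sum_tail(x: int, start: int, log_ratio: float, log1p_ratio: float,
              step: int) -> float:
    """Σ p(i|x) from ``start`` moving away from the mode in direction ``step``
    (+1: upward to infinity; -1: downward to 0), in log space with early
    termination once further terms cannot affect the double-precision sum."""
    log_total = -np.inf
    lo = start
    while True:
        if step > 0:
            block = np.arange(lo, lo + _CHUNK)
        else:
            if lo < 0:
                break
            block = np.arange(max(0, lo - _CHUNK + 1), lo + 1)
        logp = _log_pmf(x, block, log_ratio, log1p_ratio)
        log_total = np.logaddexp(log_total, logsumexp(logp))
        peak = logp.max()
        if peak < _LOG_ABS_STOP or peak < log_total - _LOG_REL_STOP:
            break
        if step > 0:
            lo += _CHUNK
        else:
            lo -= _CHUNK
            if lo < 0 and block[0] == 0:
                break
    return float(np.exp(log_total))


def _upper_tail(x: int, y: int, log_ratio: float, log1p_ratio: float,
                mean: float) -> float:
    """P(I >= y) under p(.|x)."""
    if y <= 0:
        return 1.0
    if y <= mean:
        # the direct sum would cover at least half the mass; use the
        # complement of the (small) opposite tail
        return max(0.0, 1.0 - _sum_tail(x, y - 1, log_ratio, log1p_ratio, -1))
    return _sum_tail(x, y, log_ratio, log1p_ratio, +1)


def _lower_tail(x: int, y: int, log_ratio: float, log1p_ratio: float,
                mean: float) -> float:
    """P(I <= y) under p(.|x)."""
    if y < 0:
        return 0.0
    if y >= mean:
        return max(0.0, 1.0 - _sum_tail(x, y + 1, log_ratio, log1p_ratio, +1))
    return _sum_tail(x, y, log_ratio, log1p_ratio, -1)


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided p-value for equal expression given counts x (library 1,
    total n1) and y (library 2, total n2).

    The tail containing y is summed — the upper tail when y's per-fragment
    rate is at least x's, the lower tail otherwise — then doubled and
    capped at 1.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    log_ratio = math.log(n2) - math.log(n1)
    log1p_ratio = math.log1p(n2 / n1)
    mean = (x + 1.0) * (n2 / n1)
    if y * n1 >= x * n2:  # y/n2 >= x/n1 without division
        tail = _upper_tail(x, y, log_ratio, log1p_ratio, mean)
    else:
        tail = _lower_tail(x, y, log_ratio, log1p_ratio, mean)
    return min(1.0, 2.0 * tail)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    q_(k) = min_{j >= k} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        bad = p[np.isnan(p) | (p < 0) | (p > 1)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass
class PairwiseDEResult:
    """Per-gene outcome of one two-library comparison (a vs b)."""

    gene_id: str
    sample_a: str
    sample_b: str
    x: int          # count in sample_a
    y: int          # count in sample_b
    n1: int         # total fragments, sample_a
    n2: int         # total fragments, sample_b
    p_value: float
    q_value: float
    log2_fold: float  # log2(FPKM_a/FPKM_b); +/-inf one-sided zero; nan both zero

    @property
    def fold_undefined(self) -> bool:
        return math.isnan(self.log2_fold)


def _log2_fold(fpkm_a: float, fpkm_b: float) -> float:
    if fpkm_a == 0.0 and fpkm_b == 0.0:
        return UNDEFINED
    if fpkm_b == 0.0:
        return math.inf
    if fpkm_a == 0.0:
        return -math.inf
    return math.log2(fpkm_a / fpkm_b)


def test_pair(
    table: CountTable,
    expr: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
) -> list[PairwiseDEResult]:
    """Run the exact test for every gene between two samples of a table.

    q-values come from BH over this comparison's full gene list; the
    log2 fold is oriented a over b.
    """
    ia, ib = table.sample_index(sample_a), table.sample_index(sample_b)
    n1 = int(table.totals[ia])
    n2 = int(table.totals[ib])
    xs = table.counts[:, ia]
    ys = table.counts[:, ib]
    fa = expr.sample_column(sample_a)
    fb = expr.sample_column(sample_b)

    pvals = np.array(
        [ac_pvalue(int(x), int(y), n1, n2) for x, y in zip(xs, ys)]
    )
    qvals = bh_fdr(pvals)

    return [
        PairwiseDEResult(
            gene_id=gid,
            sample_a=sample_a,
            sample_b=sample_b,
            x=int(xs[i]),
            y=int(ys[i]),
            n1=n1,
            n2=n2,
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
            log2_fold=_log2_fold(float(fa[i]), float(fb[i])),
        )
        for i, gid in enumerate(table.gene_ids)
    ]


def results_to_frame(results: list[PairwiseDEResult]):
    """Flatten pairwise results to a DataFrame (q-value column named FDR)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "sample_a": [r.sample_a for r in results],
            "sample_b": [r.sample_b for r in results],
            "count_a": [r.x for r in results],
            "count_b": [r.y for r in results],
            "p_value": [r.p_value for r in results],
            "FDR": [r.q_value for r in results],
            "log2_fold": [r.log2_fold for r in results],
        }
    )
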