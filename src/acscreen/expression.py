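"""Fragment counts to FPKM.

FPKM(A) = 10^9 * C / (N * L): C fragments uniquely aligned to gene A in a
library of N total aligned fragments, gene length L bases.  A within-sample
unit — no inter-sample normalization is applied, matching screens that
compare FPKM directly across single-replicate libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables_io import CountTable

__all__ = ["ExpressionMatrix", "compute_fpkm"]


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM values, ordered as the source CountTable."""

    genes: list[str]
    samples: list[str]
    fpkm: np.ndarray

    def sample_column(self, sample: str) -> np.ndarray:
        try:
            return self.fpkm[:, self.samples.index(sample)]
        except ValueError:
            raise KeyError(f"unknown sample id {sample!r}") from None


def compute_fpkm(table: CountTable) -> ExpressionMatrix:
    """FPKM for every gene and sample of a CountTable.

    Scale-invariant in sequencing depth (multiplying counts and totals by
    the same factor leaves FPKM unchanged) and exactly 0 where the count
    is 0.
    """
    zero = np.flatnonzero(np.asarray(table.totals) == 0)
    if zero.size:
        raise ValueError(
            f"sample {table.samples[zero[0]]!r} has zero total fragments"
        )
    lengths = table.lengths.astype(float)
    totals = table.totals.astype(float)
    fpkm = 1e9 * table.counts / (totals[np.newaxis, :] * lengths[:, np.newaxis])
    return ExpressionMatrix(genes=table.gene_ids, samples=list(table.samples), fpkm=fpkm)
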