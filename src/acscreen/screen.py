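"""Consensus fold-change screen across all group-A x group-B comparisons.

A gene is called A-high only when every pairwise comparison of an A sample
against a B sample agrees: log2 fold at or above the threshold (or an
infinite fold under the zero-expression rule) and, wherever both counts
are positive so the exact test applies, FDR at or below the cut.  The
zero-expression rule admits genes whose FPKM is exactly 0 in one group —
their ratio is uncomputable but the on/off pattern is itself evidence.
Genes with no expression anywhere, or with comparisons disagreeing in
direction, stay uncalled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .detest import PairwiseDEResult

__all__ = [
    "ScreenConfig",
    "GeneCall",
    "consensus_screen",
    "count_directions",
    "A_HIGH",
    "B_HIGH",
    "UNCALLED",
]

A_HIGH = "A_HIGH"
B_HIGH = "B_HIGH"
UNCALLED = "UNCALLED"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and group membership for the consensus screen.

    Defaults encode a 2-fold ratio (1.0 on the log2 scale) at FDR <= 0.001
    with the zero-expression rule switched on.
    """

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    min_abs_log2_fold: float = 1.0
    max_fdr: float = 0.001
    include_zero_rule: bool = True

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")
        if self.min_abs_log2_fold <= 0:
            raise ValueError("min_abs_log2_fold must be > 0")
        if not (0 < self.max_fdr < 1):
            raise ValueError("max_fdr must lie in (0, 1)")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a in self.group_a for b in self.group_b]


@dataclass
class GeneCall:
    """Direction call for one gene, with the per-comparison evidence."""

    gene_id: str
    direction: str
    folds: dict[tuple[str, str], float]    # a-over-b log2 fold per comparison
    q_values: dict[tuple[str, str], float]
    zero_rule_applied: bool = False


def _passes(fold: float, q: float, both_positive: bool, cfg: ScreenConfig,
            sign: int) -> bool:
    """One comparison's contribution to an A_HIGH (sign=+1) or B_HIGH
    (sign=-1) consensus."""
    if math.isnan(fold):
        return False
    inf_ok = cfg.include_zero_rule and math.isinf(fold) and (
        (sign > 0 and fold > 0) or (sign < 0 and fold < 0)
    )
    if math.isinf(fold):
        return inf_ok  # FDR gate waived: the ratio is untestable
    if sign > 0 and fold < cfg.min_abs_log2_fold:
        return False
    if sign < 0 and fold > -cfg.min_abs_log2_fold:
        return False
    if both_positive and q > cfg.max_fdr:
        return False
    return True


def consensus_screen(
    results: Mapping[tuple[str, str], Sequence[PairwiseDEResult]],
    config: ScreenConfig,
) -> list[GeneCall]:
    """Classify every gene as A_HIGH, B_HIGH or UNCALLED.

    ``results`` maps each (a, b) pair of the config to that comparison's
    per-gene test results; all comparisons must cover the same gene set.
    """
    expected = set(config.pairs)
    if set(results) != expected:
        raise ValueError(
            f"comparisons {sorted(set(results) ^ expected)} missing or extra"
        )

    by_pair: dict[tuple[str, str], dict[str, PairwiseDEResult]] = {}
    universe: list[str] | None = None
    for pair in config.pairs:
        lookup = {r.gene_id: r for r in results[pair]}
        if universe is None:
            universe = [r.gene_id for r in results[pair]]
        elif set(lookup) != set(universe):
            diff = sorted(set(lookup) ^ set(universe))
            raise ValueError(f"gene sets differ between comparisons: {diff}")
        by_pair[pair] = lookup

    calls: list[GeneCall] = []
    for gid in universe or []:
        folds: dict[tuple[str, str], float] = {}
        qs: dict[tuple[str, str], float] = {}
        a_ok = b_ok = True
        used_inf = False
        all_undefined = True
        for pair in config.pairs:
            r = by_pair[pair][gid]
            folds[pair] = r.log2_fold
            qs[pair] = r.q_value
            both_positive = r.x > 0 and r.y > 0
            if not math.isnan(r.log2_fold):
                all_undefined = False
            a_ok = a_ok and _passes(r.log2_fold, r.q_value, both_positive,
                                    config, +1)
            b_ok = b_ok and _passes(r.log2_fold, r.q_value, both_positive,
                                    config, -1)
            if math.isinf(r.log2_fold):
                used_inf = True

        if all_undefined or (not a_ok and not b_ok):
            direction = UNCALLED
        elif a_ok:
            direction = A_HIGH
        else:
            direction = B_HIGH
        zero_rule = (
            direction != UNCALLED and used_inf and config.include_zero_rule
        )
        calls.append(GeneCall(gid, direction, folds, qs, zero_rule))
    return calls


def count_directions(calls: Sequence[GeneCall]) -> tuple[int, int, int]:
    """Tally (a_high, b_high, uncalled); the three always sum to len(calls)."""
    a = sum(1 for c in calls if c.direction == A_HIGH)
    b = sum(1 for c in calls if c.direction == B_HIGH)
    return a, b, len(calls) - a - b
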