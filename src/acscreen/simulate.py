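"""Synthetic four-library count datasets with planted differential expression.

Emulates the two-genotype, two-strains-per-genotype, one-library-per-strain
design (samples A1, A2 vs B1, B2 by default): per-gene lengths drawn
log-uniformly, baseline expression (FPKM) log-normally, a chosen fraction
of genes planted with a group-wise log2 shift, and fragment counts drawn
per library from Poisson (or negative-binomial, to expose the
overdispersion sensitivity of no-replicate Poisson tests) around

    E[count] = FPKM * N * L / 1e9.

Each sample consumes its own random stream derived from the master seed,
so adding a sample never perturbs the counts of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .screen import A_HIGH, B_HIGH, UNCALLED, GeneCall
from .tables_io import CountTable, GeneRecord

__all__ = [
    "SimulationSpec",
    "TruthTable",
    "RecoveryMetrics",
    "simulate_counts",
    "evaluate_recovery",
]

NONE = "NONE"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the generator.

    ``library_totals`` are target depths; realized totals are the column
    sums of the drawn counts.  ``baseline_law`` is (mu, sigma) of the
    natural-log normal for per-gene FPKM; ``length_law`` gives log-uniform
    bounds in bases.  ``effect_log2`` multiplies the high group's FPKM by
    2**effect_log2, so it equals the true between-group log2 ratio.
    ``direction_mix`` is the share of planted genes that are A-high.
    """

    n_genes: int = 5000
    library_totals: tuple[int, int, int, int] = (
        1_000_000, 1_000_000, 1_000_000, 1_000_000,
    )
    sample_names: tuple[str, str, str, str] = ("A1", "A2", "B1", "B2")
    group_a: tuple[str, ...] = ("A1", "A2")
    group_b: tuple[str, ...] = ("B1", "B2")
    length_law: tuple[float, float] = (200.0, 10_000.0)
    baseline_law: tuple[float, float] = (np.log(80.0), 0.5)
    de_fraction: float = 0.05
    effect_log2: float = 2.0
    direction_mix: float = 0.9
    noise_family: str = "POISSON"          # or NEGATIVE_BINOMIAL
    dispersion: float = 0.1                # NB: Var = mu + dispersion*mu^2
    seed: int = 0
    replicate: int = 0                     # re-draws counts, keeps genes fixed

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.library_totals) != len(self.sample_names):
            raise ValueError("library_totals must match sample_names in length")
        if any(t <= 0 for t in self.library_totals):
            raise ValueError("library_totals must be positive")
        if set(self.group_a) | set(self.group_b) != set(self.sample_names) or (
            set(self.group_a) & set(self.group_b)
        ):
            raise ValueError("group_a and group_b must partition sample_names")
        lo, hi = self.length_law
        if not (0 < lo <= hi):
            raise ValueError("length_law bounds must satisfy 0 < lo <= hi")
        if self.baseline_law[1] < 0:
            raise ValueError("baseline_law sigma must be >= 0")
        if not (0 <= self.de_fraction < 1):
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be positive")
        if not (0 <= self.direction_mix <= 1):
            raise ValueError("direction_mix must lie in [0, 1]")
        if self.noise_family not in ("POISSON", "NEGATIVE_BINOMIAL"):
            raise ValueError(
                f"noise_family must be POISSON or NEGATIVE_BINOMIAL, "
                f"got {self.noise_family!r}"
            )
        if self.noise_family == "NEGATIVE_BINOMIAL" and self.dispersion <= 0:
            raise ValueError("dispersion must be positive for NB noise")


@dataclass
class TruthTable:
    """Planted ground truth: per-gene direction and true log2 effect."""

    gene_ids: list[str]
    direction: list[str]        # A_HIGH / B_HIGH / NONE
    log2_effect: np.ndarray     # signed; 0 for unplanted genes

    def planted(self) -> list[str]:
        return [g for g, d in zip(self.gene_ids, self.direction)
                if d != NONE]


def _gene_stream(seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), 0])


def _sample_stream(seed: int, sample_index: int,
                   replicate: int) -> np.random.Generator:
    # per-sample stream keyed by position, independent of how many samples exist
    return np.random.default_rng([int(seed), 1, int(sample_index),
                                  int(replicate)])


def expected_counts(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray,
                                                   np.ndarray, "TruthTable"]:
    """Deterministic layer of the generator: lengths, per-sample expected
    FPKM and expected counts, plus the truth table.  Exposed so tests can
    check realized counts against the exact generative expectation."""
    rng = _gene_stream(spec.seed)
    n = spec.n_genes
    lo, hi = spec.length_law
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    lengths = np.maximum(1, np.round(lengths)).astype(np.int64)
    base_fpkm = rng.lognormal(spec.baseline_law[0], spec.baseline_law[1], size=n)

    n_planted = int(round(spec.de_fraction * n))
    planted_idx = rng.choice(n, size=n_planted, replace=False)
    n_a = int(round(spec.direction_mix * n_planted))
    a_idx = planted_idx[:n_a]
    b_idx = planted_idx[n_a:]

    direction = np.full(n, NONE, dtype=object)
    direction[a_idx] = A_HIGH
    direction[b_idx] = B_HIGH
    effect = np.zeros(n)
    effect[a_idx] = spec.effect_log2
    effect[b_idx] = -spec.effect_log2

    in_a = np.array([s in spec.group_a for s in spec.sample_names])
    fpkm = np.empty((n, len(spec.sample_names)))
    for j, is_a in enumerate(in_a):
        shift = np.where(
            direction == (A_HIGH if is_a else B_HIGH),
            2.0 ** spec.effect_log2,
            1.0,
        )
        fpkm[:, j] = base_fpkm * shift

    totals = np.asarray(spec.library_totals, dtype=float)
    mu = fpkm * totals[np.newaxis, :] * lengths[:, np.newaxis] / 1e9

    gene_ids = [f"gene{i:05d}" for i in range(n)]
    truth = TruthTable(gene_ids, list(direction), effect)
    return lengths, mu, fpkm, truth


def simulate_counts(spec: SimulationSpec) -> tuple[CountTable, TruthTable]:
    """Draw a CountTable from the spec's generative law.

    Identical specs (including seed) yield identical tables; realized
    library totals are recorded as column sums.
    """
    lengths, mu, _, truth = expected_counts(spec)
    n, m = mu.shape
    counts = np.empty((n, m), dtype=np.int64)
    for j in range(m):
        rng = _sample_stream(spec.seed, j, spec.replicate)
        col_mu = mu[:, j]
        if spec.noise_family == "POISSON":
            counts[:, j] = rng.poisson(col_mu)
        else:
            # NB via gamma-Poisson: shape 1/phi, mean mu
            shape = 1.0 / spec.dispersion
            lam = rng.gamma(shape, col_mu * spec.dispersion)
            counts[:, j] = rng.poisson(lam)

    genes = [GeneRecord(g, int(l)) for g, l in zip(truth.gene_ids, lengths)]
    table = CountTable(
        genes=genes,
        samples=list(spec.sample_names),
        counts=counts,
        totals=counts.sum(axis=0),
    )
    return table, truth


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the screen recovered the planted structure."""

    sensitivity: float          # planted called in true direction / planted
    false_direction_rate: float  # planted called in the opposite direction / planted
    fdp: float                  # called genes not planted in that direction / called
    n_planted: int
    n_called: int


def evaluate_recovery(calls: list[GeneCall], truth: TruthTable) -> RecoveryMetrics:
    """Confusion-matrix summary of screen calls against the planted truth."""
    call_map = {c.gene_id: c.direction for c in calls}
    if set(call_map) != set(truth.gene_ids):
        diff = sorted(set(call_map) ^ set(truth.gene_ids))
        raise ValueError(f"gene universes differ: {diff[:10]}")

    true_map = dict(zip(truth.gene_ids, truth.direction))
    planted = [g for g, d in true_map.items() if d != NONE]
    called = [g for g, d in call_map.items() if d != UNCALLED]

    correct = sum(1 for g in planted if call_map[g] == true_map[g])
    flipped = sum(
        1 for g in planted
        if call_map[g] != UNCALLED and call_map[g] != true_map[g]
    )
    false_calls = sum(1 for g in called if true_map[g] != call_map[g])

    n_p, n_c = len(planted), len(called)
    return RecoveryMetrics(
        sensitivity=correct / n_p if n_p else 0.0,
        false_direction_rate=flipped / n_p if n_p else 0.0,
        fdp=false_calls / n_c if n_c else 0.0,
        n_planted=n_p,
        n_called=n_c,
    )
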