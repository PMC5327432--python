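"""End-to-end wiring: counts -> FPKM -> pairwise exact tests -> consensus
screen -> report, with a serializable configuration."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .detest import test_pair
from .expression import compute_fpkm
from .screen import ScreenConfig, consensus_screen, count_directions
from .tables_io import read_count_table, write_report

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("acscreen")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    counts_path: str
    lengths_path: str
    report_path: str
    group_a: list[str] = field(default_factory=lambda: ["R1", "R2"])
    group_b: list[str] = field(default_factory=lambda: ["W1", "W2"])
    annotation_path: str | None = None
    totals_path: str | None = None
    min_abs_log2_fold: float = 1.0
    max_fdr: float = 0.001
    include_zero_rule: bool = True
    zero_sentinel: str = "—"

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            group_a=tuple(self.group_a),
            group_b=tuple(self.group_b),
            min_abs_log2_fold=self.min_abs_log2_fold,
            max_fdr=self.max_fdr,
            include_zero_rule=self.include_zero_rule,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screen and write the report.

    Returns the stage tallies (total genes, tested, A-high, B-high,
    uncalled).  Any stage failure aborts, removes the partial report and
    re-raises as :class:`PipelineError` naming the stage.
    """
    stage = "read"
    try:
        table = read_count_table(
            config.counts_path,
            config.lengths_path,
            annotation_path=config.annotation_path,
            totals_path=config.totals_path,
        )
        logger.info("read %d genes x %d samples", len(table.genes),
                    len(table.samples))

        stage = "fpkm"
        expr = compute_fpkm(table)

        stage = "detest"
        cfg = config.screen_config()
        results = {
            pair: test_pair(table, expr, *pair) for pair in cfg.pairs
        }
        logger.info("tested %d genes in %d comparisons", len(table.genes),
                    len(results))

        stage = "screen"
        calls = consensus_screen(results, cfg)
        a_high, b_high, uncalled = count_directions(calls)
        logger.info("calls: %d A-high, %d B-high, %d uncalled", a_high,
                    b_high, uncalled)

        stage = "report"
        called = [c for c in calls if c.direction != "UNCALLED"]
        write_report(called, expr, table.genes, config.report_path,
                     zero_sentinel=config.zero_sentinel)
    except Exception as exc:
        report = Path(config.report_path)
        if stage == "report" and report.exists():
            report.unlink()
        raise PipelineError(stage, exc) from exc

    return {
        "n_genes": len(table.genes),
        "n_comparisons": len(results),
        "a_high": a_high,
        "b_high": b_high,
        "uncalled": uncalled,
    }
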