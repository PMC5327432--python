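"""Reading and writing the screen's tabular contracts.

All downstream stages consume the :class:`CountTable` built here: per-gene
fragment counts for named samples, per-sample library totals N (the total
number of fragments uniquely aligned to all genes) and per-gene lengths L
in bases.  Everything is tab-separated plain text so that intermediate
artifacts stay inspectable with standard shell tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "CountTable",
    "read_count_table",
    "write_count_table",
    "write_report",
    "EM_DASH",
]

#: Sentinel printed in reports where a fold's denominator FPKM is exactly 0.
EM_DASH = "—"


@dataclass(frozen=True)
class GeneRecord:
    """One transcript: id, length in bases, optional annotation."""

    gene_id: str
    length_bases: int
    annotation_id: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.length_bases < 1:
            raise ValueError(
                f"gene {self.gene_id!r}: length_bases must be >= 1, "
                f"got {self.length_bases}"
            )


@dataclass
class CountTable:
    """Gene x sample fragment counts with library totals.

    ``totals[s]`` is N for sample ``s`` — it may exceed the column sum when
    the table covers only a subset of the aligned genes, but never be
    smaller.
    """

    genes: list[GeneRecord]
    samples: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer
    totals: np.ndarray  # shape (n_samples,), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.totals = np.asarray(self.totals)
        n_genes, n_samples = len(self.genes), len(self.samples)
        if self.counts.shape != (n_genes, n_samples):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n_genes} genes x {n_samples} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count for gene {self.genes[g].gene_id!r}, "
                f"sample {self.samples[s]!r}"
            )
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate gene id {dup!r}")
        colsums = self.counts.sum(axis=0)
        for j, s in enumerate(self.samples):
            if self.totals[j] < colsums[j]:
                raise ValueError(
                    f"sample {s!r}: declared total {self.totals[j]} is below "
                    f"the column sum {colsums[j]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([g.length_bases for g in self.genes], dtype=np.int64)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id {sample!r}") from None


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_count_table(
    path: str | Path,
    lengths_path: str | Path,
    annotation_path: str | Path | None = None,
    totals_path: str | Path | None = None,
) -> CountTable:
    """Load a count matrix plus gene lengths into a validated CountTable.

    ``path`` is a TSV whose header row is ``gene_id`` followed by sample
    ids; ``lengths_path`` maps every gene id to its length in bases.  When
    ``totals_path`` (a two-column ``sample_id<TAB>total_fragments`` sidecar)
    is absent, library totals default to column sums, i.e. the table is
    assumed to cover every aligned gene.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need a gene_id column plus >=1 sample column")
    gene_col = raw.columns[0]
    samples = [str(c) for c in raw.columns[1:]]
    gene_ids = raw[gene_col].tolist()

    counts = np.empty((len(gene_ids), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        for i, cell in enumerate(raw[s]):
            try:
                v = int(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {cell!r} at gene "
                    f"{gene_ids[i]!r}, sample {s!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}: negative count {v} at gene {gene_ids[i]!r}, "
                    f"sample {s!r}"
                )
            counts[i, j] = v

    lengths_df = _read_tsv(lengths_path)
    lengths = dict(zip(lengths_df.iloc[:, 0], lengths_df.iloc[:, 1]))

    annotation: Mapping[str, tuple[str | None, str | None]] = {}
    if annotation_path is not None:
        ann = _read_tsv(annotation_path)
        annotation = {
            row.iloc[0]: (row.iloc[1] or None, row.iloc[2] if len(row) > 2 and row.iloc[2] else None)
            for _, row in ann.iterrows()
        }

    genes = []
    for gid in gene_ids:
        if gid not in lengths:
            raise ValueError(f"{lengths_path}: no length for gene {gid!r}")
        ann_id, product = annotation.get(gid, (None, None))
        genes.append(GeneRecord(gid, int(lengths[gid]), ann_id, product))

    if totals_path is not None:
        tdf = _read_tsv(totals_path)
        declared = dict(zip(tdf.iloc[:, 0], tdf.iloc[:, 1]))
        missing = [s for s in samples if s not in declared]
        if missing:
            raise ValueError(f"{totals_path}: no totals for samples {missing}")
        totals = np.array([int(declared[s]) for s in samples], dtype=np.int64)
    else:
        totals = counts.sum(axis=0)

    return CountTable(genes=genes, samples=samples, counts=counts, totals=totals)


def write_count_table(
    table: CountTable,
    path: str | Path,
    lengths_path: str | Path,
    totals_path: str | Path | None = None,
) -> None:
    """Serialize a CountTable back to its TSV contracts (round-trip safe)."""
    df = pd.DataFrame(table.counts, columns=table.samples)
    df.insert(0, "gene_id", table.gene_ids)
    df.to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": table.gene_ids, "length_bases": table.lengths}
    ).to_csv(lengths_path, sep="\t", index=False)
    if totals_path is not None:
        pd.DataFrame(
            {"sample_id": table.samples, "total_fragments": table.totals}
        ).to_csv(totals_path, sep="\t", index=False)


def _format_fold(value: float) -> str:
    """Render a log2 fold for the report; infinities mean denominator 0."""
    if math.isinf(value) or math.isnan(value):
        return EM_DASH
    return f"{value:.2f}"


def write_report(
    calls: Sequence,
    expr,
    genes: Iterable[GeneRecord],
    path: str | Path,
    zero_sentinel: str = EM_DASH,
) -> None:
    """Write the screen's result table.

    One row per called gene: id, annotation id, FPKM per sample (2
    decimals), the log2 fold per configured comparison (2 decimals, or the
    zero-denominator sentinel), and the direction call.  Rows are ordered
    by functional category (the annotation ``product``) then gene id when
    annotation is present, otherwise in input order.
    """
    gene_map = {g.gene_id: g for g in genes}
    expr_index = {g: i for i, g in enumerate(expr.genes)}

    records = []
    for call in calls:
        gid = call.gene_id
        if gid not in expr_index:
            raise ValueError(f"called gene {gid!r} absent from expression matrix")
        rec = gene_map.get(gid)
        row: dict[str, str] = {
            "gene_id": gid,
            "annotation_id": (rec.annotation_id or "") if rec else "",
        }
        gi = expr_index[gid]
        for j, s in enumerate(expr.samples):
            row[f"fpkm_{s}"] = f"{expr.fpkm[gi, j]:.2f}"
        for (a, b), fold in call.folds.items():
            if fold is None or math.isinf(fold) or math.isnan(fold):
                row[f"fold_{a}_{b}"] = zero_sentinel
            else:
                row[f"fold_{a}_{b}"] = f"{fold:.2f}"
        row["direction"] = call.direction
        product = (rec.product or "") if rec else ""
        records.append((product, gid, row))

    annotated = any(p for p, _, _ in records)
    if annotated:
        records.sort(key=lambda t: (t[0], t[1]))

    if records:
        df = pd.DataFrame([r for _, _, r in records])
    else:
        cols = ["gene_id", "annotation_id"]
        cols += [f"fpkm_{s}" for s in expr.samples]
        cols += ["direction"]
        df = pd.DataFrame(columns=cols)
    df.to_csv(path, sep="\t", index=False)
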