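"""Depletion-efficiency and library-composition metrics.

A gene count table is a pandas DataFrame of genes x samples with two flag
columns, ``organism`` and ``is_rrna``.  rRNA percent is computed per the
mapping convention of the depletion workflow: rRNA-mapped reads as a fraction
of total reads mapped to the organism.  RPM excludes rRNA genes from both
numerator and denominator.

Threshold semantics differ deliberately between operations: detection curves
count genes strictly ABOVE each expression threshold, while the expression
filter keeps genes AT OR ABOVE the minimum RPM in every sample (comparator
configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneCountTable",
    "LibraryMetrics",
    "rrna_percent",
    "organism_partition",
    "rpm",
    "detection_curve",
    "expression_filter",
    "library_correlation",
]

FLAG_COLUMNS = ("organism", "is_rrna")


@dataclass
class GeneCountTable:
    """Genes x samples read counts with organism and rRNA annotations."""

    data: pd.DataFrame  # index: gene ids; columns: samples + organism, is_rrna

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("gene ids must be unique")
        for col in FLAG_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"missing required column {col!r}")
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.data.columns if c not in FLAG_COLUMNS]

    @property
    def counts(self) -> pd.DataFrame:
        return self.data[self.samples]

    @property
    def is_rrna(self) -> pd.Series:
        return self.data["is_rrna"].astype(bool)

    @property
    def organism(self) -> pd.Series:
        return self.data["organism"]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df["is_rrna"] = df["is_rrna"].astype(bool)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


@dataclass(frozen=True)
class LibraryMetrics:
    total_mapped: int
    rrna_mapped: int
    rrna_percent: float
    organism_percents: dict[str, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.rrna_percent <= 100.0):
            raise ValueError("rrna_percent must be in [0, 100]")


def rrna_percent(table: GeneCountTable, sample: str, organism: str | None = None) -> float:
    """rRNA-mapped reads as a percentage of total organism-mapped reads."""
    counts = table.counts[sample]
    if organism is not None:
        mask = table.organism == organism
        counts = counts[mask]
        rrna = table.is_rrna[mask]
    else:
        rrna = table.is_rrna
    total = counts.sum()
    if total == 0:
        raise ValueError(f"sample {sample!r}: no mapped reads")
    return 100.0 * float(counts[rrna].sum()) / float(total)


def organism_partition(table: GeneCountTable, sample: str) -> dict[str, float]:
    """Percentage of mapped reads per organism; sums to 100 over mapped reads."""
    counts = table.counts[sample]
    if table.organism.isna().any():
        bad = table.organism.index[table.organism.isna()][0]
        raise ValueError(f"gene {bad!r} has no organism tag")
    total = counts.sum()
    if total == 0:
        raise ValueError(f"sample {sample!r}: no mapped reads")
    by_org = counts.groupby(table.organism).sum()
    return {org: 100.0 * float(c) / float(total) for org, c in by_org.items()}


def rpm(table: GeneCountTable) -> pd.DataFrame:
    """Reads per million after removal of rRNA reads.

    RPM_g = 1e6 * count_g / (total non-rRNA mapped); rRNA genes are excluded
    from both numerator and denominator and do not appear in the output.
    """
    non_rrna = table.counts[~table.is_rrna]
    totals = non_rrna.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r}: zero non-rRNA reads")
    return 1e6 * non_rrna / totals


def detection_curve(
    table: GeneCountTable,
    sample: str,
    thresholds: Sequence[float],
    downsample_to: int | None = None,
    seed: int = 0,
) -> list[int]:
    """Genes detected strictly above each expression threshold (read counts),
    after optional seeded downsampling to ``downsample_to`` reads.

    Downsampling draws reads without replacement (multivariate hypergeometric
    over gene counts), i.e. it samples sequencing reads, not gene totals.
    Result is non-increasing in threshold.
    """
    thresholds = list(thresholds)
    if not thresholds or any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be ascending")
    counts = table.counts[sample].to_numpy(dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty table")
    total = int(counts.sum())
    if downsample_to is not None and downsample_to < total:
        rng = np.random.default_rng(seed)
        counts = rng.multivariate_hypergeometric(counts, downsample_to)
    return [int((counts > t).sum()) for t in thresholds]


def expression_filter(
    table: GeneCountTable,
    min_rpm: float = 2.0,
    samples: Sequence[str] | None = None,
    strict: bool = False,
) -> list[str]:
    """Genes expressed at RPM >= min_rpm in ALL given samples.

    ``strict=True`` switches the comparator to > (the default >= keeps genes
    at exactly the minimum).  rRNA genes are never returned.
    """
    values = rpm(table)
    samples = list(samples) if samples is not None else table.samples
    sub = values[samples]
    mask = (sub > min_rpm).all(axis=1) if strict else (sub >= min_rpm).all(axis=1)
    return list(sub.index[mask])


def library_correlation(
    table: GeneCountTable,
    sample_a: str,
    sample_b: str,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> float:
    """Pearson correlation of per-gene expression between two libraries.

    Computed on log10(RPM + pseudocount) by default; ``log_transform=False``
    correlates linear RPM.  Requires >= 3 genes and non-degenerate variance.
    """
    values = rpm(table)
    a = values[sample_a].to_numpy(dtype=float)
    b = values[sample_b].to_numpy(dtype=float)
    if log_transform:
        a = np.log10(a + pseudocount)
        b = np.log10(b + pseudocount)
    finite = np.isfinite(a) & np.isfinite(b)
    a, b = a[finite], b[finite]
    if a.size < 3:
        raise ValueError("need at least 3 shared genes with finite values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def library_metrics(
    table: GeneCountTable, sample: str, rrna_organism: str | None = None
) -> LibraryMetrics:
    """Bundle the headline per-library metrics."""
    counts = table.counts[sample]
    total = int(counts.sum())
    rrna = int(counts[table.is_rrna].sum())
    return LibraryMetrics(
        total_mapped=total,
        rrna_mapped=rrna,
        rrna_percent=rrna_percent(table, sample, rrna_organism),
        organism_percents=organism_partition(table, sample),
    )
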