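"""Alignment ingest, demultiplex/trim, per-position coverage, and downsampling.

Coordinates are 1-based inclusive in all external files and reports; the
internal numpy arrays are 0-based (array index p-1 holds position p).  That
boundary is the only place the two conventions meet and it is tested.

SAM support is a deliberately minimal read-only subset via pysam: header plus
the 11 mandatory columns, flags interpreted only for mapped/unmapped.  The
package consumes alignments, it is not an aligner.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

__all__ = [
    "AlignmentRecord",
    "CoverageProfile",
    "BarcodeSpec",
    "load_alignments",
    "build_coverage",
    "cumulative_read_fraction",
    "downsample",
    "demux_trim",
    "write_sam",
    "write_start_counts_tsv",
    "write_bedgraph",
]

DEFAULT_ALIGNED_LENGTH = 51  # read-2 trim length; used when a dialect omits it


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment line: query, reference, 1-based leftmost coordinate."""

    query_id: str
    reference_id: str
    position: int  # 1-based leftmost mapped coordinate; 0 if unmapped
    aligned_length: int
    is_mapped: bool

    def end(self) -> int:
        """1-based inclusive rightmost covered coordinate."""
        return self.position + self.aligned_length - 1


@dataclass
class CoverageProfile:
    """Per-position read-start counts and overlap depth along one reference."""

    reference_id: str
    length: int
    start_counts: np.ndarray  # start_counts[p-1] = reads whose mapped coord == p
    depth: np.ndarray  # depth[p-1] = reads overlapping position p

    def __post_init__(self) -> None:
        self.start_counts = np.asarray(self.start_counts, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.length <= 0:
            raise ValueError("reference length must be positive")
        if len(self.start_counts) != self.length or len(self.depth) != self.length:
            raise ValueError("count arrays must match reference length")
        if (self.start_counts < 0).any() or (self.depth < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(self.start_counts.sum())

    def starts_at(self, position: int) -> int:
        """Read-start count at a 1-based position."""
        return int(self.start_counts[position - 1])


@dataclass(frozen=True)
class BarcodeSpec:
    """Barcode demultiplexing and trim policy for paired reads."""

    valid_barcodes: frozenset[str]
    barcode_offset: int = 0  # 0-based start of barcode in read 1
    read1_trim: int = 25
    read2_trim: int = 51

    def __post_init__(self) -> None:
        lengths = {len(b) for b in self.valid_barcodes}
        if len(lengths) > 1:
            raise ValueError("all barcodes must have the same length")
        if self.read1_trim <= 0 or self.read2_trim <= 0:
            raise ValueError("trim lengths must be positive")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.valid_barcodes))) if self.valid_barcodes else 0


def load_alignments(
    path: str | Path,
    dialect: str = "sam",
    reference_lengths: Mapping[str, int] | None = None,
    default_aligned_length: int = DEFAULT_ALIGNED_LENGTH,
) -> list[AlignmentRecord]:
    """Load alignments from SAM (subset) or 3/4-column TSV.

    TSV columns: query_id, reference_id, position[, aligned_length]; missing
    aligned_length defaults to ``default_aligned_length``.  Unmapped reads are
    retained with ``is_mapped=False``.  Mapped coordinates are validated
    against the declared reference lengths (SAM header or the
    ``reference_lengths`` mapping).
    """
    if dialect == "sam":
        return _load_sam(path)
    if dialect == "tsv":
        return _load_tsv(path, reference_lengths, default_aligned_length)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def _load_sam(path: str | Path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                records.append(
                    AlignmentRecord(aln.query_name, "*", 0, 0, is_mapped=False)
                )
                continue
            ref = aln.reference_name
            if ref not in lengths:
                raise ValueError(f"alignment to unknown reference {ref!r}")
            pos = aln.reference_start + 1  # pysam is 0-based
            if pos < 1:
                raise ValueError(
                    f"mapped read {aln.query_name!r} has invalid position 0"
                )
            span = aln.reference_length or (aln.query_length or 0)
            if span <= 0:
                raise ValueError(f"read {aln.query_name!r}: non-positive span")
            if pos + span - 1 > lengths[ref]:
                raise ValueError(
                    f"read {aln.query_name!r} extends past end of {ref!r} "
                    f"({pos + span - 1} > {lengths[ref]})"
                )
            records.append(AlignmentRecord(aln.query_name, ref, pos, span, True))
    return records


def _load_tsv(
    path: str | Path,
    reference_lengths: Mapping[str, int] | None,
    default_aligned_length: int,
) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >=3 tab-separated columns")
            query, ref, pos_s = parts[:3]
            pos = int(pos_s)
            span = int(parts[3]) if len(parts) > 3 else default_aligned_length
            if pos < 1:
                raise ValueError(f"line {lineno}: position must be 1-based (got {pos})")
            if reference_lengths is not None:
                if ref not in reference_lengths:
                    raise ValueError(f"line {lineno}: unknown reference {ref!r}")
                if pos + span - 1 > reference_lengths[ref]:
                    raise ValueError(
                        f"line {lineno}: alignment exceeds reference length"
                    )
            records.append(AlignmentRecord(query, ref, pos, span, True))
    return records


def build_coverage(
    alignments: Iterable[AlignmentRecord],
    reference_lengths: Mapping[str, int],
) -> dict[str, CoverageProfile]:
    """Accumulate start counts and overlap depth per reference.

    sum(start_counts) equals the number of mapped reads on each reference.
    Depth uses difference-array accumulation over [position, end].
    """
    starts = {
        ref: np.zeros(length, dtype=np.int64)
        for ref, length in reference_lengths.items()
    }
    diffs = {
        ref: np.zeros(length + 1, dtype=np.int64)
        for ref, length in reference_lengths.items()
    }
    for rec in alignments:
        if not rec.is_mapped:
            continue
        if rec.reference_id not in starts:
            raise ValueError(f"mapped read on unknown reference {rec.reference_id!r}")
        length = reference_lengths[rec.reference_id]
        if rec.position < 1 or rec.end() > length:
            raise ValueError(
                f"read {rec.query_id!r} out of bounds on {rec.reference_id!r}"
            )
        starts[rec.reference_id][rec.position - 1] += 1
        diffs[rec.reference_id][rec.position - 1] += 1
        diffs[rec.reference_id][rec.end()] -= 1
    return {
        ref: CoverageProfile(ref, reference_lengths[ref], starts[ref],
                             np.cumsum(diffs[ref][:-1]))
        for ref in reference_lengths
    }


def cumulative_read_fraction(profile: CoverageProfile) -> np.ndarray:
    """Cumulative percentage of reads whose mapped coordinate is <= p.

    Non-decreasing, final value exactly 100.0.
    """
    total = profile.total_reads
    if total == 0:
        raise ValueError(f"no mapped reads on {profile.reference_id!r}")
    cum = np.cumsum(profile.start_counts, dtype=np.float64)
    return 100.0 * cum / total


def downsample(
    alignments: Sequence[AlignmentRecord], n: int, seed: int
) -> list[AlignmentRecord]:
    """Uniform sample of exactly min(n, total) records without replacement.

    Seeded shuffle; identical seed gives the identical subset.  Input order of
    the retained records is preserved.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    total = len(alignments)
    if n >= total:
        return list(alignments)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.permutation(total)[:n])
    return [alignments[i] for i in keep]


def demux_trim(
    read_pairs: Iterable[tuple[tuple[str, str], tuple[str, str]]],
    spec: BarcodeSpec,
) -> tuple[list[tuple[tuple[str, str], tuple[str, str]]], Counter]:
    """Retain pairs with a valid read-1 barcode; trim read 1/2 to spec lengths.

    Each pair is ((id1, seq1), (id2, seq2)).  Returns (retained pairs, counter)
    where the counter tallies each valid barcode plus the drop reasons
    ``invalid_barcode`` and ``too_short``.  Reads shorter than their trim are
    dropped and counted, never raised.
    """
    counts: Counter = Counter()
    retained = []
    bc_end = spec.barcode_offset + spec.barcode_length
    for (id1, seq1), (id2, seq2) in read_pairs:
        if len(seq1) < max(spec.read1_trim, bc_end) or len(seq2) < spec.read2_trim:
            counts["too_short"] += 1
            continue
        barcode = seq1[spec.barcode_offset : bc_end]
        if barcode not in spec.valid_barcodes:
            counts["invalid_barcode"] += 1
            continue
        counts[barcode] += 1
        retained.append(
            ((id1, seq1[: spec.read1_trim]), (id2, seq2[: spec.read2_trim]))
        )
    return retained, counts


def write_sam(
    alignments: Iterable[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write records as minimal text SAM (header + 11 mandatory columns)."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref, length in reference_lengths.items():
            handle.write(f"@SQ\tSN:{ref}\tLN:{length}\n")
        for rec in alignments:
            if rec.is_mapped:
                cigar = f"{rec.aligned_length}M"
                seq = "N" * rec.aligned_length
                handle.write(
                    f"{rec.query_id}\t0\t{rec.reference_id}\t{rec.position}\t60\t"
                    f"{cigar}\t*\t0\t0\t{seq}\t*\n"
                )
            else:
                handle.write(f"{rec.query_id}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")


def write_start_counts_tsv(profile: CoverageProfile, path: str | Path) -> None:
    """TSV of 1-based position and read-start count (covered positions only)."""
    with open(path, "w") as handle:
        handle.write("reference\tposition\tstart_count\n")
        for idx in np.nonzero(profile.start_counts)[0]:
            handle.write(
                f"{profile.reference_id}\t{idx + 1}\t{profile.start_counts[idx]}\n"
            )


def write_bedgraph(profile: CoverageProfile, path: str | Path) -> None:
    """bedGraph (0-based half-open) of overlap depth, run-length merged."""
    with open(path, "w") as handle:
        depth = profile.depth
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        edges = np.concatenate(([0], boundaries, [len(depth)]))
        for lo, hi in zip(edges[:-1], edges[1:]):
            if depth[lo] > 0:
                handle.write(f"{profile.reference_id}\t{lo}\t{hi}\t{depth[lo]}\n")
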