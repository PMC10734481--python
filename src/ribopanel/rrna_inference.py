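"""Annotation-free rRNA locus inference from genome-scaffold read pileups.

Eukaryotic rDNA sits in tandem repeats, so on a genome scaffold the rRNA
subunits show up as a periodic series of high-coverage blocks.  The workflow:

1. find maximal runs of positions whose depth is >= min_fold x the scaffold's
   median covered depth (median, not mean, to resist the spikes themselves);
2. label consecutive block triplets whose inter-summit spacings match the
   expected subunit sizes (small/short/large, default 18S/5.8S/28S-like);
3. collapse consecutive triplets with a consistent period into one locus with
   a repeat count, anchoring probes at the block 3' ends of the FIRST repeat.

The anchors feed ``oligo_design.design_rnaseh_probes`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coverage import CoverageProfile

__all__ = [
    "PileupBlock",
    "SubunitSizeModel",
    "LabeledTriplet",
    "InferredRrnaLocus",
    "find_pileup_blocks",
    "match_triplet_pattern",
    "detect_tandem_repeats",
    "infer_probe_anchors",
]


@dataclass(frozen=True)
class PileupBlock:
    """A contiguous high-coverage region on a scaffold (1-based inclusive)."""

    scaffold_id: str
    start: int
    end: int
    read_count: int
    summit: int  # position of maximal start-count within the block

    def __post_init__(self) -> None:
        if not (self.start <= self.summit <= self.end):
            raise ValueError("summit must lie within the block")
        if self.read_count <= 0:
            raise ValueError("read_count must be positive")


@dataclass(frozen=True)
class SubunitSizeModel:
    """Expected subunit lengths (nt) and matching tolerance.

    Defaults describe a canonical eukaryotic rDNA repeat read left to right as
    small (18S-like, ~1800 nt) -> short (5.8S-like, ~160 nt) -> large
    (28S-like, ~3400 nt); the order and all sizes are configurable — the
    matcher is size-model-agnostic.
    """

    small_nt: int = 1800
    short_nt: int = 160
    large_nt: int = 3400
    rel_tolerance: float = 0.35
    order: tuple[str, ...] = ("small", "short", "large")

    def __post_init__(self) -> None:
        if min(self.small_nt, self.short_nt, self.large_nt) <= 0:
            raise ValueError("subunit lengths must be positive")
        if not (0 < self.rel_tolerance <= 1):
            raise ValueError("rel_tolerance must be in (0, 1]")
        if sorted(self.order) != ["large", "short", "small"]:
            raise ValueError("order must be a permutation of small/short/large")

    def size_of(self, label: str) -> int:
        return {"small": self.small_nt, "short": self.short_nt,
                "large": self.large_nt}[label]


@dataclass(frozen=True)
class LabeledTriplet:
    """Three consecutive blocks labeled with subunit assignments."""

    blocks: tuple[PileupBlock, PileupBlock, PileupBlock]
    labels: tuple[str, str, str]

    @property
    def start(self) -> int:
        return self.blocks[0].summit


@dataclass(frozen=True)
class InferredRrnaLocus:
    """One rDNA locus: tandem repeats of a labeled subunit triplet."""

    scaffold_id: str
    repeats: tuple[LabeledTriplet, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.repeats:
            raise ValueError("locus must contain at least one repeat")

    @property
    def repeat_count(self) -> int:
        return len(self.repeats)

    @property
    def three_prime_anchors(self) -> dict[str, int]:
        return infer_probe_anchors(self)


def find_pileup_blocks(
    profile: CoverageProfile, min_fold: float = 5.0
) -> list[PileupBlock]:
    """Maximal runs of positions with depth >= min_fold x median covered depth.

    The median is taken over covered positions only (depth > 0).  Blocks are
    separated by at least one sub-threshold position.  All-zero coverage
    yields an empty result.
    """
    depth = profile.depth
    covered = depth[depth > 0]
    if covered.size == 0:
        return []
    threshold = min_fold * float(np.median(covered))
    above = depth >= threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    transitions = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(transitions == 1)
    run_ends = np.flatnonzero(transitions == -1) - 1
    blocks = []
    for lo, hi in zip(run_starts.tolist(), run_ends.tolist()):
        window_starts = profile.start_counts[lo : hi + 1]
        summit = lo + int(np.argmax(window_starts))
        count = int(window_starts.sum())
        blocks.append(
            PileupBlock(
                scaffold_id=profile.reference_id,
                start=lo + 1,
                end=hi + 1,
                read_count=max(count, 1),
                summit=summit + 1,
            )
        )
    return blocks


def _within(observed: float, expected: float, tol: float) -> bool:
    return abs(observed - expected) <= tol * expected


def match_triplet_pattern(
    blocks: Sequence[PileupBlock], model: SubunitSizeModel | None = None
) -> tuple[list[LabeledTriplet], list[PileupBlock]]:
    """Label consecutive block triplets whose summit spacings fit the model.

    Reading a repeat left to right, the gap between summit i and summit i+1
    approximates the length of subunit i+1, so a triplet matches when
    gap(b1,b2) ~ size(order[1]) and gap(b2,b3) ~ size(order[2]) within the
    relative tolerance.  Greedy left-to-right, non-overlapping.  Returns
    (labeled triplets, unmatched blocks).
    """
    model = model or SubunitSizeModel()
    ordered = sorted(blocks, key=lambda b: b.start)
    triplets: list[LabeledTriplet] = []
    unmatched: list[PileupBlock] = []
    i = 0
    while i < len(ordered):
        if i + 2 < len(ordered):
            b1, b2, b3 = ordered[i], ordered[i + 1], ordered[i + 2]
            gap12 = b2.summit - b1.summit
            gap23 = b3.summit - b2.summit
            if _within(gap12, model.size_of(model.order[1]), model.rel_tolerance) and \
               _within(gap23, model.size_of(model.order[2]), model.rel_tolerance):
                triplets.append(LabeledTriplet((b1, b2, b3), tuple(model.order)))
                i += 3
                continue
        unmatched.append(ordered[i])
        i += 1
    return triplets, unmatched


def detect_tandem_repeats(
    triplets: Sequence[LabeledTriplet],
    rel_tolerance: float = 0.35,
    strand: str = "+",
) -> list[InferredRrnaLocus]:
    """Group consecutive triplets with a consistent period into loci.

    The period is the distance between the first summits of consecutive
    triplets; successive periods must agree within ``rel_tolerance``.  Each
    inconsistent step starts a new locus.  Probe anchors come from the first
    repeat of each locus.
    """
    if not triplets:
        return []
    ordered = sorted(triplets, key=lambda t: t.start)
    loci: list[InferredRrnaLocus] = []
    group = [ordered[0]]
    period: float | None = None
    for trip in ordered[1:]:
        gap = trip.start - group[-1].start
        if period is None or _within(gap, period, rel_tolerance):
            group.append(trip)
            period = gap if period is None else period
        else:
            loci.append(
                InferredRrnaLocus(group[0].blocks[0].scaffold_id, tuple(group), strand)
            )
            group = [trip]
            period = None
    loci.append(
        InferredRrnaLocus(group[0].blocks[0].scaffold_id, tuple(group), strand)
    )
    return loci


def infer_probe_anchors(locus: InferredRrnaLocus) -> dict[str, int]:
    """Per-subunit 3'-end anchor coordinates, taken from the FIRST repeat.

    On the forward strand the anchor is each labeled block's end coordinate;
    with a reverse-strand locus, block starts are used instead.
    """
    first = locus.repeats[0]
    if locus.strand == "+":
        return {
            label: block.end for label, block in zip(first.labels, first.blocks)
        }
    return {label: block.start for label, block in zip(first.labels, first.blocks)}
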