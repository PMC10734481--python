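"""Hotspot identification from read-coverage profiles.

The procedure is a deterministic ranking heuristic, not a statistical peak
caller: take the top-k coordinates by read-start count (the step increases of
the cumulative read distribution), cluster them wherever consecutive sorted
coordinates are separated by more than a fixed gap ("natural breaks"), rank
clusters by their summed read counts, and pick the downstream-most (3'-most)
member of each retained cluster as the primer target.

All ties break toward the downstream (3'-most) coordinate, consistent with the
downstream placement preference of the design stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage import CoverageProfile

__all__ = [
    "HotspotCandidate",
    "HotspotCluster",
    "HotspotConfig",
    "top_step_coordinates",
    "cluster_by_gaps",
    "select_hotspot_targets",
    "find_targets",
]


@dataclass(frozen=True)
class HotspotCandidate:
    """A 1-based coordinate and its read-start count (step-increase size)."""

    coordinate: int
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count <= 0:
            raise ValueError("candidate read_count must be positive")


@dataclass(frozen=True)
class HotspotCluster:
    """A run of nearby candidates; the target is its 3'-most member."""

    members: tuple[HotspotCandidate, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be non-empty")
        coords = [m.coordinate for m in self.members]
        if coords != sorted(coords):
            raise ValueError("cluster members must be sorted ascending")

    @property
    def coordinates(self) -> tuple[int, ...]:
        return tuple(m.coordinate for m in self.members)

    @property
    def total_reads(self) -> int:
        return sum(m.read_count for m in self.members)

    @property
    def target(self) -> int:
        """Downstream-most (largest) member coordinate."""
        return self.members[-1].coordinate


@dataclass(frozen=True)
class HotspotConfig:
    top_k: int = 50
    cluster_gap_nt: int = 100
    max_targets_per_subunit: int = 4
    min_cluster_read_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.cluster_gap_nt < 0:
            raise ValueError("cluster_gap_nt must be >= 0")
        if self.max_targets_per_subunit < 1:
            raise ValueError("max_targets_per_subunit must be >= 1")
        if not (0.0 <= self.min_cluster_read_fraction <= 1.0):
            raise ValueError("min_cluster_read_fraction must be in [0, 1]")


def top_step_coordinates(
    profile: CoverageProfile, top_k: int = 50
) -> list[HotspotCandidate]:
    """Top-k coordinates by read-start count.

    Returns all covered positions if fewer than top_k exist.  Ties break
    toward the downstream (larger) coordinate.  Output is sorted by count
    descending, then coordinate descending.
    """
    if profile.total_reads == 0:
        raise ValueError(f"no mapped reads on {profile.reference_id!r}")
    covered = np.nonzero(profile.start_counts)[0]
    counts = profile.start_counts[covered]
    # sort by (count desc, coordinate desc): downstream-most wins ties
    order = np.lexsort((-(covered), -counts))
    chosen = order[: min(top_k, len(order))]
    return [
        HotspotCandidate(int(covered[i]) + 1, int(counts[i])) for i in chosen
    ]


def cluster_by_gaps(
    candidates: Sequence[HotspotCandidate], gap_nt: int = 100
) -> list[HotspotCluster]:
    """Partition 5'->3' sorted candidates at gaps exceeding ``gap_nt``."""
    if not candidates:
        raise ValueError("no candidates to cluster")
    ordered = sorted(candidates, key=lambda c: c.coordinate)
    clusters: list[HotspotCluster] = []
    current = [ordered[0]]
    for cand in ordered[1:]:
        if cand.coordinate - current[-1].coordinate > gap_nt:
            clusters.append(HotspotCluster(tuple(current)))
            current = [cand]
        else:
            current.append(cand)
    clusters.append(HotspotCluster(tuple(current)))
    return clusters


def select_hotspot_targets(
    clusters: Sequence[HotspotCluster],
    cfg: HotspotConfig,
    subunit_total_reads: int,
    reference_length: int | None = None,
) -> list[int]:
    """Rank clusters by summed reads and emit up to max_targets target coords.

    Clusters holding less than ``min_cluster_read_fraction`` of the subunit's
    mapped reads are dropped.  When ``reference_length`` is given, clusters
    whose target lies within ``cluster_gap_nt`` of the reference 3' end are
    absorbed into the 3'-end primer's territory and not emitted.  Output is
    sorted 5'->3'.
    """
    if subunit_total_reads < sum(c.total_reads for c in clusters):
        raise ValueError("subunit_total_reads below sum of cluster totals")
    eligible = [
        c
        for c in clusters
        if c.total_reads >= cfg.min_cluster_read_fraction * subunit_total_reads
    ]
    if reference_length is not None:
        eligible = [
            c for c in eligible if c.target < reference_length - cfg.cluster_gap_nt
        ]
    # rank by total desc; equal totals at the cut keep the downstream cluster
    ranked = sorted(eligible, key=lambda c: (-c.total_reads, -c.target))
    kept = ranked[: cfg.max_targets_per_subunit]
    return sorted(c.target for c in kept)


def find_targets(
    profile: CoverageProfile,
    cfg: HotspotConfig | None = None,
    reference_length: int | None = None,
) -> list[int]:
    """Full pipeline: top-k candidates -> gap clusters -> ranked targets."""
    cfg = cfg or HotspotConfig()
    candidates = top_step_coordinates(profile, cfg.top_k)
    clusters = cluster_by_gaps(candidates, cfg.cluster_gap_nt)
    return select_hotspot_targets(
        clusters,
        cfg,
        profile.total_reads,
        reference_length if reference_length is not None else profile.length,
    )
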