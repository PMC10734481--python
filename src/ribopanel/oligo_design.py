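"""Blocking-primer and RNase H probe design, and mix composition.

Blocking primers are reverse complements of the sense reference, anchored at
the subunit 3' end or ~100 nt downstream of a hotspot target.  They start at
30 nt and are extended 5'-ward (the 3' terminus stays anchored, which is what
matters for priming) one base at a time until the duplex Tm exceeds the design
minimum (65 degC by default); hotspot primers may additionally shift their
anchor by a few bases when extension alone cannot reach the gate.

RNase H probes target antisense amplified RNA, so they are verbatim
sense-strand copies of the reference, always exactly 50 nt, placed ending at
each blocking-primer anchor so that RNase H cleavage removes the
adapter-proximal end of the aRNA.  Probes carry no Tm gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .hotspots import HotspotConfig, find_targets
from .coverage import CoverageProfile
from .seqcore import (
    NucleotideSequence,
    ThermoConfig,
    melting_temperature,
    reverse_complement,
)

__all__ = [
    "BlockingPrimer",
    "RNaseHProbe",
    "DesignConfig",
    "MixSpec",
    "SpeciesPanel",
    "DesignError",
    "PanelValidationError",
    "design_three_prime_primer",
    "design_hotspot_primer",
    "design_rnaseh_probes",
    "design_species_panel",
    "compose_blocking_mix",
    "compose_coculture_probe_mix",
]

PROBE_LENGTH = 50
PROBE_MERGE_OVERLAP = 0.8
MAX_BLOCKING_PRIMERS_PER_SPECIES = 10
MAX_PROBES_PER_SPECIES = 10


class DesignError(ValueError):
    """A primer or probe could not be designed under the configured rules."""


class PanelValidationError(ValueError):
    """A designed panel violates the per-species oligo-count ceilings."""


@dataclass(frozen=True)
class BlockingPrimer:
    """A designed blocking primer.

    ``ref_start``/``ref_end`` are the 1-based inclusive coordinates of the
    binding site on the sense reference; ``sequence`` is the reverse
    complement of that window.
    """

    name: str
    subunit_id: str
    kind: str  # "three_prime" | "hotspot"
    ref_start: int
    ref_end: int
    sequence: str
    tm_C: float
    shift: int = 0
    merged_with_three_prime: bool = False

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass(frozen=True)
class RNaseHProbe:
    """A 50-nt sense-strand probe ending at its anchor coordinate."""

    name: str
    subunit_id: str
    anchor: int
    ref_start: int
    ref_end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1

    def __post_init__(self) -> None:
        if self.length != PROBE_LENGTH:
            raise DesignError(
                f"probe {self.name!r}: length {self.length} != {PROBE_LENGTH}"
            )


@dataclass(frozen=True)
class DesignConfig:
    initial_length: int = 30
    min_tm_C: float = 65.0
    max_length: int = 45
    max_shift_nt: int = 5
    hotspot_offset_nt: int = 100
    thermo: ThermoConfig = field(default_factory=ThermoConfig)

    def __post_init__(self) -> None:
        if self.initial_length > self.max_length:
            raise ValueError("initial_length must be <= max_length")
        if self.min_tm_C <= 0:
            raise ValueError("min_tm_C must be positive")
        if self.max_shift_nt < 0:
            raise ValueError("max_shift_nt must be >= 0")


@dataclass(frozen=True)
class MixSpec:
    """Per-oligo amounts with per-group totals; µM for primer mixes, ng for
    probe mixes."""

    components: dict[str, float]
    group_totals: dict[str, float]
    unit: str
    bootstrap: bool = False

    @property
    def total(self) -> float:
        return sum(self.components.values())

    def __post_init__(self) -> None:
        if abs(self.total - sum(self.group_totals.values())) > 1e-9 * max(
            1.0, self.total
        ):
            raise ValueError("group totals do not sum to the component total")


@dataclass(frozen=True)
class SpeciesPanel:
    """All primers and probes designed for one species, plus the config used."""

    species_id: str
    primers: tuple[BlockingPrimer, ...]
    probes: tuple[RNaseHProbe, ...]
    design_cfg: DesignConfig
    hotspot_cfg: HotspotConfig
    hotspot_targets: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def three_prime_primers(self) -> tuple[BlockingPrimer, ...]:
        return tuple(p for p in self.primers if p.kind == "three_prime")

    @property
    def hotspot_primers(self) -> tuple[BlockingPrimer, ...]:
        return tuple(p for p in self.primers if p.kind == "hotspot")

    @property
    def n_oligos(self) -> int:
        return len(self.primers) + len(self.probes)


def _primer_at(
    reference: NucleotideSequence,
    ref_end: int,
    length: int,
    cfg: DesignConfig,
) -> tuple[int, int, str, float] | None:
    """Candidate primer with binding-site 3' terminus at ``ref_end``.

    Returns (ref_start, ref_end, sequence, tm) or None if out of bounds,
    N-containing, or below the Tm gate.
    """
    ref_start = ref_end - length + 1
    if ref_start < 1 or ref_end > len(reference):
        return None
    window = reference.window(ref_start, ref_end)
    if "N" in window:
        return None
    tm = melting_temperature(window, cfg.thermo)
    if tm > cfg.min_tm_C:
        return (ref_start, ref_end, reverse_complement(window), tm)
    return None


def design_three_prime_primer(
    reference: NucleotideSequence, cfg: DesignConfig | None = None
) -> BlockingPrimer:
    """Primer whose binding site ends exactly at the reference 3' terminus.

    Starts at ``initial_length`` and extends 5'-ward one base at a time until
    Tm > min_tm_C or ``max_length`` is reached.
    """
    cfg = cfg or DesignConfig()
    if len(reference) < cfg.initial_length:
        raise DesignError(
            f"{reference.id!r}: reference length {len(reference)} below "
            f"initial primer length {cfg.initial_length}"
        )
    best_tm = float("-inf")
    for length in range(cfg.initial_length, cfg.max_length + 1):
        cand = _primer_at(reference, len(reference), length, cfg)
        if cand is not None:
            start, end, seq, tm = cand
            return BlockingPrimer(
                name=f"{reference.id}_3p",
                subunit_id=reference.id,
                kind="three_prime",
                ref_start=start,
                ref_end=end,
                sequence=seq,
                tm_C=tm,
            )
        window = reference.window(len(reference) - length + 1, len(reference))
        if "N" not in window:
            best_tm = max(best_tm, melting_temperature(window, cfg.thermo))
    raise DesignError(
        f"{reference.id!r}: no 3'-end primer up to {cfg.max_length} nt reaches "
        f"Tm > {cfg.min_tm_C} (best achieved {best_tm:.2f})"
    )


def _shift_order(max_shift: int) -> list[int]:
    """0, -1, +1, -2, +2, ... +-max_shift (extension is tried before shifts)."""
    order = [0]
    for s in range(1, max_shift + 1):
        order.extend([-s, s])
    return order


def design_hotspot_primer(
    reference: NucleotideSequence,
    target_coord: int,
    cfg: DesignConfig | None = None,
) -> BlockingPrimer:
    """Primer placed ~hotspot_offset_nt downstream (3'-ward) of a hotspot.

    The binding-site 3' terminus goes at target + offset, clamped to the
    reference 3' end (a clamped primer is flagged as merged with the 3'-end
    primer).  Search order: each shift (0, -1, +1 ... +-max_shift_nt) tries
    length extension 30..45 before moving to the next shift; the first
    candidate exceeding the Tm gate wins.
    """
    cfg = cfg or DesignConfig()
    if not (1 <= target_coord <= len(reference)):
        raise DesignError(
            f"{reference.id!r}: hotspot target {target_coord} out of bounds"
        )
    base_end = target_coord + cfg.hotspot_offset_nt
    merged = base_end >= len(reference)
    base_end = min(base_end, len(reference))
    best: tuple[float, str] | None = None
    for shift in _shift_order(cfg.max_shift_nt):
        end = base_end + shift
        if end > len(reference) or end < 1:
            continue
        for length in range(cfg.initial_length, cfg.max_length + 1):
            cand = _primer_at(reference, end, length, cfg)
            if cand is not None:
                start, end_, seq, tm = cand
                return BlockingPrimer(
                    name=f"{reference.id}_hs{target_coord}",
                    subunit_id=reference.id,
                    kind="hotspot",
                    ref_start=start,
                    ref_end=end_,
                    sequence=seq,
                    tm_C=tm,
                    shift=shift,
                    merged_with_three_prime=merged,
                )
            start = end - length + 1
            if start >= 1:
                window = reference.window(start, end)
                if "N" not in window:
                    tm = melting_temperature(window, cfg.thermo)
                    if best is None or tm > best[0]:
                        best = (tm, window)
    detail = f"best achieved {best[0]:.2f}" if best else "no valid window"
    raise DesignError(
        f"{reference.id!r}: no hotspot primer at target {target_coord} reaches "
        f"Tm > {cfg.min_tm_C} within +-{cfg.max_shift_nt} nt ({detail})"
    )


def design_rnaseh_probes(
    reference: NucleotideSequence,
    anchors: Sequence[int],
    cfg: DesignConfig | None = None,
) -> list[RNaseHProbe]:
    """One 50-nt sense-strand probe per anchor, window [anchor-49, anchor].

    Windows are clamped to stay in bounds; windows overlapping by >= 80% are
    merged, keeping the downstream window.  For the 3'-end anchor the probe is
    the terminal 50 sense bases.
    """
    cfg = cfg or DesignConfig()
    if len(reference) < PROBE_LENGTH:
        raise DesignError(
            f"{reference.id!r}: reference length {len(reference)} below probe "
            f"length {PROBE_LENGTH}"
        )
    windows: list[tuple[int, int, int]] = []  # (start, end, anchor)
    for anchor in anchors:
        if not (1 <= anchor <= len(reference)):
            raise DesignError(f"{reference.id!r}: anchor {anchor} out of bounds")
        start = max(1, anchor - PROBE_LENGTH + 1)
        start = min(start, len(reference) - PROBE_LENGTH + 1)
        windows.append((start, start + PROBE_LENGTH - 1, anchor))
    windows.sort()
    merged: list[tuple[int, int, int]] = []
    for win in windows:
        if merged:
            prev = merged[-1]
            overlap = min(prev[1], win[1]) - max(prev[0], win[0]) + 1
            if overlap >= PROBE_MERGE_OVERLAP * PROBE_LENGTH:
                merged[-1] = win  # keep the downstream window
                continue
        merged.append(win)
    return [
        RNaseHProbe(
            name=f"{reference.id}_probe{end}",
            subunit_id=reference.id,
            anchor=anchor,
            ref_start=start,
            ref_end=end,
            sequence=reference.window(start, end),
        )
        for start, end, anchor in merged
    ]


def design_species_panel(
    references: Sequence[NucleotideSequence],
    profiles: Mapping[str, CoverageProfile] | None = None,
    hotspot_cfg: HotspotConfig | None = None,
    design_cfg: DesignConfig | None = None,
    species_id: str = "species",
    validate: bool = True,
) -> SpeciesPanel:
    """Design the full panel for one species.

    Without coverage profiles the panel is the bootstrap mode: one 3'-end
    primer and one 3'-end probe per subunit.  With coverage, hotspot targets
    are detected per subunit and hotspot primers added; probes anchor at every
    blocking-primer binding-site 3' terminus.  Hotspot primers clamped into
    the 3'-end primer's territory are merged away rather than duplicated.
    """
    hotspot_cfg = hotspot_cfg or HotspotConfig()
    design_cfg = design_cfg or DesignConfig()
    primers: list[BlockingPrimer] = []
    probes: list[RNaseHProbe] = []
    targets_by_subunit: dict[str, tuple[int, ...]] = {}
    for ref in references:
        try:
            three_prime = design_three_prime_primer(ref, design_cfg)
            primers.append(three_prime)
            targets: list[int] = []
            profile = (profiles or {}).get(ref.id)
            if profile is not None and profile.total_reads > 0:
                targets = find_targets(profile, hotspot_cfg, len(ref))
            targets_by_subunit[ref.id] = tuple(targets)
            anchors = [len(ref)]
            for target in targets:
                primer = design_hotspot_primer(ref, target, design_cfg)
                if primer.merged_with_three_prime:
                    continue
                primers.append(primer)
                anchors.append(primer.ref_end)
            probes.extend(design_rnaseh_probes(ref, sorted(anchors), design_cfg))
        except DesignError as exc:
            raise DesignError(f"subunit {ref.id!r}: {exc}") from exc
    panel = SpeciesPanel(
        species_id=species_id,
        primers=tuple(primers),
        probes=tuple(probes),
        design_cfg=design_cfg,
        hotspot_cfg=hotspot_cfg,
        hotspot_targets=targets_by_subunit,
    )
    if validate:
        if len(panel.primers) > MAX_BLOCKING_PRIMERS_PER_SPECIES:
            raise PanelValidationError(
                f"{species_id}: {len(panel.primers)} blocking primers exceed "
                f"the {MAX_BLOCKING_PRIMERS_PER_SPECIES}-per-species ceiling"
            )
        if len(panel.probes) > MAX_PROBES_PER_SPECIES:
            raise PanelValidationError(
                f"{species_id}: {len(panel.probes)} probes exceed the "
                f"{MAX_PROBES_PER_SPECIES}-per-species ceiling"
            )
    return panel


def compose_blocking_mix(
    panel: SpeciesPanel,
    three_prime_total_uM: float = 50.0,
    hotspot_total_uM: float = 50.0,
) -> MixSpec:
    """Blocking primer mix: the 3'-end primers together at 50 µM and the
    hotspot primers together at 50 µM (total 100 µM).

    With no hotspot primers the mix is the 50 µM bootstrap mix of 3'-end
    primers only, flagged as such.
    """
    three_prime = panel.three_prime_primers
    hotspot = panel.hotspot_primers
    if not three_prime:
        raise ValueError("panel has no 3'-end primers")
    components: dict[str, float] = {}
    for p in three_prime:
        components[p.name] = three_prime_total_uM / len(three_prime)
    for p in hotspot:
        components[p.name] = hotspot_total_uM / len(hotspot)
    group_totals = {"three_prime": three_prime_total_uM}
    if hotspot:
        group_totals["hotspot"] = hotspot_total_uM
    return MixSpec(
        components=components,
        group_totals=group_totals,
        unit="uM",
        bootstrap=not hotspot,
    )


def compose_coculture_probe_mix(
    masses_ng: Mapping[str, float],
    groups: Mapping[str, str] | None = None,
) -> MixSpec:
    """Probe mix from per-probe masses (ng), with per-group subtotals.

    ``groups`` maps probe name -> group label (e.g. fungal_28S, bacterial);
    ungrouped probes fall into group "probes".
    """
    if not masses_ng:
        raise ValueError("no probe masses given")
    for name, mass in masses_ng.items():
        if mass <= 0:
            raise ValueError(f"probe {name!r}: mass must be positive")
    group_totals: dict[str, float] = {}
    for name, mass in masses_ng.items():
        group = (groups or {}).get(name, "probes")
        group_totals[group] = group_totals.get(group, 0.0) + mass
    return MixSpec(
        components=dict(masses_ng), group_totals=group_totals, unit="ng"
    )
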