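"""Primer/probe placement rules, Tm gating, panel assembly, mix arithmetic."""

import numpy as np
import pytest

from ribopanel.oligo_design import (
    DesignConfig,
    DesignError,
    PanelValidationError,
    compose_blocking_mix,
    compose_coculture_probe_mix,
    design_hotspot_primer,
    design_rnaseh_probes,
    design_species_panel,
    design_three_prime_primer,
)
from ribopanel.seqcore import (
    NucleotideSequence,
    melting_temperature,
    reverse_complement,
)


def _random_ref(seed: int, length: int, name: str = "ref") -> NucleotideSequence:
    rng = np.random.default_rng(seed)
    return NucleotideSequence(name, "".join(rng.choice(list("ACGT"), length)))


def _ref_with_tail(tail: str, length: int = 200, seed: int = 0) -> NucleotideSequence:
    body = _random_ref(seed, length - len(tail)).residues
    return NucleotideSequence("tailed", body + tail)


# ---------------------------------------------------------------- 3'-end primers

def test_gc_rich_three_prime_end_accepted_at_initial_length():
    ref = _ref_with_tail("GC" * 20)  # 40-nt GC tail; the 30-mer is hot enough
    primer = design_three_prime_primer(ref)
    assert primer.length == 30
    assert primer.ref_end == len(ref)
    assert primer.tm_C > 65.0


def test_at_rich_three_prime_end_extends_to_minimal_passing_length():
    # AT-leaning terminal 30-mer sits at 58 degC; the gate forces extension
    ref = _ref_with_tail("GAAATTGTGTTATATATGACAAGGGCTTGG", seed=3)
    primer = design_three_prime_primer(ref)
    assert 30 < primer.length <= 45
    assert primer.length == 38  # frozen from an independent length scan
    assert primer.tm_C > 65.0
    # oracle scan over lengths: every shorter window must fail the gate
    for length in range(30, primer.length):
        window = ref.residues[len(ref) - length :]
        assert melting_temperature(window) <= 65.0


def test_three_prime_primer_is_reverse_complement_of_terminal_window():
    ref = _random_ref(5, 300)
    primer = design_three_prime_primer(ref)
    window = ref.window(primer.ref_start, primer.ref_end)
    assert primer.sequence == reverse_complement(window)
    assert reverse_complement(primer.sequence) == window


def test_three_prime_primer_rejects_short_reference():
    with pytest.raises(DesignError):
        design_three_prime_primer(_random_ref(1, 25))


def test_three_prime_primer_reports_achieved_tm_on_failure():
    ref = NucleotideSequence("polyA", "AT" * 50)
    with pytest.raises(DesignError, match="best achieved"):
        design_three_prime_primer(ref)


# ---------------------------------------------------------------- hotspot primers

def test_hotspot_primer_placed_100nt_downstream_of_target():
    ref = _random_ref(8, 2000)
    primer = design_hotspot_primer(ref, 500)
    assert abs(primer.ref_end - 600) <= DesignConfig().max_shift_nt
    assert primer.tm_C > 65.0
    assert not primer.merged_with_three_prime


def test_hotspot_primer_near_three_prime_end_is_clamped_and_flagged():
    ref = _random_ref(8, 2000)
    primer = design_hotspot_primer(ref, 1970)  # 30 nt from the 3' end
    assert primer.ref_end <= len(ref)
    assert primer.merged_with_three_prime


def test_hotspot_primer_matches_shift_length_grid_oracle():
    """First hit of the documented search order: shifts 0,-1,+1..., lengths
    30..45 within each shift."""
    cfg = DesignConfig()
    for seed in range(6):
        ref = _random_ref(100 + seed, 1500)
        target = 700
        primer = design_hotspot_primer(ref, target, cfg)
        shifts = [0] + [s for k in range(1, 6) for s in (-k, k)]
        expected = None
        for shift in shifts:
            end = target + cfg.hotspot_offset_nt + shift
            for length in range(30, 46):
                window = ref.residues[end - length : end]
                if melting_temperature(window) > 65.0:
                    expected = (end - length + 1, end, shift)
                    break
            if expected:
                break
        assert (primer.ref_start, primer.ref_end, primer.shift) == expected


def test_hotspot_primer_sequence_roundtrips_to_reference():
    ref = _random_ref(21, 1200)
    primer = design_hotspot_primer(ref, 400)
    assert reverse_complement(primer.sequence) == ref.window(
        primer.ref_start, primer.ref_end
    )


# ---------------------------------------------------------------- RNase H probes

def test_probe_at_three_prime_anchor_covers_terminal_50():
    ref = _random_ref(2, 1542)
    (probe,) = design_rnaseh_probes(ref, [1542])
    assert (probe.ref_start, probe.ref_end) == (1493, 1542)
    assert probe.sequence == ref.residues[-50:]
    assert probe.length == 50


def test_probe_window_clamped_at_reference_start():
    ref = _random_ref(2, 300)
    (probe,) = design_rnaseh_probes(ref, [30])
    assert (probe.ref_start, probe.ref_end) == (1, 50)


def test_probes_with_80pct_overlap_are_merged():
    ref = _random_ref(2, 1000)
    probes = design_rnaseh_probes(ref, [600, 610])  # 41/50 shared > 80%
    assert len(probes) == 1
    assert probes[0].ref_end == 610  # downstream window kept
    probes = design_rnaseh_probes(ref, [600, 660])  # no merge below 80%
    assert len(probes) == 2


def test_probes_are_sense_strand_verbatim(default_panel, species):
    rrna, _ = species
    by_id = {r.id: r for r in rrna}
    for probe in default_panel.probes:
        ref = by_id[probe.subunit_id]
        assert probe.sequence == ref.window(probe.ref_start, probe.ref_end)
        assert probe.length == 50


def test_probe_rejects_short_reference():
    with pytest.raises(DesignError):
        design_rnaseh_probes(_random_ref(0, 49), [10])
    # a 5S-sized reference (120 nt) still qualifies
    assert design_rnaseh_probes(_random_ref(0, 120), [120])


# ---------------------------------------------------------------- species panels

def test_bootstrap_panel_without_coverage_has_one_oligo_pair_per_subunit(species):
    rrna, _ = species
    panel = design_species_panel(rrna, profiles=None)
    assert len(panel.primers) == 3
    assert all(p.kind == "three_prime" for p in panel.primers)
    assert len(panel.probes) == 3


def test_default_panel_respects_count_ceilings(default_panel):
    assert len(default_panel.primers) <= 10
    assert len(default_panel.probes) <= 10
    assert default_panel.n_oligos <= 20
    for sub, targets in default_panel.hotspot_targets.items():
        assert len(targets) <= 4


def test_every_panel_primer_roundtrips_and_passes_tm(default_panel, species):
    rrna, _ = species
    by_id = {r.id: r for r in rrna}
    for primer in default_panel.primers:
        ref = by_id[primer.subunit_id]
        assert reverse_complement(primer.sequence) == ref.window(
            primer.ref_start, primer.ref_end
        )
        assert primer.tm_C > 65.0
        if primer.kind == "three_prime":
            assert primer.ref_end == len(ref)


def test_panel_is_deterministic(species, rrna_profiles):
    rrna, _ = species
    a = design_species_panel(rrna, rrna_profiles)
    b = design_species_panel(rrna, rrna_profiles)
    assert a == b


def test_panel_validation_ceiling_enforced(species, rrna_profiles):
    rrna, _ = species
    from ribopanel.hotspots import HotspotConfig

    # an absurdly permissive config that multiplies hotspot primers
    greedy = HotspotConfig(max_targets_per_subunit=10, min_cluster_read_fraction=0.0)
    with pytest.raises(PanelValidationError):
        design_species_panel(rrna, rrna_profiles, hotspot_cfg=greedy)


# ---------------------------------------------------------------- mixes

def test_blocking_mix_splits_group_totals(default_panel):
    mix = compose_blocking_mix(default_panel)
    n3 = len(default_panel.three_prime_primers)
    nh = len(default_panel.hotspot_primers)
    assert n3 == 3 and nh > 0
    for p in default_panel.three_prime_primers:
        assert mix.components[p.name] == pytest.approx(50.0 / n3)
    for p in default_panel.hotspot_primers:
        assert mix.components[p.name] == pytest.approx(50.0 / nh)
    assert mix.total == pytest.approx(100.0)
    assert not mix.bootstrap


def test_bootstrap_blocking_mix_is_50uM_flagged(species):
    rrna, _ = species
    panel = design_species_panel(rrna, profiles=None)
    mix = compose_blocking_mix(panel)
    assert mix.total == pytest.approx(50.0)
    assert mix.bootstrap


def test_blocking_mix_requires_three_prime_primers(default_panel):
    from dataclasses import replace

    empty = replace(default_panel, primers=default_panel.hotspot_primers)
    with pytest.raises(ValueError):
        compose_blocking_mix(empty)


def test_coculture_probe_mix_sums_to_850ng():
    masses = {f"fungal_28S_{i}": 100.0 for i in range(2)}
    masses |= {f"fungal_18S_{i}": 50.0 for i in range(2)}
    masses["fungal_5.8S"] = 50.0
    masses |= {f"bacterial_{i}": 50.0 for i in range(10)}
    groups = {k: k.rsplit("_", 1)[0] if not k.startswith("bact") else "bacterial"
              for k in masses}
    mix = compose_coculture_probe_mix(masses, groups)
    assert mix.total == pytest.approx(850.0)
    assert mix.group_totals["fungal_28S"] == pytest.approx(200.0)
    assert mix.group_totals["bacterial"] == pytest.approx(500.0)


def test_probe_mix_trivia_and_validation():
    assert compose_coculture_probe_mix({"p": 50.0}).total == 50.0
    rng = np.random.default_rng(0)
    masses = {f"p{i}": float(m) for i, m in enumerate(rng.integers(10, 200, 13))}
    assert compose_coculture_probe_mix(masses).total == pytest.approx(
        sum(masses.values())
    )
    with pytest.raises(ValueError):
        compose_coculture_probe_mix({"p": -1.0})
    with pytest.raises(ValueError):
        compose_coculture_probe_mix({})
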