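"""Shared fixtures: one default synthetic species, built once per session."""

import pytest

from ribopanel.coverage import build_coverage
from ribopanel.fixtures import (
    FixtureConfig,
    synth_alignments,
    synth_fungal_scaffold,
    synth_references,
)
from ribopanel.oligo_design import design_species_panel

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def fixture_cfg():
    return FixtureConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def species(fixture_cfg):
    """(rRNA references, transcriptome) for the default synthetic species."""
    return synth_references(fixture_cfg)


@pytest.fixture(scope="session")
def alignments(fixture_cfg, species):
    rrna, genes = species
    return synth_alignments(fixture_cfg, rrna, genes)


@pytest.fixture(scope="session")
def rrna_profiles(species, alignments):
    rrna, _ = species
    lengths = {r.id: len(r) for r in rrna}
    mapped = [a for a in alignments if a.reference_id in lengths]
    return build_coverage(mapped, lengths)


@pytest.fixture(scope="session")
def default_panel(species, rrna_profiles):
    rrna, _ = species
    return design_species_panel(rrna, rrna_profiles)


@pytest.fixture(scope="session")
def fungal(fixture_cfg):
    """(scaffold, coverage profile, planted truth) for the rDNA repeat."""
    return synth_fungal_scaffold(fixture_cfg)
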