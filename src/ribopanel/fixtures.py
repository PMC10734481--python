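"""Seeded synthetic-data generators for every pipeline stage.

Everything here is synthetic and bit-reproducible under a fixed seed: rRNA
subunit references with a companion mRNA transcriptome, alignment sets whose
read-start geometry mimics a bootstrap depletion library (a dominant 3'-end
pileup, point-mass spikes at planted internal hotspots, and a sparse uniform
background), tandem-repeat scaffold coverage with known rRNA geometry, and
negative-binomial gene count tables.

The generators emit the same dialects the pipeline consumes (FASTA,
SAM-subset, TSV) and record the seed in every emitted file header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import AlignmentRecord, CoverageProfile
from .metrics import GeneCountTable
from .rrna_inference import SubunitSizeModel
from .seqcore import NucleotideSequence

__all__ = [
    "FixtureConfig",
    "FungalSpec",
    "synth_references",
    "synth_alignments",
    "synth_fungal_scaffold",
    "synth_counts",
    "config_hash",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# read geometry of a bootstrap (3'-end primers only) depletion library:
# most rRNA reads pile up at the 3' end and at a handful of internal hotspots.
# the background must stay sparse enough that chance candidates cannot chain
# across a cluster gap, or step-increase selection loses the planted truth
THREE_PRIME_WEIGHT = 0.30
BACKGROUND_WEIGHT = 0.002


@dataclass(frozen=True)
class FungalSpec:
    """Geometry of the synthetic tandem-repeat rDNA scaffold."""

    size_model: SubunitSizeModel = field(default_factory=SubunitSizeModel)
    repeat_count: int = 4
    intergenic_nt: int = 3500
    jitter_nt: int = 3
    block_width_nt: int = 150
    lead_in_nt: int = 1000
    background_depth: int = 2
    block_depth: int = 50

    @property
    def period_nt(self) -> int:
        m = self.size_model
        return m.small_nt + m.short_nt + m.large_nt + self.intergenic_nt


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic species.

    Subunit lengths default to 16S/23S/5S-like (1542/2904/120 nt).  Hotspot
    spikes sit on the two large subunits only; the 5S-like subunit is too
    short to warrant internal targets.  ``rrna_read_fraction`` defaults to the
    heavily rRNA-dominated regime (>80% of reads) these libraries start from.
    """

    seed: int = 7
    subunit_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"rrna_16S": 1542, "rrna_23S": 2904, "rrna_5S": 120}
    )
    subunit_read_weights: Mapping[str, float] = field(
        default_factory=lambda: {"rrna_16S": 0.40, "rrna_23S": 0.55, "rrna_5S": 0.05}
    )
    hotspot_spec: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "rrna_16S": (370, 820, 1150),
            "rrna_23S": (450, 1100, 1750, 2300),
        }
    )
    n_reads: int = 5000
    read_length: int = 51
    rrna_read_fraction: float = 0.85
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (300, 1500)
    spike_smear_nt: int = 0
    plant_off_target: bool = False
    fungal_spec: FungalSpec = field(default_factory=FungalSpec)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rrna_read_fraction <= 1.0):
            raise ValueError("rrna_read_fraction must be in [0, 1]")
        if any(v <= 0 for v in self.subunit_lengths.values()):
            raise ValueError("subunit lengths must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for sub, coords in self.hotspot_spec.items():
            length = self.subunit_lengths[sub]
            for c in coords:
                if not (1 <= c <= length - self.read_length + 1):
                    raise ValueError(
                        f"spike coordinate {c} out of bounds on {sub!r}"
                    )


def config_hash(cfg: FixtureConfig) -> str:
    """Short stable hash of the full fixture configuration."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def synth_references(
    cfg: FixtureConfig,
) -> tuple[list[NucleotideSequence], list[NucleotideSequence]]:
    """Random GC~50% rRNA subunits plus an mRNA transcriptome.

    No transcript shares a >=15-nt substring with the rRNA oligo-design
    windows (3'-end and hotspot neighborhoods) unless ``plant_off_target`` is
    set, in which case transcript gene_0001 carries a verbatim 30-nt copy of
    the 16S-like 3'-end window.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    tag = f"seed={cfg.seed} cfg={config_hash(cfg)}"
    rrna = [
        NucleotideSequence(name, _random_seq(rng, length), description=tag)
        for name, length in cfg.subunit_lengths.items()
    ]
    # design-relevant windows: terminal 60 nt plus +-150 nt around each spike
    forbidden: set[str] = set()
    for ref in rrna:
        forbidden |= _kmers(ref.residues[-60:], 15)
        for coord in cfg.hotspot_spec.get(ref.id, ()):
            lo = max(0, coord - 150)
            hi = min(len(ref), coord + 150)
            forbidden |= _kmers(ref.residues[lo:hi], 15)
    lo_len, hi_len = cfg.gene_length_range
    genes: list[NucleotideSequence] = []
    for i in range(cfg.n_genes):
        length = int(rng.integers(lo_len, hi_len + 1))
        for _ in range(50):
            seq = _random_seq(rng, length)
            if not (_kmers(seq, 15) & forbidden):
                break
        else:  # pragma: no cover - vanishingly unlikely with random 15-mers
            raise RuntimeError("could not draw a transcript avoiding rRNA 15-mers")
        genes.append(
            NucleotideSequence(f"gene_{i + 1:04d}", seq, description=tag)
        )
    if cfg.plant_off_target:
        donor = rrna[0].residues[-50:-20]  # 30 nt from the 16S-like 3' window
        victim = genes[0]
        planted = donor + victim.residues[30:]
        genes[0] = NucleotideSequence(
            victim.id, planted, description=f"{tag} planted_off_target"
        )
    return rrna, genes


def _subunit_position_sampler(
    cfg: FixtureConfig, subunit: str, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw n read-start positions on one rRNA subunit.

    Mixture: THREE_PRIME_WEIGHT at the 3'-end pileup (starts in the last
    read-length window), BACKGROUND_WEIGHT uniform, remainder split equally
    over the planted spikes (absent spikes fold into the 3'-end mass).
    """
    length = cfg.subunit_lengths[subunit]
    max_start = length - cfg.read_length + 1
    spikes = cfg.hotspot_spec.get(subunit, ())
    tp_w = THREE_PRIME_WEIGHT if spikes else 1.0 - BACKGROUND_WEIGHT
    spike_w = (1.0 - tp_w - BACKGROUND_WEIGHT) / len(spikes) if spikes else 0.0
    probs = [tp_w, BACKGROUND_WEIGHT] + [spike_w] * len(spikes)
    choice = rng.choice(len(probs), size=n, p=np.asarray(probs) / sum(probs))
    positions = np.empty(n, dtype=np.int64)
    tp_mask = choice == 0
    positions[tp_mask] = max_start - rng.integers(0, 6, size=int(tp_mask.sum()))
    bg_mask = choice == 1
    positions[bg_mask] = rng.integers(1, max_start + 1, size=int(bg_mask.sum()))
    for k, coord in enumerate(spikes):
        mask = choice == k + 2
        pos = np.full(int(mask.sum()), coord, dtype=np.int64)
        if cfg.spike_smear_nt:
            pos += rng.integers(
                -cfg.spike_smear_nt, cfg.spike_smear_nt + 1, size=pos.size
            )
        positions[mask] = np.clip(pos, 1, max_start)
    return positions


def synth_alignments(
    cfg: FixtureConfig,
    rrna: Sequence[NucleotideSequence],
    transcriptome: Sequence[NucleotideSequence],
) -> list[AlignmentRecord]:
    """Simulated alignment records over rRNA subunits and mRNA transcripts.

    rRNA reads follow the bootstrap-library start geometry; mRNA reads fall
    uniformly on length-weighted transcripts.  The realized rRNA fraction is
    binomial around ``rrna_read_fraction``.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    rrna_by_id = {r.id: r for r in rrna}
    for sub in cfg.subunit_read_weights:
        if sub not in rrna_by_id:
            raise ValueError(f"unknown subunit {sub!r} in read weights")
    records: list[AlignmentRecord] = []
    is_rrna_read = rng.random(cfg.n_reads) < cfg.rrna_read_fraction
    n_rrna = int(is_rrna_read.sum())
    subs = list(cfg.subunit_read_weights)
    weights = np.array([cfg.subunit_read_weights[s] for s in subs], dtype=float)
    sub_choice = rng.choice(len(subs), size=n_rrna, p=weights / weights.sum())
    read_no = 0
    for si, sub in enumerate(subs):
        n_sub = int((sub_choice == si).sum())
        positions = _subunit_position_sampler(cfg, sub, rng, n_sub)
        for pos in positions.tolist():
            read_no += 1
            records.append(
                AlignmentRecord(
                    f"read_{read_no:06d}", sub, pos, cfg.read_length, True
                )
            )
    n_mrna = cfg.n_reads - n_rrna
    lengths = np.array([len(g) for g in transcriptome], dtype=float)
    eligible = lengths >= cfg.read_length
    gene_p = np.where(eligible, lengths, 0.0)
    gene_choice = rng.choice(len(transcriptome), size=n_mrna, p=gene_p / gene_p.sum())
    for gi in gene_choice.tolist():
        gene = transcriptome[gi]
        read_no += 1
        pos = int(rng.integers(1, len(gene) - cfg.read_length + 2))
        records.append(
            AlignmentRecord(f"read_{read_no:06d}", gene.id, pos, cfg.read_length, True)
        )
    return records


def synth_fungal_scaffold(
    cfg: FixtureConfig,
) -> tuple[NucleotideSequence, CoverageProfile, dict]:
    """Tandem-repeat rDNA scaffold coverage with known subunit geometry.

    Each repeat lays the subunits contiguously in the size model's order, so
    consecutive block summits (at the subunit 3' ends) are spaced by the
    subunit lengths.  Every subunit 3' end carries a high-coverage block of
    ``block_width_nt`` ending at the (jittered) subunit end over a low uniform
    background.  Returns (scaffold sequence, coverage profile, truth) where
    truth holds the planted per-repeat anchor coordinates and repeat count.
    """
    spec = cfg.fungal_spec
    rng = np.random.default_rng([cfg.seed, 3])
    model = spec.size_model
    sizes = [model.size_of(label) for label in model.order]
    scaffold_len = spec.lead_in_nt + spec.repeat_count * spec.period_nt + 1000
    depth = np.full(scaffold_len, spec.background_depth, dtype=np.int64)
    starts = np.zeros(scaffold_len, dtype=np.int64)
    anchors: list[dict[str, int]] = []
    for r in range(spec.repeat_count):
        offset = spec.lead_in_nt + r * spec.period_nt
        cum = 0
        repeat_anchors: dict[str, int] = {}
        for label, size in zip(model.order, sizes):
            cum += size
            end = offset + cum
            if spec.jitter_nt:
                end += int(rng.integers(-spec.jitter_nt, spec.jitter_nt + 1))
            block_lo = end - spec.block_width_nt + 1
            depth[block_lo - 1 : end] = spec.block_depth
            starts[end - 1] = 30
            starts[end - 1 - spec.block_width_nt // 2] = 2
            repeat_anchors[label] = end
        anchors.append(repeat_anchors)
    scaffold = NucleotideSequence(
        "scaffold_synthetic",
        _random_seq(rng, scaffold_len),
        description=f"seed={cfg.seed} cfg={config_hash(cfg)} synthetic rDNA repeat",
    )
    profile = CoverageProfile("scaffold_synthetic", scaffold_len, starts, depth)
    truth = {
        "repeat_count": spec.repeat_count,
        "anchors": anchors,
        "first_repeat_anchors": anchors[0],
    }
    return scaffold, profile, truth


def synth_counts(
    cfg: FixtureConfig,
    n_samples_per_group: int = 3,
    mean_expression: float = 50.0,
    mean_sigma: float = 1.0,
    dispersion: float = 0.1,
    planted_log2fc: Mapping[str, float] | None = None,
    n_rrna_genes: int = 2,
    rrna_mean: float = 20000.0,
) -> GeneCountTable:
    """Negative-binomial gene count table with two sample groups (A/B).

    Per-gene means are lognormal around ``mean_expression``; ``planted_log2fc``
    shifts named genes in group B.  ``dispersion`` -> 0 approaches Poisson.
    The first ``n_rrna_genes`` rows are rRNA-flagged high-count genes.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    gene_ids = [f"gene_{i + 1:04d}" for i in range(cfg.n_genes)]
    mu = mean_expression * rng.lognormal(0.0, mean_sigma, size=cfg.n_genes)
    mu[:n_rrna_genes] = rrna_mean
    samples = [f"A{i + 1}" for i in range(n_samples_per_group)] + [
        f"B{i + 1}" for i in range(n_samples_per_group)
    ]
    data: dict[str, np.ndarray] = {}
    for sample in samples:
        m = mu.copy()
        if sample.startswith("B") and planted_log2fc:
            for gene, lfc in planted_log2fc.items():
                m[gene_ids.index(gene)] *= 2.0**lfc
        if dispersion > 0:
            size = 1.0 / dispersion
            p = size / (size + m)
            data[sample] = rng.negative_binomial(size, p)
        else:
            data[sample] = rng.poisson(m)
    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene"))
    df["organism"] = "bacteria"
    df["is_rrna"] = [i < n_rrna_genes for i in range(cfg.n_genes)]
    return GeneCountTable(df)
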