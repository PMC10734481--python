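"""Nucleotide sequence primitives: FASTA I/O, reverse complement, melting temperature.

Sequences are stored uppercase over the DNA alphabet {A, C, G, T}; RNA input is
normalized (U -> T) on ingest so rRNA references supplied as RNA work
transparently.  Melting temperatures are computed under nearest-neighbor
thermodynamics (unified dH/dS parameter set) with a logarithmic monovalent-salt
correction; the model and its conditions live in :class:`ThermoConfig` because
the >65 degC design gate depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "NucleotideSequence",
    "ThermoConfig",
    "SequenceError",
    "reverse_complement",
    "melting_temperature",
    "read_fasta",
    "write_fasta",
]

_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")

MIN_TM_LENGTH = 8


class SequenceError(ValueError):
    """Invalid sequence content or length."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence.

    Residues are canonical uppercase {A,C,G,T}; ``N`` is admitted only when
    constructed with ``permissive=True`` (windows containing N are ineligible
    for oligo design downstream).
    """

    id: str
    residues: str
    description: str = ""
    permissive: bool = False

    def __post_init__(self) -> None:
        raw = self.residues.upper().replace("U", "T")
        alphabet = _DNA_N if self.permissive else _DNA
        if not raw:
            raise SequenceError(f"{self.id!r}: empty sequence")
        for i, base in enumerate(raw):
            if base not in alphabet:
                raise SequenceError(
                    f"{self.id!r}: invalid residue {base!r} at position {i + 1}"
                )
        object.__setattr__(self, "residues", raw)

    def __len__(self) -> int:
        return len(self.residues)

    def window(self, start: int, end: int) -> str:
        """Sense-strand substring, 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self)):
            raise SequenceError(
                f"{self.id!r}: window [{start},{end}] out of bounds (length {len(self)})"
            )
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class ThermoConfig:
    """Conditions for nearest-neighbor duplex Tm.

    monovalent_salt_mM: Na+ equivalent concentration (mM).
    oligo_conc_nM: total oligo strand concentration (nM), template in excess.
    parameter_set: identifier of the NN dH/dS table ('unified' = the unified
        DNA/DNA parameter set).
    """

    model: str = "nearest_neighbor"
    monovalent_salt_mM: float = 50.0
    oligo_conc_nM: float = 250.0
    parameter_set: str = "unified"

    def __post_init__(self) -> None:
        if self.monovalent_salt_mM <= 0:
            raise ValueError("monovalent_salt_mM must be positive")
        if self.oligo_conc_nM <= 0:
            raise ValueError("oligo_conc_nM must be positive")
        if self.model != "nearest_neighbor":
            raise ValueError(f"unknown Tm model {self.model!r}")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: NucleotideSequence | str) -> NucleotideSequence | str:
    """Watson-Crick reverse complement; an involution."""
    if isinstance(seq, str):
        return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]
    return NucleotideSequence(
        id=seq.id,
        residues=seq.residues.translate(_COMPLEMENT)[::-1],
        description=seq.description,
        permissive=seq.permissive,
    )


def melting_temperature(seq: NucleotideSequence | str, cfg: ThermoConfig | None = None) -> float:
    """Duplex Tm (degC) of ``seq`` against its perfect complement.

    Nearest-neighbor model with the unified dH/dS table and the entropic
    log-salt correction dS += 0.368 (N-1) ln[Na+].  Invariant under reverse
    complementation (a duplex and its complement are the same duplex).
    """
    cfg = cfg or ThermoConfig()
    residues = seq if isinstance(seq, str) else seq.residues
    residues = residues.upper().replace("U", "T")
    if len(residues) < MIN_TM_LENGTH:
        raise SequenceError(
            f"sequence of length {len(residues)} below Tm minimum {MIN_TM_LENGTH}"
        )
    if "N" in residues:
        raise SequenceError("N residues are not allowed in Tm computation")
    return float(
        _mt.Tm_NN(
            Seq(residues),
            nn_table=_mt.DNA_NN3,
            Na=cfg.monovalent_salt_mM,
            K=0,
            Tris=0,
            Mg=0,
            dNTPs=0,
            dnac1=cfg.oligo_conc_nM,
            dnac2=0,
            selfcomp=False,
            saltcorr=5,
        )
    )


def read_fasta(path: str | Path, permissive: bool = False) -> list[NucleotideSequence]:
    """Read a multi-record FASTA into NucleotideSequences (any line wrap)."""
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise SequenceError(f"record {idx + 1}: malformed/empty header")
        if rec.id in seen:
            raise SequenceError(f"record {idx + 1}: duplicate id {rec.id!r}")
        if len(rec.seq) == 0:
            raise SequenceError(f"record {idx + 1} ({rec.id!r}): empty record")
        try:
            records.append(
                NucleotideSequence(
                    id=rec.id,
                    residues=str(rec.seq),
                    description=rec.description[len(rec.id) :].strip(),
                    permissive=permissive,
                )
            )
        except SequenceError as exc:
            raise SequenceError(f"record {idx + 1}: {exc}") from exc
        seen.add(rec.id)
    return records


def write_fasta(
    sequences: Iterable[NucleotideSequence], path: str | Path, wrap: int = 70
) -> None:
    """Write sequences as FASTA; roundtrips ids and residues exactly."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with open(path, "w") as handle:
        for seq in sequences:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(seq.residues), wrap):
                handle.write(seq.residues[i : i + wrap] + "\n")
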