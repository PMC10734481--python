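"""Off-target screening of designed oligos against a transcriptome.

For each oligo the screen finds the maximal-scoring ungapped local alignment
(match +1, mismatch -2 by default) against every transcript on both strands —
exhaustively over all offsets, with no heuristic seeding: oligos are <= 50 nt
and transcriptomes at screening scale are small, so the O(m*n) search is
cheap.  Significance uses the Karlin-Altschul expectation

    E = K * m * n * exp(-lambda * S)

with the published ungapped lambda/K for +1/-2 scoring, and the database
length n counts both strands.  An oligo passes when its best E-value is below
``evalue_max`` (default 1.0) AND its longest consecutive exact-match run is
strictly below ``run_max_nt`` (default 15, i.e. runs <= 14 pass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqcore import NucleotideSequence, reverse_complement

__all__ = [
    "ScreenConfig",
    "SpecificityVerdict",
    "best_ungapped_local_score",
    "longest_exact_run",
    "evalue",
    "screen_panel",
]

# published Karlin-Altschul parameters for ungapped +1/-2 nucleotide scoring
DEFAULT_LAMBDA = 1.28
DEFAULT_KAPPA = 0.46


@dataclass(frozen=True)
class ScreenConfig:
    match_score: int = 1
    mismatch_score: int = -2
    ka_lambda: float = DEFAULT_LAMBDA
    ka_kappa: float = DEFAULT_KAPPA
    evalue_max: float = 1.0
    run_max_nt: int = 15  # pass requires longest run strictly below this

    def __post_init__(self) -> None:
        if not (self.match_score > 0 > self.mismatch_score):
            raise ValueError("need match_score > 0 > mismatch_score")
        if self.ka_lambda <= 0 or self.ka_kappa <= 0:
            raise ValueError("lambda and kappa must be positive")


@dataclass(frozen=True)
class SpecificityVerdict:
    oligo_name: str
    best_evalue: float
    longest_run_nt: int
    worst_transcript_id: str
    passed: bool


_ENCODE = {ord(b): i for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


def _as_string(seq: NucleotideSequence | str) -> str:
    return seq if isinstance(seq, str) else seq.residues


def _diagonal_matrix(oligo: str, transcript: str) -> np.ndarray:
    """Boolean match indicators arranged so each column is one alignment
    diagonal.

    Row i holds oligo base i compared against the transcript, right-shifted by
    i; column d then reads down a single ungapped diagonal.  N never matches.
    """
    m, n = len(oligo), len(transcript)
    q = _encode(oligo)
    t = _encode(transcript)
    width = n + m - 1
    mat = np.zeros((m, width), dtype=bool)
    for i in range(m):
        # oligo[i] vs transcript[j] lands in column j + (m - 1 - i)
        eq = (t == q[i]) & (t != ord("N"))
        mat[i, m - 1 - i : m - 1 - i + n] = eq
    return mat


def _best_score_one_strand(
    oligo: str, transcript: str, match: int, mismatch: int
) -> tuple[int, int]:
    """(best ungapped local score, transcript 0-based end position)."""
    mat = _diagonal_matrix(oligo, transcript)
    scores = np.where(mat, match, mismatch).astype(np.int64)
    m = len(oligo)
    width = scores.shape[1]
    running = np.zeros(width, dtype=np.int64)
    best = np.zeros(width, dtype=np.int64)
    best_row = np.zeros(width, dtype=np.int64)
    # Kadane down each column; rows beyond the transcript span score as
    # mismatches but can only lower a running sum, never create a maximum
    # outside the valid overlap.
    for i in range(m):
        running = np.maximum(running + scores[i], scores[i])
        improved = running > best
        best = np.where(improved, running, best)
        best_row[improved] = i
    col = int(np.argmax(best))
    # transcript index of the alignment end: row i in column col matches
    # transcript position col - (m - 1 - i)
    end_pos = col - (m - 1 - int(best_row[col]))
    return int(best.max()), end_pos


def best_ungapped_local_score(
    oligo: NucleotideSequence | str,
    transcript: NucleotideSequence | str,
    cfg: ScreenConfig | None = None,
) -> tuple[int, dict]:
    """Maximal ungapped local alignment score over all offsets, both strands.

    Returns (score, location) where location records the strand and the
    0-based transcript coordinate of the alignment end on that strand.
    """
    cfg = cfg or ScreenConfig()
    q = _as_string(oligo)
    t = _as_string(transcript)
    if not q or not t:
        raise ValueError("empty oligo or transcript")
    fwd, fwd_end = _best_score_one_strand(q, t, cfg.match_score, cfg.mismatch_score)
    rev, rev_end = _best_score_one_strand(
        q, reverse_complement(t), cfg.match_score, cfg.mismatch_score
    )
    if fwd >= rev:
        return fwd, {"strand": "+", "end": fwd_end}
    return rev, {"strand": "-", "end": rev_end}


def _longest_run_one_strand(oligo: str, transcript: str) -> int:
    mat = _diagonal_matrix(oligo, transcript)
    width = mat.shape[1]
    run = np.zeros(width, dtype=np.int64)
    best = 0
    for i in range(mat.shape[0]):
        run = np.where(mat[i], run + 1, 0)
        best = max(best, int(run.max(initial=0)))
    return best


def longest_exact_run(
    oligo: NucleotideSequence | str, transcript: NucleotideSequence | str
) -> int:
    """Longest common substring length between oligo and transcript, either
    strand."""
    q = _as_string(oligo)
    t = _as_string(transcript)
    if not q or not t:
        return 0
    return max(
        _longest_run_one_strand(q, t),
        _longest_run_one_strand(q, reverse_complement(t)),
    )


def evalue(
    score: float, oligo_len: int, db_len: int, cfg: ScreenConfig | None = None
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    cfg = cfg or ScreenConfig()
    if oligo_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    if score < 0:
        raise ValueError("score must be >= 0")
    return cfg.ka_kappa * oligo_len * db_len * math.exp(-cfg.ka_lambda * score)


def screen_panel(
    oligos: Sequence,
    transcriptome: Sequence[NucleotideSequence],
    cfg: ScreenConfig | None = None,
    rrna_ids: Iterable[str] = (),
) -> list[SpecificityVerdict]:
    """Screen every panel oligo against a transcriptome.

    The transcriptome must exclude the rRNA references themselves (they are
    the intended targets); any transcript id listed in ``rrna_ids`` found in
    the transcriptome raises.  The database length for E-values is the total
    transcriptome length times two (both strands).
    """
    cfg = cfg or ScreenConfig()
    if not transcriptome:
        raise ValueError("empty transcriptome")
    forbidden = set(rrna_ids) & {t.id for t in transcriptome}
    if forbidden:
        raise ValueError(
            f"transcriptome contains rRNA references {sorted(forbidden)!r}; "
            "exclude the intended targets before screening"
        )
    db_len = 2 * sum(len(t) for t in transcriptome)
    verdicts: list[SpecificityVerdict] = []
    for oligo in oligos:
        name = getattr(oligo, "name", None) or getattr(oligo, "id", "oligo")
        seq = getattr(oligo, "sequence", None) or _as_string(oligo)
        best_e = math.inf
        worst_id = ""
        longest = 0
        best_score = -1
        for transcript in transcriptome:
            score, _ = best_ungapped_local_score(seq, transcript, cfg)
            run = longest_exact_run(seq, transcript)
            longest = max(longest, run)
            if score > best_score:
                best_score = score
                worst_id = transcript.id
        best_e = evalue(best_score, len(seq), db_len, cfg)
        verdicts.append(
            SpecificityVerdict(
                oligo_name=name,
                best_evalue=best_e,
                longest_run_nt=longest,
                worst_transcript_id=worst_id,
                passed=(best_e < cfg.evalue_max and longest < cfg.run_max_nt),
            )
        )
    return verdicts
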