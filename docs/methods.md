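# Methods

## The design procedure

`ribopanel` operationalizes a depletion-oligo design workflow whose target is
the residual rRNA signal in a sequencing library. The library's rRNA reads
are summarized as a per-position count of read starts along each subunit
("step increases" of the cumulative read distribution). The design pipeline
is a deterministic ranking heuristic, not a statistical peak caller — there
is no background model, and we implement it as such:

1. **Candidates.** The top 50 coordinates by read-start count
   (`HotspotConfig.top_k`). If fewer positions are covered, all are taken.
2. **Clusters.** Candidates sorted 5′→3′ are split wherever consecutive
   coordinates are more than `cluster_gap_nt` = 100 nt apart. We chose a
   fixed gap over 1-D Jenks/natural-breaks optimization: it is deterministic,
   has one interpretable parameter, and real hotspot clusters are separated
   by gaps far larger than their internal spread. The gap is recorded in
   every report.
3. **Selection.** Clusters are ranked by summed read counts. A cluster must
   hold at least `min_cluster_read_fraction` = 1% of the subunit's mapped
   reads, at most `max_targets_per_subunit` = 4 targets are kept, and each
   target is its cluster's 3′-most member. There is no principled published
   cutoff separating "top clusters" from the rest, so both knobs are exposed
   configuration with these defaults rather than hidden constants. Clusters
   whose target lies within one cluster gap of the reference 3′ end are
   absorbed into the 3′-end primer's territory and emit no extra oligo.
4. **Ties** (equal counts, equal cluster totals) always break toward the
   3′-most coordinate, matching the downstream placement preference of the
   primer design itself.

## Oligo placement rules

**Blocking primers** bind the sense reference, so their sequence is the
reverse complement of the binding window. The 3′-end primer's window ends
exactly at the subunit terminus; a hotspot primer's window ends 100 nt
(`hotspot_offset_nt`) downstream of its target, clamped to the terminus
(a clamped primer duplicates the 3′-end primer and is merged away). Windows
start at 30 nt (`initial_length`) and grow 5′-ward one base at a time —
keeping the 3′ terminus anchored, which is what matters for priming — until
the duplex Tm exceeds `min_tm_C` = 65 °C, to a hard cap of 45 nt
(`max_length`). Hotspot primers that cannot reach the gate by extension also
try anchor shifts in the order 0, −1, +1, … ±5 (`max_shift_nt`), lengths
before shifts, first hit wins; the shift is recorded. The length cap and
shift bound are our bounds on "approximately 30 nt" and "a few bases"; both
are configurable. Design failure raises with the best Tm achieved.

**RNase H probes** target the antisense amplified RNA, so they are verbatim
sense-strand copies, always exactly 50 nt, with no Tm gate (length and exact
match are the only constraints). Each probe window ends at its anchor (a
primer binding-site 3′ terminus or the subunit end) so that cleavage removes
the adapter-proximal end of the amplified RNA; windows are clamped in bounds
and windows overlapping ≥ 80% are merged, keeping the downstream one.
Windows containing N are ineligible.

A full species panel is validated against the ceilings the protocol was
designed around: ≤ 10 blocking primers and ≤ 10 probes per species. Without
coverage data the panel is the bootstrap mode — 3′-end oligos only — which
is exactly how a first library is made before hotspots can be measured.

## Melting temperature

No specific Tm calculator is canonical for the > 65 °C gate, so the model is
explicit configuration (`ThermoConfig`), logged in every panel manifest:
nearest-neighbor thermodynamics with the unified DNA/DNA ΔH/ΔS parameter
set, the entropic log-salt correction ΔS += 0.368 (N−1) ln[Na⁺], defaults
50 mM Na⁺ and 250 nM oligo (template in excess). The computation is
delegated to Biopython's `MeltingTemp.Tm_NN`; the test suite pins it against
an independently hand-summed oracle to 10⁻⁶ °C.

One property worth knowing: extending a primer with G/C raises Tm throughout
the design-relevant regime, but it is *not* a theorem — at 50 mM Na⁺ the
marginal G/C stack's ΔH/ΔS ratio corresponds to ≈ 71 °C, so a duplex already
hotter than that can lose a fraction of a degree. The monotonicity test is
therefore restricted to primers below 70 °C; the 65 °C gate sits safely
inside that regime.

## Specificity screen

Oligos are ≤ 50 nt and screening-scale transcriptomes are small, so instead
of a seeded heuristic search the screen computes the exact maximal ungapped
local alignment (match +1, mismatch −2) over all offsets and both strands,
via per-diagonal maximum-subarray scans. Significance uses the
Karlin–Altschul expectation E = K·m·n·e^(−λS) with the published ungapped
parameters for +1/−2 scoring (λ = 1.28, K = 0.46), database length = total
transcriptome × 2 strands. An oligo passes when best E < 1 *and* the longest
consecutive exact match is < 15 nt (14 passes, 15 fails).

Two caveats are documented rather than hidden. First, with an exhaustive
search the best chance score grows like ln(K·m·n)/λ, so at whole-
transcriptome database scale chance-level hits land near E ≈ 1 and a
substantial fraction of perfectly sound oligos fail the E gate; the run-length
rule is the binding constraint in practice, and E-gated rejections at
database scale should be read as conservative. Second, E-values here
approximate, not reproduce, BLAST's (no finite-size edge corrections).
Failed oligos are reported with their worst transcript; redesign is advice,
never an automatic loop, so the audit trail stays intact.

## Unannotated rRNA locus inference

Eukaryotic rDNA sits in tandem repeats; on a genome scaffold the subunits
appear as a periodic series of high-coverage blocks. Blocks are maximal runs
of depth ≥ `min_fold` = 5 × the median depth over covered positions — the
median, not the mean, so the spikes cannot inflate their own threshold.
Consecutive block triplets are labeled when inter-summit spacings match the
expected subunit sizes: defaults small 1800 nt (18S-like), short 160 nt
(5.8S-like), large 3400 nt (28S-like), relative tolerance 0.35, reading
order small→short→large — the canonical rDNA order, but the matcher is
size-model-agnostic and the order configurable because block identity cannot
be proven from coverage alone. Triplets with consistent periods group into
one locus with a repeat count (repeats arise when multi-mapping reads are
allowed); probe anchors are the block 3′ ends of the *first* repeat.
Transcription is assumed left→right unless a reverse-strand flag is given
(anchors then use block starts); the flag is recorded with the result.

## Library metrics

rRNA percent is rRNA-mapped reads over total organism-mapped reads × 100.
RPM excludes rRNA genes from numerator and denominator and conserves 10⁶ per
sample. Detection curves count genes strictly *above* each threshold
("above" semantics), after downsampling that draws reads without replacement
(multivariate hypergeometric over gene counts) — sampling reads, not gene
totals. The expression filter keeps genes at RPM ≥ the minimum in *all*
samples ("at least" semantics, boundary inclusive; a strict comparator is
available). Library correlation defaults to Pearson r on log₁₀(RPM + 1) with
a linear-space option, and the transform choice is part of the reported
result since the two differ materially on skewed expression data.

## Synthetic data: what it emulates, what it does not

The generators produce the study conditions the pipeline is designed for:
an rRNA-dominated library (85% rRNA reads by default) over 16S/23S/5S-like
subunits (1542/2904/120 nt). Read starts on each subunit follow a mixture of
a dominant 3′-end pileup (30% — what a bootstrap 3′-end-primer library
shows), point-mass spikes at planted hotspot coordinates (3 on the 16S-like,
4 on the 23S-like, none on the 120-nt subunit, which barely exceeds one
primer+probe footprint), and a sparse 0.2% uniform background. The
background is deliberately sparse: the step-increase procedure presumes
hotspot-dominated coverage, and a dense noise floor would let chance
candidates chain across cluster gaps and displace targets from the planted
truth the recovery suite checks. Default depth is 5,000 reads — enough for
spike counts to dwarf noise while the full pipeline runs in seconds; the
acceptance script uses the same size. Transcripts (100 genes, 300–1500 nt,
GC ≈ 50%) are re-drawn if they share any 15-mer with an rRNA design window,
so off-targets exist only when explicitly planted.

Real libraries differ in ways these fixtures do not model: 3′-biased
background decay, sequence-dependent coverage, PCR duplicates, quality
scores, multi-mapping within a genome, and hotspot spikes with realistic
width. Passing tests therefore demonstrate that the rules are implemented
exactly and that planted structure is recovered under the stated geometry —
not that the defaults are tuned for any particular real organism.

The tandem-repeat scaffold lays the subunits contiguously per repeat with a
3.5-kb intergenic spacer (period ≈ 8.9 kb), a 150-nt coverage block ending
at each (±3 nt jittered) subunit 3′ end at 25× the background depth, and
records the planted anchors as ground truth; recovery is required to ±5 nt
for repeat counts 1–6.

## Numerical and degenerate-input conventions

- Coordinates are 1-based inclusive in every external file and report;
  internal arrays are 0-based. BED output is 0-based half-open.
- U→T normalization and uppercase canonicalization on ingest; ambiguity
  codes rejected unless a permissive flag admits N (N windows are never
  designable).
- Downsampling is a seeded shuffle without replacement; all generator
  randomness flows from one seed via independent substreams, and outputs are
  byte-reproducible.
- Zero mapped reads: cumulative distributions and rRNA percent raise;
  pileup-block finding returns empty.
- Mix arithmetic: group totals (3′-end primers 50 µM + hotspot primers
  50 µM) are split equally within each group; a hotspot-free mix totals
  50 µM and is flagged bootstrap.

## Known limitations

- SAM support is a text-only subset (header + 11 mandatory columns, flags
  read for mapped/unmapped only); no BAM, no split alignments.
- No primer-dimer, hairpin, or secondary-structure checks; no vendor export.
- The screen is ungapped by design; gapped off-targets with short exact
  seeds would be under-scored (they are also poor hybridization targets).
- Inferred rRNA loci are coverage-geometric hypotheses; they carry no
  covariance-model evidence and deserve orthogonal confirmation before use.
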