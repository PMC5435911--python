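# Methods

## The measurement problem

Mitochondrial genomes are transcribed as two genome-length polycistronic
precursors; individual rRNAs, mRNAs and tRNAs are released by excision of
the interleaved tRNAs (the tRNA punctuation model, with RNase P cutting
tRNA 5' ends and RNase Z/ELAC2 the 3' ends). Standard RNA-seq sees the
bodies of these molecules but not their boundaries: a read tells you a
position was transcribed, not that a molecule *ended* there.

Circularized RNA sequencing solves this by ligating each RNA's 3' end to
its own 5' end before reverse transcription. RNase R then destroys
anything that failed to circularize, so every surviving molecule carries a
covalent record of both of its termini at the ligation junction.
Random-primed reverse transcription proceeds rolling-circle around the
circle, so a single cDNA can contain several tandem copies of a short
molecule. A sequencing read that crosses the junction shows the molecule's
3'-terminal sequence immediately followed by its 5'-terminal sequence —
recovering that breakpoint recovers the molecule's ends, including for
partially processed precursors that span several genes and for decay
fragments with non-templated tails (3'-CCA on tRNAs, short poly(A) on
mRNA-derived fragments).

`circends` implements the complete computational path from raw paired-end
reads to: per-molecule terminus calls ("links"), per-position 5'/3'-end and
coverage tracks (raw and CPM), condition contrasts (log2 fold changes),
and small-RNA tail statistics — plus a generative simulator of the library
chemistry so that every stage has a parameter-recovery test against known
ground truth.

## Pipeline stages and their models

### Read preparation (`readprep`)

3' adapter read-through is removed by occurrence scanning: the best adapter
occurrence (full internal match, or a >= 3 nt adapter prefix at the read
end) at <= 10% mismatches, lowest mismatch rate winning and ties going to
the longest trim. Pairs with either mate under 20 nt are dropped. Mates
are then merged over the overlap (mate 2 reverse-complemented) that
minimises mismatch density, scanned from 245 nt down to 10 nt, accepted at
density <= 0.25; within the overlap the higher-quality base is kept, ties
keeping mate 1. Unmerged pairs contribute only read 1 downstream — read 2
of a non-merging pair duplicates no junction information the aligner
needs. Note one structural consequence of the 245 nt overlap cap: an
insert of exactly one read length has a full-length overlap that the cap
excludes, but read 1 already contains the complete insert.

### Rolling-circle collapse (`monomerize`)

Each read is scanned for the smallest period `p` (>= 15 nt, leaving >= 2
copies) at which `seq[i] != seq[i+p]` holds at no more than 10% of
positions; qualifying reads are collapsed to a per-column majority-vote
consensus (ties keep the first copy's base). With three or more copies the
consensus also corrects most substitution errors. The period scan is a
direct self-comparison rather than an alignment-scoring automaton: on a
single short genome it is exact, deterministic, and checkable against a
brute-force oracle. Reads without a qualifying period pass through
unchanged.

### Split alignment (`align`)

The genome is a single circle of ~16 kb, so alignment is done internally:
a k-mer index (k = 12, both strands, origin-spanning k-mers included)
seeds diagonals; hits are clustered per diagonal band; each candidate
window is solved exactly by an affine-gap local DP (match +2, mismatch −4,
gap open −6, extend −1, the common local-mode constants) with traceback,
on a numba kernel. The single best placement is kept (ties: lowest genome
coordinate, then plus strand), reads scoring under 40 are unaligned.
Soft-clipped ends of >= 15 nt are realigned end-to-end by exhaustive
substitution-only placement over every genome offset, with an edit budget
of max(2, 10% of length) — exact and fast at this genome size. Alignment
works in strand-resolved ("transcript-sense") read coordinates against
the forward genome: minus-strand reads are reverse-complemented once, and
all downstream junction logic is then strand-uniform.

Origin-spanning placements are found by aligning against the
concatenated genome and reported with `gstart` in `[0, L)` and `gend`
possibly past `L`.

### Junction calling (`links`)

Two adjacent segments of one read whose genome placements are
non-contiguous (gap > 2 nt after accounting for the read gap) define a
junction: on the plus strand the earlier segment ends at the molecule's
3' nucleotide and the later one starts at its 5' nucleotide; the roles
mirror on the minus strand.

The exact breakpoint is *not* taken from where the local aligner stopped:
an extension can absorb tail bases or run across the junction whenever
flanking genome sequence coincides for a few bases. Instead a
mismatch-minimising split-point search assigns every read base near the
junction to segment A's diagonal, a non-templated tail (empty, CCA, or an
A-run up to 45 nt; reverse-complemented in these coordinates on the minus
strand), or segment B's diagonal, and picks the assignment with the
fewest genome mismatches. Ties prefer the longest templated body, then
the shortest tail — genome-encoded bases are body, not tail. Both
start- and end-anchored diagonals of each segment are tried, since an
indel inside an over-extension corrupts one anchor. Junctions whose best
explanation still leaves > max(2, 15%) mismatches are discarded as
chimeras, as are three-part (left/middle/right) groups whose two
junctions disagree by more than 2 nt — successive rolling-circle copies
must agree.

Collapsed monomers take a dedicated route: doubling the monomer
linearises the molecule regardless of the random rotation at which
reverse transcription entered the circle, so a single local placement
spans the full body and the refinement (against a tripled context, for
enough flanking sequence) yields both termini and the tail in one step.

Calls pool into a link table (read-level counts — duplicates are *not*
collapsed, abundance is read-level) and per-position 5'/3'-end profiles;
exports are TSV, BEDGraph and Circos link/karyotype text, all 1-based.

### Quantification and contrast (`coverage`, `links.compare_links`)

Depth counts reference-consuming bases (M and D ops) per strand with
wraparound. CPM divides by the number of genome-aligned reads (reads, not
bases). Differential tracks are log2((A + ψ)/(B + ψ)) with ψ = 1 CPM by
default (configurable); the pseudocount keeps all positions finite, and
the same form applies to link tables after CPM normalisation. Replicates
are pooled for links and coverage but kept separate for the small-RNA
replicate statistics.

### Small RNAs (`srna`)

Candidates are collapsed monomers with >= 2 copies and 15–60 nt length.
Each is rotated into transcript orientation using its junction call, then
classified: trailing exact `CCA` beats a trailing A-run of 3–20 nt; a
tail whose bases the genome encodes at the placement's 3' flank is
templated, and a fully templated A-run is body, never poly(A).
Feature assignment is a strand-aware cascade: tRNA if the body overlaps a
same-strand tRNA by >= 80% (3' extensions allowed), else rRNA/mRNA if the
body lies entirely inside a same-strand feature *and* its 3' terminus is
not at the feature's annotated 3' end (which would be the canonical
poly(A) site, not a decay mark), else unassigned. Per-tRNA CCA ratios are
read depth of CCA-bearing over all tRNA-assigned reads at the annotated
3'-terminal nucleotide. Per-gene poly(A) proportions are compared between
conditions by a two-sided equal-variance Student's t-test on
per-replicate proportions (no multiple-testing correction — by design the
statistic mirrors the named test; identical groups report p = 1,
zero-variance separation p = 0).

## The simulator (`simulate`, `toy`)

The generative model follows the library chemistry stage by stage:
template molecules with defined termini and tails (tails appended before
circularization, so junctions read `...tail|5'-end...`); Bernoulli
circularization (default 0.85 — the chemistry's efficiency is not
published, this is a documented guess); non-circularized molecules yield
no reads (RNase R); copy number 1 + Geometric with mean 2.5 (rolling
circle demonstrably yields "more than two" copies of small RNAs but no
distribution is published; geometric is the memoryless minimal choice);
uniform random rotation (random priming); sequential fragmentation with
Normal(350, 80) lengths truncated to [30, 500]; 250 nt paired reads with
independent substitutions at a configurable rate, constant quality, and
adapter read-through when the insert is short. Read 1 is emitted in
molecule sense; the aligner is strand-symmetric so this convention is
free. Truth tables record every molecule (termini, strand, tail, copies,
circularized) and every read (fragment coordinates and contained junction
offsets).

The default template population per scenario: mature species at exact
annotated ends (tRNAs with CCA, mRNAs with 30 nt poly(A), rRNA-weighted
abundances), multi-gene precursors spanning unprocessed tRNA boundaries,
ORF-internal degradation intermediates, and short tRNA-3'/mRNA-internal
fragments with tail probabilities (CCA 0.6; poly(A) 0.1 wild-type vs 0.3
knockout). The knockout scenario doubles precursor and
degradation-intermediate weight — the stalled-processing phenotype — with
weights as fractions of total abundance so the doubling is exact.

The toy genome mirrors a vertebrate mitochondrial gene order (rRNAs,
tRNA-punctuated mRNAs on the heavy strand, a light-strand mRNA and tRNAs,
a control region) on random seeded sequence, with one deliberate
property: single bases flanking gene boundaries are adjusted so that no
default template's junction is ambiguous. On fully random sequence,
roughly 40% of junctions allow a zero-cost one-base shift (the base after
the 3' end equals the 5'-start base, or continues the tail homopolymer) —
no caller could resolve those from reads, and a ground-truth simulator
that cannot be decoded cannot verify anything. Real genomes carry
whatever ambiguity they carry; see limitations.

## What the tests show — and what they do not

Parameter-recovery tests demonstrate that the implementation inverts its
own generative model: exact termini for >= 99% of evaluable
junction-spanning reads at zero error, within ±1 nt for >= 90% at 0.5%
substitutions; alignment scores equal to an exhaustive Smith–Waterman
oracle; repeat collapse equal to a brute-force period scan; a simulated
2× precursor contrast, CCA fraction, and poly(A) shift recovered at their
binomial tolerances. Problem sizes (2,000 molecules for recovery, ~5,000
reads per condition for the contrast, 500 reads for the alignment oracle,
20 seeded runs for the t-test check) were chosen so each study answers
its question at useful statistical resolution on a desk machine.

The simulator does not model: PCR duplicates, quality-score structure,
ligation sequence bias (none was found for this chemistry), indel
sequencing errors (available behind a flag, off by default —
substitutions dominate on this platform), nuclear mitochondrial DNA
copies (the pipeline aligns only to the organellar genome; real nuclear
reads would need pre-filtering), or junction-context ambiguity (above).
Passing tests therefore certify the computation, not these properties of
real libraries.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; every exported file is
  1-based inclusive.
- Contiguity tolerance 2 nt: segments within 2 nt of colinear are one
  locus (alignment jitter), not a 1–2 nt "processing site".
- Alignment tie-breaks (lowest coordinate, then plus strand) and the
  refinement tie-breaks (longest body, then shortest tail) make all calls
  deterministic; end-to-end placement ties resolve to the lowest genome
  offset.
- CPM of an empty library and log2FC of non-CPM tracks raise; empty FASTQ
  input produces empty but valid outputs with zero counts.
- `cca_ratio` reports NaN for tRNAs with no read at the terminal
  nucleotide rather than 0 — absence of evidence is not a ratio.
- Every read lands in exactly one accounting bin (dropped at trim,
  unmerged mate 2 discarded, unaligned, aligned single-locus, aligned
  split) and stage totals always sum to the input.

## Known limitations

- Junction positions on real genomes are ambiguous wherever the 5'-start
  sequence coincides with the 3'-flank (the tie-break then reports the
  maximal templated body, a consistent but arbitrary convention); the
  same applies to poly(A) tails abutting genomically encoded adenosines —
  a known biological identifiability problem, not an implementation one.
- The end-to-end clip realignment is substitution-only; clips containing
  indels fall back to incomplete groups and produce no call.
- Multi-locus ("chimeric") short molecules would be discarded by the
  rotation-consistency gate; the model assumes contiguous transcripts.
- The t-test on 3-vs-3 proportions is the field's named convention here,
  not a recommendation; with many genes it needs multiplicity control.
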