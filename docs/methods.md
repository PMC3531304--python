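# Methods

This note records the models, parameter choices and numerical conventions
behind `chimeraseq`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and formats

All genomic intervals are 0-based half-open throughout the package — the
native semantics of PSL and BED — and 1-based coordinates appear only in
report columns that say so (junction-read start positions are reported
1-based, the convention in which the valid window for 76 nt reads runs
from position 1 to 67). PSL is the
canonical alignment input because the junction gap/overlap rule needs
query coordinates, which BED12 lacks; BED12 records can be imported but
are excluded from discovery with reason `bed12_no_query_coords`. FASTQ
quality encoding is fixed to Sanger Phred+33 (no autodetection, for
determinism). Parsers reject invariant-violating input rather than
repairing it.

## Discovery

Defaults: `min_identity = 0.96`, `min_align_len = 100` nt, both inclusive;
junction tolerance `|g| ≤ 10` nt. "Non-contiguous" is operationalised as:
different chromosome, or different strand, or — same chromosome and
strand — any layout inconsistent with one colinear cis transcript. That
admits out-of-order and nested partner intervals, and admits colinear
layouts only when the separation exceeds `max_intron` (default
1,000,000 nt, our choice: comfortably above real intron lengths while
still admitting genuinely distant read-through-like pairs). Transcripts
with three or more surviving alignments are excluded as ambiguous rather
than pairwise-enumerated, and an exact tie in the two parts' query starts
leaves the 5′/3′ assignment undefined, so such transcripts are suppressed.
Intra-strand ordering is classified after mirroring minus-strand
coordinates, so "downstream" always means downstream in transcription
direction; partially overlapping non-nested intervals are reported
`ambiguous` and left out of order tabulations. An optional Blat-style
near-best filter (drop alignments more than 0.5% identity below the
per-transcript best) is off by default, since inputs are usually
pre-filtered upstream.

## Spliced alignment and junction verification

The fused reference joins the two partner regions in transcribed
orientation, each with `flank = 500` nt of context (our choice; some flank
is required so donor/acceptor context exists at partner edges, and 500 nt
also covers alignment slop at region boundaries). The spliced aligner is a
deliberately simple model matched to its inputs: local alignment with
+1/−1 match/mismatch scoring in which the only gaps are target-side jumps
of at least `min_intron = 30` nt at a flat penalty of 4. Mature transcripts
against their own genomic source differ by substitutions only, so there
are no small-indel states. The DP is vectorised but contract-equivalent to
a scalar recurrence with a fixed tie-break order (diagonal first, then the
intron with the leftmost optimal source, then stop; best cell at the
smallest query then target index), which the test suite verifies against
an independent scalar implementation. An alignment covering < 50% of the
query, or containing a block with > 4% mismatches (the 96%-identity regime
again), marks the candidate unverifiable rather than raising.

A junction is *precise* when one block ends exactly at the fusion
transcript coordinate and the next begins there, the two blocks sitting on
opposite sides of the artificial join. Donor/acceptor dinucleotides are
read off the fused reference immediately outside those blocks — already in
transcribed orientation, so minus-strand partners whose plus strand shows
CT..AC read canonically as GT..AG. Only the trans-junction is required to
be GT/AG; cis-intron signals are reported informationally. Reading-frame
integrity is operationalised as *the longest forward-frame ORF (ATG to
stop, standard code; an ATG without a downstream stop runs to the last
complete codon) spans the fusion point* — the natural reading of
"structural integrity" for transcripts without CDS annotation.

## EST support

The EST aligner is a seeded local aligner: a shared exact 11-mer (the
classic nucleotide word size) gates a full Smith–Waterman (+1/−1, gap −2);
hits below 96% identity or shorter than 22 columns are discarded. ESTs are
unstranded, so the reverse complement is aligned too. A single local hit
must cover the `[junction − 20, junction + 20)` window — split/spliced EST
alignments are not stitched. Support requires ≥ 3 distinct EST ids.

## Junction quantification

Read QC removes reads whose **mean** post-trim Phred is below 20 (the
common read-level reading of a per-read quality cutoff; a `min` mode is
available), right-trims longer reads to the cohort length, and drops
shorter ones. Genome mapping is ungapped Hamming mapping with ≤ 2
mismatches — the Bowtie-v-style model in which a mapped read is by
construction contiguous, so junction evidence can only come from unmapped
reads; multi-mapped reads are discarded. The mapper uses a pigeonhole
k-mer index (k = 16, m+1 seeds for m mismatches) and is exactly equivalent
to a brute-force scan, which the tests verify; reads shorter than
(m+1)·k take the exhaustive path.

Junction references concatenate the last L−k nt of the 5′ part with the
first L−k nt of the 3′ part (k = 5). Sides shorter than L−k are clipped
and the reference excluded from start-window calling. A read matching
several references is assigned to the fewest-mismatch one; exact ties are
flagged shared and excluded from per-event counts. Validation: ≥ 3
distinct start positions or ≥ 3 distinct samples. The 49-nt cohort is
analysed identically (reference length 88, starts 1…40).

## Statistics

CV uses the n−1 (sample) standard deviation, in percent; a zero-mean event
is flagged undefined and excluded from summaries. The KS normality check
estimates mean and sd from the data and uses the asymptotic p-value; no
Lilliefors correction by default (a flag exists), matching the common
practice of reporting a plain one-sample KS against fitted parameters.
Counts are compared raw — junction-read counts, not normalised rates — by
design. The rank-sum test enumerates all C(nA+nB, nA) label assignments
whenever that count is ≤ 10⁶ (two-sided p = 2·min of the tail
probabilities, capped at 1, midranks under ties); beyond that a
tie-corrected normal approximation without continuity correction is used.
Note the exact test is conservative at nominal 0.05 for small groups: for
5 vs 6 the largest achievable two-sided level below 0.05 is 14/462 ≈
0.030, and the calibration experiment measures exactly that.

## Motif analysis

Region categories use `up_window = down_window = 2000` nt (our choice: the
scale of proximal promoter/terminator neighbourhoods), read in
transcription direction, exons/introns taken from the candidate's own
alignment blocks. The shared-motif search enumerates shared exact 10-mers,
extends each seed pair outward under +1/−1 scoring keeping the
best-scoring extension, clamps the width to [10, 30] by trimming the
lower-contributing edge, and keeps the single best site pair — one motif
per pair, zero or one site per sequence. Significance is empirical: the
fraction of 200 dinucleotide-shuffled replicates of one member whose best
score reaches the observed one (dinucleotide shuffling preserves local
composition such as CpG content); pairs with p > 0.05 yield nothing. Each
chimera contributes its best pair to the 4×4 category matrix.

PFM comparison scores mean per-column Pearson correlation of frequency
columns over all offsets with ≥ 4 overlapping columns and both
orientations; degenerate (uniform) columns contribute 0. The null permutes
the library motif's columns; the add-one estimator (1+exceed)/(1+n) keeps
p in (0, 1]. Benjamini–Hochberg FDR is applied across the library. The
bundled PFM library is synthetic — a CTCF-like profile built from the
planted consensus plus unrelated profiles — and any JASPAR-format file can
be supplied instead.

## The synthetic study

The generator's defaults define the study conditions: a four-chromosome
genome (300 kb + 200 kb + 1.5 Mb + a 16 kb mitochondrion-like chromosome,
GC 0.42), genes of three exons (~200–240 nt) with GT..AG introns, and 20
clean chimeras covering every fusion class and intra-strand ordering type
in roughly the skewed proportions real intra-strand events show (most with
the 5′ partner downstream; nested cases built by embedding one partner
gene inside the other's long intron; one colinear pair 1.1 Mb apart on the
large chromosome; one partner on the mitochondrion-like chromosome). Each
of 7 decoys violates exactly one filter: PSL identity 0.95, a 99-nt part,
an 11-nt junction gap, a GC–AG donor, a frame-breaking stop block, only
two spanning ESTs, or junction reads pinned to two starts in two samples.

Clean chimeras join at exon boundaries so the trans-junction inherits a GT
donor and AG acceptor; a long ORF is written across the junction; the
transcript bases flanking the junction are fixed so the spliced alignment
cannot slide the junction by one base; and the intron bases just beyond
the splice signals are set to mismatch the transcript continuation, so a
junction read overhanging by only 5 nt can never map contiguously to the
genome within the 2-mismatch budget. These edits make the planted truth
*exactly* recoverable — which is the point of the experiment, and also its
limitation: real data contain homologous junction contexts, indels,
quality-correlated errors, positional/GC coverage bias and incomplete
genomes, none of which the generator models. Passing tests demonstrate
that the pipeline implements its stated rules exactly, not that those
rules are sufficient on real tissue data.

The read cohorts mirror a two-tissue design: eleven "liver" individuals
(five male, six female; three sequenced at 101 nt to exercise
right-trimming to 76 nt) and three "muscle" breed pools at 49 nt. Per-event
per-sample counts are log-normal with cohort CV targets of 57% (liver) and
35% (muscle) around a mean of 120 reads; uniform fragment starts;
substitution-only errors (no indels, matching the ungapped mappers);
qualities drawn uniformly in 33–40. Junction-read truth records every read
whose post-trim span overlaps the fusion point by ≥ 5 nt on both sides.
The measured CV of junction-read counts exceeds the programmed transcript-
level CV because window thinning adds counting noise on top of it.

## Problem sizes

The default experiments run in minutes on one CPU: the full study is a
~2 Mb genome with ~27 planted objects and ~45k reads across 14 samples;
oracle-equivalence suites use ≤ 100 kb genomes and ≤ 500 nt sequence
pairs; the rank-sum calibration uses 1000 replicates of 5-vs-6; the motif
study 40 pairs of 1 kb at 200 shuffles. The end-to-end smoke test lowers
only the motif shuffle count (30), never a threshold.

## Known limitations

* Ungapped mapping and substitution-only alignment: indel-bearing reads or
  transcripts are invisible by design.
* The spliced aligner is not a consensus-splice-signal-aware aligner; it
  finds maximal-scoring exon chains and leaves the GT/AG judgement to the
  explicit signal check.
* The empirical motif p-values have resolution 1/n_shuffles; the PFM
  similarity is a column-correlation score, not an information-content
  weighted log-likelihood.
* Exact rank-sum enumeration is conservative at small group sizes
  (discrete null); this is a property of the test, not an implementation
  artefact.
* The unique-event overlap rule is strand-insensitive genomic overlap,
  the stricter of the plausible readings.
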