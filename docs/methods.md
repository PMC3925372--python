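# Methods

This note documents the models and procedures srnakit implements, the
defaults it ships with, what the synthetic data do and do not emulate, and
the design choices made where the design was genuinely open.

## Read processing

Reads are expected to be insert + full 3′ adapter.  The insert is whatever
precedes the left-most exact match of the adapter's first 8 nt; reads with
no adapter seed are discarded, because without the adapter the insert end
is undefined.  Inserts outside 18–30 nt or containing non-ACGT bases are
discarded (downstream mapping is exact-match, so ambiguous bases cannot be
placed).  Identical inserts collapse into unique tags with per-library
counts; the retained-read total is the library's clean-read count and is
the depth (`N1`/`N2`) used by the differential statistic.  A
minimum-mean-quality threshold exists as a configuration hook but defaults
to off: the simulator emits constant Q40, and real "low quality" criteria
vary by platform pipeline.

## Annotation hierarchy

Unique tags are mapped to the genome on both strands with no mismatches and
every occurrence kept.  Mapping is a hash index of all genome substrings at
the tag lengths in use — an exact-search replacement for a short-read
aligner that is practical up to a few hundred kb and is verified in tests
against a brute-force position scan.  Each tag then receives exactly one
category by priority:

GenBank ncRNA (rRNA/tRNA/snRNA/snoRNA/scRNA) > Rfam > known miRNA >
repeat > exon > intron > siRNA > unannotated,

with exon/intron hits split sense/antisense relative to the feature strand
("antisense to exon" = the tag matches the reverse complement of an
annotated exon).  Ties inside one priority level resolve to the
lexicographically smallest feature id, for determinism only.  Multi-locus
tags are not count-split: the whole count goes to the one chosen category,
so categories partition the clean reads — an invariant the pipeline checks
at run time.  The residual "siRNA" category is operationally "matches a
feature explicitly labelled siRNA"; anything else is unannotated.

## Differential statistic

`p(y|x) = (N2/N1)^y (x+y)!/(x!y!) / (1+N2/N1)^(x+y+1)` is evaluated in
log space via log-gamma, which stays finite at counts ≥ 10⁷.  The
accumulated tail `q` is the CDF of a negative binomial with `x+1` successes
of probability `N1/(N1+N2)`, computed as the regularized incomplete beta
`I_{N1/(N1+N2)}(x+1, y+1)` — O(1) instead of an O(y) summation.  Tests pin
both routes against a truncated summation and against exact
`fractions.Fraction` arithmetic.

Numerical/edge choices:

* `q` exactly 0.5 gives `p = 2q = 1.0` (the "larger than 0.5" branch is
  strict).
* Two-tailed doubling can exceed 1 at the mode; `p` is clipped to [0, 1].
* Normalization is reads-per-15-million.  The up/down thresholds are
  strict: `|log2| > 1` and `p < 0.05`; a ratio of exactly 2 is "equal".
* When exactly one normalized value is 0, half a read (0.5 count) is
  substituted **for the ratio only**; the p-value always uses raw counts.
  Both counts 0 short-circuits to call = equal, p = 1.
* No multiple-testing correction enters the calls; a Benjamini–Hochberg
  column is emitted alongside for transparency.
* `fold_change_percent` (for microarray-style worked examples) is
  `round(100·treatment/control)`, half away from zero.  Several published
  worked-example cells are only reproducible if the percentage was computed
  on unrounded signals; the bundled table keeps the arithmetically
  consistent cells only.

## Target prediction

Duplexes are ungapped and antiparallel: position *i* from the miRNA 5′ end
faces site position *L−i+1*.  The criteria reference fixed positions
(2–12, 10–11), which is only well-defined without bulges, hence the
no-gap design.  G:U wobbles are not mismatches for rules 1–4; they count
0.5 only in rule 5's positional score over positions 1–12 (cap 2.5).
Rule 3 ("no more than two adjacent mismatches") is ambiguous between a run
limit and an event count; it is implemented as "no run of three or more
consecutive mismatches".

The energy model is a per-pair stand-in — GC −3, AU −2, GU −1, mismatch
0 — not a nearest-neighbour thermodynamic model.  Rule 6 uses the *ratio*
to the perfect-complement energy (≥ 0.75), which damps sensitivity to the
absolute scale; the energy function is pluggable (`pair_energies`) for
anyone wanting a finer model.  `scan_targets` evaluates every window of
every transcript and is tested against exhaustive enumeration.

## Novel-miRNA hairpin screen

The screen is deliberately *not* a secondary-structure folder.  For an
ungapped stem, window position *i* pairs with *c − i* for a single pairing
constant *c*; scanning *c* therefore scans all candidate ungapped
stem-loops.  A candidate (searched in a 250-nt window centred on each
genomic occurrence of an unannotated tag, one candidate per locus) is
accepted when the mature tag sits wholly on one arm with ≥ L−4 of its L
positions paired (G:U allowed; 17/21 for a 21-mer), the loop is ≥ 15 nt,
and the stem energy (same stand-in scores) is ≤ −30.  All thresholds are
keyword arguments.  Accepted candidates are named
`<tissue>_miRNA%04d_<arm>` by descending summed count, and the reported
subset keeps counts strictly greater than 100 — interpreted as counts
summed across the tissue's libraries (the per-library reading was equally
plausible; summed is the documented choice).  Random-shuffle controls in
the tests require ≥ 95 % rejection.

## tasiRNA phasing and network

Only 21-nt tags are mapped, sense strand, perfect match, all positions
kept.  The phase register of a start position is
`(pos − cleavage_position) mod 21`; the read starting exactly at the
initiator cleavage site is register 0 (the canonical phasing origin —
plots elsewhere sometimes use transcript position 1, which only rotates
the histogram).  Per-sequence differential tests keep sequences whose
count exceeds 10 reads in at least one of the two compared libraries
(strict `> 10`, applied to the maximum over the pair).  The network is a
typed multigraph: `initiates` edges from the initiator miRNA to its MIR
gene and each cleaved TAS locus, `generated_from` edges backed by perfect
21-nt mappings, `targets` edges backed by duplexes passing all six rules;
sRNA nodes carry the DE call, and the export is SIF + GraphML
(Cytoscape-compatible without depending on Cytoscape).

## NAT-siRNA quantification

A read counts in an OL/WL region iff its genomic match is fully contained
in the region interval — containment, not overlap, is unambiguous for
18–30-nt reads.  Orientation is the strand whose sequence the read equals
(+ forward, − reverse complement); a palindromic tag counts once per
orientation.  Cis pairs require opposite strands and OL ⊆ both WLs (so
OL ≤ WL per orientation is a checked invariant); trans pairs carry two
complementary OL segments whose counts are pooled.  Per-pair OL totals
(orientations pooled, per-orientation columns retained) feed the
differential test, and a pair is "altered in both lines" when both
treatment comparisons agree on a non-equal call.

## Synthetic data: what it emulates, and what it does not

The generator builds a ~50 kb mini-genome containing one instance of every
annotation class, eight miRNA hairpins (mature + ≥15-nt loop + perfect
star, so the hairpin screen accepts them by construction), two unannotated
hairpins (the "novel" sources), four TAS-like loci whose 21 nt upstream of
the cleavage site are the perfect complement of the initiator miRNA, a
cis- and a trans-NAT pair, and a small transcriptome with planted perfect
target sites for the first phased tasiRNA of each TAS locus.  The adapter's
8-nt seed (and its reverse complement) is patched out of all reference
sequence so trimming is exact on noise-free reads.

A library draws a multinomial over sources whose base class mixture is
miRNA 0.20, tasiRNA 0.12, 24-nt heterochromatic siRNA 0.26, tRNA fragment
0.04 (0.25 in roots, renormalizing the rest), genic background 0.16
(lengths drawn from an 18–30 distribution peaked at 21 and 24), novel
hairpins 0.02, NAT regions 0.12, adapter-free decoys 0.08.  These weights
were chosen so that a processed library reproduces the canonical 21/24-nt
length modes and root 19-nt tRNA peak at 20 000 reads per library (8 000
in the test suite — large enough that the designated 4-fold spikes have
control counts in the hundreds).  Abundance multipliers scale a source's
absolute expected count (the library total grows with them, as a real
spike would), so the raw count ratio between conditions is the multiplier
in expectation; the *normalized* ratio is smaller because the treatment
library is deeper.  The default condition multipliers emulate the study
design: two miRNAs ×4 and the initiator ×3 in overexpression leaves, the
TAS1-like loci ×2.5, one miRNA ×0.25, the TAS4-like locus ×0.2, one
cis-NAT OL region ×10.  The initiator's ×3 is deliberately borderline —
after depth normalization it sits near the 2-fold threshold, so only the
≥4-fold spikes are guaranteed "up" calls.

Not emulated: sequencing error profiles and quality variation (constant
Q40; `noise_rate` exists but defaults to 0), partial adapter ligation, RNA
degradation, strand biases, genome repetitiveness at scale, and replicate
structure.  Passing tests therefore demonstrate correctness of the
*computations* under the stated generative assumptions, not robustness to
real-library artefacts.

## Problem sizes and determinism

Defaults are desk-scale by design: ~50 kb genome, 20 000 reads per library
(8 000 in the test suite and acceptance script), eight libraries.  A full
pipeline run takes seconds on one CPU.  All randomness derives from one
integer seed; per-stage and per-library seeds are SHA-256-derived from it,
and a fixed seed reproduces every output byte for byte (checked via the
manifest checksums).

## Known limitations

* The hairpin screen's ungapped stem misses bulged precursors a real
  folder would accept; its thresholds are structural heuristics, not
  thermodynamics.
* The stand-in energy model makes rule 6 a pairing-composition ratio, not
  a free-energy ratio.
* Known-miRNA counting matches tags exactly equal to a mature sequence;
  isomiRs (shifted/trimmed variants) are not aggregated.
* Antisense phased reads on TAS loci are out of scope (sense-strand
  mapping only), as is genome-wide de novo phased-locus discovery and
  phasing significance scores beyond the register histogram.
* Single libraries per condition: the statistic models sampling, not
  biological dispersion; with replicates a negative-binomial DE model
  should be preferred.
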