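# Methods

## The recombination model

V(D)J recombination is modeled at the level at which it determines
breakpoint coordinates. RAG cleavage is placed exactly at the boundary
between a gene segment and the heptamer of its flanking RSS. For a
rearrangement between an upstream segment (using its 3′ RSS) and a
downstream segment (using its 5′ RSS), the two cut sites define the
*excision boundaries*; the intervening DNA becomes the excision circle
and its length equals their distance exactly, because signal ends are
blunt and fuse without processing. The signal joint is therefore a
head-to-head heptamer fusion with zero untemplated bases — an invariant
the test suite checks literally (the 14-mer across the circle closure is
the downstream heptamer reverse-complemented, then the upstream
heptamer).

Coding joints, by contrast, are processed: each coding end may lose up to
`max_del_per_end` bases (uniform 1..max with probability `p_del`, default
8/0.5) and gain untemplated N bases (geometric with mean 2.5, truncated
at `max_n_insert` = 10, with probability `p_ins` = 0.5). The same noise
model applies per junction when a circle reinserts or a translocation is
formed. P-nucleotides are not modeled; they would add ≤ 2 bp of
palindromic sequence at coding ends and are irrelevant to the
signal-end-mediated junctions this package is about. The 12/23 rule is
enforced: rearrangement is refused unless the paired RSS spacers are
{12, 23}. D–D rearrangement (Dδ2→Dδ3) is permitted — the upstream
partner must be a D segment, the downstream partner D or J — since that
is precisely the rearrangement whose circle matters here.

Circle reinsertion re-opens the circle exactly at the signal joint,
regenerating the two blunt RSS-terminated ends, and inserts the fragment
at the target position with per-junction noise; the derived allele
records both pseudo-hybrid junction coordinates as truth. A deletion of
≥ 8 bp on an insert end destroys its heptamer and is recorded as
"RSS not identifiable". An end-trimmed insertion is still an insertion —
the classifier flags completeness as `entire` (both breakpoints exactly
at the annotated cleavage edges), `partial` (≥ 8 bp lost from an end), or
`indeterminate` (1–7 bp lost: junctional modification and partial
insertion cannot be told apart at this scale).

## The surrogate reference

One contig per locus — TRD (30 kb), TRB, TRG, IGH (20 kb each) — plus
partner contigs: a ZFP36L2 surrogate region (20 kb, gene at 5–15 kb), a
second partner region (MORN3, 12 kb), and a 16.5 kb mtDNA contig treated
as one more partner. Defaults place the Dδ2/Dδ3 excision boundaries
10,000 bp apart and Dβ2/Jβ2-3 1,200 bp apart, so the full circles have
those sizes by construction; both distances are configuration fields.
Spacer conventions: D segments carry a 12-spacer 5′ RSS and a 23-spacer
3′ RSS; J segments a 12-spacer 5′ RSS (23 for the IGH J, matching its
locus convention).

Background sequence is uniform random DNA from the config seed. After
planting the annotated RSSs, every contig is rescanned and any window
reaching the cryptic-RSS threshold outside a planted motif is mutated
(the double-weighted CAC core is broken) until none remains. This makes
"no cryptic RSS at the partner break" a constructible ground truth:
type 2 events are simulated into certifiably RSS-free sequence, and
type 1 events require explicitly planted germline cryptic RSSs.

The capture panel covers each annotated segment plus its RSSs with a
300 bp flank — partner genes are deliberately un-baited, as in a
TR-targeted diagnostic panel, so junction recovery must come from
TR-side-anchored fragments. Coordinates are 0-based half-open everywhere;
BED files round-trip the full annotation.

## RSS scoring

score = 0.7 · (weighted heptamer identity) + 0.3 · (nonamer identity),
with the first three heptamer positions (CAC) counted twice (weights
2,2,2,1,1,1,1 over a total of 10). A perfect heptamer + nonamer scores
1.0; a random window scores 0.25 in expectation; one nonamer mismatch
costs 0.3/9. Spacer content is unscored. Cryptic scanning covers both
strands and spacers {11,12,13,22,23,24} (±1 biological flexibility;
annotated RSSs stay strict 12/23) with threshold 0.80. The production
scan is vectorized; the test suite holds it equal to an independent
naive re-scan on dozens of random intervals. The 0.7/0.3 split, CAC
double-weighting, 0.80 threshold and the ±25 bp annotation window are
package decisions — presence/absence of cryptic RSSs at clinical
breakpoints is usually asserted without a printed scoring scheme — and
all are exposed in configuration and flagged in output.

A breakpoint end is `authentic_signal_end` only if it coincides exactly
with an annotated RSS cleavage edge; `cryptic_rss` if a scan hit's
cleavage edge lies within 25 bp; otherwise `none`.

## Split-read calling

Mapping is k-mer seeded (k = 17, odd to avoid palindromic seeds) with
ungapped extension. Each read takes its leftmost and rightmost uniquely
placed seeds; agreeing anchors give one segment, disagreeing anchors
trigger a split search minimizing
`mismatches(prefix) + mismatches(suffix) + 0.35·gap` over the split
point and an untemplated gap of 0–15 bases. The gap penalty sits well
below the 0.75 expected mismatch saving of a random untemplated base, and
below ~0.4 so that the true gap still wins at signal-end junctions where
both reference continuations begin with near-identical heptamer sequence.
Multi-mapping seeds are skipped; reads with only multi-mapping seeds are
counted ambiguous and contribute no evidence.

Breakpoints are canonicalized by left-shifting through microhomology to
the lowest reference coordinates — the simulator applies the identical
rule to truth coordinates, so noise-free comparisons are exact.
Microhomology and untemplated sequence are mutually exclusive by this
convention. Observations agreeing within 10 bp on both sides cluster
into a call: modal breakpoint, support = distinct read pairs (min 3),
modal microhomology/untemplated values.

Two calls pair into an insertion candidate when their partner-side
positions lie within 100 bp on one contig and their TR-side positions
bound an excised interval of ≥ 50 bp — the floor separates true
insertions from reciprocal-translocation junction pairs, which share
(almost) a single TR position.

The classifier re-aligns canonical breakpoints to annotated cleavage
edges where the junction's own ambiguity allows (sliding right through
the microhomology span), and tolerates outward drift of
microhomology + untemplated length + 6 bp when matching D–J intervals:
untemplated bases that coincidentally match a reference continuation are
absorbed by parsimony and drag the canonical breakpoint outward. Inward
tolerance is 25 bp, covering bounded junctional deletions.

## What the simulator does and does not emulate

It emulates: cleavage-accurate junction coordinates, junctional
trimming/N-addition, blunt signal joints, capture by panel projection
(through each derived allele's block structure), uniform substitution
errors, and truth-channel read names. It does not emulate: indel
sequencing errors, base-quality variation, PCR duplicates, GC- or
mappability-biased coverage, repeat-rich or homologous genomic context
(background is screened random sequence with essentially unique
17-mers), V-to-DJ second-step rearrangement, or inversion-orientation
derivatives. Passing tests therefore demonstrate correctness of the
junction logic and classification rules under the stated read model, not
performance on real libraries, where mapping ambiguity and coverage
dropout would dominate the error budget.

## Problem sizes and determinism

The standard evaluation cohort is 100 events — 20 each of TRD-circle
insertion, TRB-circle insertion, type 1, type 2 (both into partner
genes), and TRD–TRG trans-rearrangement — at 100× pre-capture coverage,
150 bp reads, 0.002 substitution error, default junctional noise; the
noise-free check uses 20 events. These sizes give tight empirical
properties (junction recall is measured over 200 truth junctions) while
keeping a full run in tens of seconds. Every stochastic step draws from
an explicitly passed seeded generator; identical seeds give
byte-identical FASTQ, tables, and VCF output.

## Known limitations

* Type 1 events require the cryptic RSS to exist in the reference the
  caller maps against (it is germline); `plant_cryptic_rss` returns a
  modified reference copy, and cohort simulation plants a fixed set of
  sites up front.
* Insertion sizes at default noise can differ from the trimmed-truth
  span by a few bases of microhomology/absorption ambiguity; at zero
  noise they are exact.
* The per-sample cap of two independent informative events mirrors
  clinical observation (1–2 per patient); more events are still
  reported, with a QC warning.
* A sample's ordinary intra-locus coding joints are detected as
  junctions but filtered as non-events; they are not reported as
  rearrangement genotypes.
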