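# Methods

This note documents the models, rules, numerical choices and known
limitations of `catnet`, in the order data flows through the package.

## Coordinates and containers

All internal coordinates are 0-based, half-open; GTF (1-based, closed) is
converted only at the IO boundary. The central container is the
`OccupancyTrack`: a sparse `(chrom, strand) -> {position: count}` table.
Masked positions are *deleted*, never set to zero — a masked base carries
no information, and averaging a structural zero into a metaprofile would
fabricate a dip. Every processing step conserves or reduces the total
count; nothing downstream of read extraction can create signal.

## Read processing

**Duplicate collapse** uses exact `(chrom, start, end, strand, UMI)` keys
(the behaviour of exact-distance UMI clustering). No edit-distance
merging is attempted: with 10-nt UMIs the collision space is ~10^6 per
position and sequencing-error-induced UMI divergence inflates counts by a
bounded, strand-symmetric amount that cancels in comparative analyses.

**Mispriming filter.** During reverse transcription the RT primer can
anneal to genomic sequence, producing a read whose "UMI" is actually
genome. A read is removed iff its UMI equals, case-insensitively, the
genomic k-mer immediately adjacent to the read's 3' end *in read
orientation* (for a + alignment: the k bases after `end`; for a −
alignment: the reverse complement of the k bases before `start`). The 3'
side is the RT-primer side, hence the default; `side="5prime"|"either"`
covers other chemistries. Exact matching is used — a genuine random UMI
matches a fixed 10-mer with probability 4^-10 ≈ 10^-6, so the false
removal rate is negligible, while allowing mismatches would scale false
removals by ~30x per allowed mismatch.

**Extraction.** The 5'-most aligned base of a read in read orientation is
the 3' end of the nascent RNA — the polymerase position. Because the
library is sequenced from the RNA 3' end, the alignment strand is the
complement of the transcript strand, so counts are flipped to the
opposite strand by default. Flipping twice with the flag toggled mirrors
every count; this involution is property-tested.

**Intermediate masking.** RNA-splicing and 3'-cleavage intermediates have
3' ends exactly at the last nucleotide of exons/introns and at polyA
sites. Those single positions (on the annotation's strand) are deleted
and recorded in the mask set so plots can skip them.

## Active genes and isoforms

A gene is active iff its summed isoform TPM is ≥ 1 **and** at least one
de-novo transcription unit on its own strand overlaps it. "Overall gene
activity" is the sum of isoform TPMs (not a separate gene-level column),
for internal consistency between the two rules. An isoform is active iff
it contributes ≥ 10% of that sum; the active TSS/polyA sets and the
gene's effective span derive from active isoforms only. Both thresholds
are configurable.

## Transcription-unit caller

The caller is a transparent gap-merge: positions with count ≥ 1 (knob:
`min_cov`) are merged into maximal runs where consecutive covered
positions lie ≤ 250 bp apart (`max_gap`); runs shorter than 150 bp
(`min_body`) or with fewer than 10 reads (`min_count`) are dropped; long
runs are never split at internal dips (`max_init_body` is retained as a
documentation knob for compatibility with two-value body-size
conventions, but no splitting is performed). The design goal is a caller
whose exact output can be checked against exhaustive run enumeration —
which it is, by property test — rather than a reimplementation of
fold-over-background peak callers whose parameter semantics are not
fully specified. Defaults were chosen so that, on the synthetic study
conditions, genic sense signal yields one TU per gene and enhancer-level
signal (tens of reads over a few hundred bp) survives the filters.

## Antisense classification and enhancer calling

All distance rules are strict at their stated bounds, and all are
exercised at the exact boundary by tests against an independent
brute-force oracle (999 vs 1000 bp; 499 vs 500 bp; 49.9x% vs 50%; 90%
coverage; termination-zone edge):

- **Candidate:** a TU overlapping ≥ 1 bp of an active gene on the
  opposite strand; the host is the gene with the greatest overlap, ties
  broken by origin-to-TSS distance, then gene id.
- **Spill-over discard:** overlap with a same-strand gene amounting to
  ≥ 50% of the TU or ≥ 90% of that gene; or the TU covering the entire
  host span.
- **DAT:** origin strictly inside (TSS − 1000, TSS) in host orientation
  for *any* active TSS — this single rule also implements the
  reassignment of apparent convergent units that are really the
  divergent partner of a downstream alternative promoter.
- **CAT:** otherwise, origin strictly downstream of the first active TSS
  and inside the host span (the inside-span requirement is a
  configurable default; origins beyond the polyA are promoter-ambiguous
  and discarded).
- **Intragenic enhancer:** a CAT whose TU interval intersects ≥ 1 bp of
  an H3K27ac peak *and* an H3K4me1 peak; center = CAT origin.
- **Extragenic enhancer:** TUs with zero overlap of any active gene's
  effective span (either strand), origin outside every annotated isoform
  TSS ± 500 bp (active or not — promoters of silent genes still
  initiate) and outside every active termination zone
  [polyA, polyA + 2000] in gene orientation (inclusive at the far edge).
  Eligible opposite-strand origins < 500 bp apart merge greedily
  (nearest pair first, coordinate tie-break, each TU used once) into
  bidirectional calls centered at the origin midpoint; leftovers are
  unidirectional. Both marks are required on the (merged) interval.

The promoter half-width (500 bp) and the ≥ 1 bp mark-overlap geometry are
deliberate minimal readings of "annotated promoter region" and
"co-localize"; both are knobs.

## Differential occupancy

**Quantification** sums track counts over a region on the sense,
antisense or both strands. **RPM** scales columns to 1e6; **TPM**
length-normalizes (per kb) before closure; **RLE** divides by supplied
size factors.

**Spike-in size factors** are median-of-ratios computed on spike-in
regions only (geometric-mean reference; regions with any zero excluded)
and applied to *all* regions. The point is quantified by the package's
own failure demonstration: under a simulated uniform 4-fold loss of
primary signal, spike-anchored factors recover a median gene-body log2FC
of −2 while library-size factors computed on the primary regions report
≈ 0. Within-sample normalization cannot see a global change; an
unchanged exogenous reference can.

**The test** is a negative-binomial Wald test chosen for transparency
over a full GLM framework: regions with < 6 raw reads summed over all
samples are excluded; log2FC = log2((mean_t + 0.5) / (mean_c + 0.5)) on
RLE-normalized counts (pseudocount 0.5); the variance of the log fold
change uses Var(K) = mu + alpha mu^2 with a per-region method-of-moments
dispersion pooled across conditions and floored at 0 (Poisson); the
statistic is referred to a Student t with n_c + n_t − 1 degrees of
freedom. The effective df is one more than the pooled-residual count
because the variance is partly model-based (the Poisson floor is known,
and dispersion is shared between groups); this choice was calibrated on
null negative-binomial simulations (3 vs 3, dispersion 0.05), where the
empirical type-I error at alpha = 0.05 is ~0.048 (df = n−2 was
measurably conservative, a plain normal reference anti-conservative at
~0.11). BH controls FDR; significance is padj < 0.05. With a single
replicate per condition the dispersion collapses to Poisson and the
reference to the normal, with a warning implicit in the contract. No
dispersion shrinkage is performed; an export path (counts + factors as
TSV) supports running an external shrinkage-based tool instead.

**Pausing matrices** pair per-region proximal and distal log2FCs and
assign quadrants by sign; an exactly zero component maps to "unchanged"
rather than being forced into a quadrant. Region geometry defaults:
promoter-proximal = first 500 bp downstream of the first active TSS;
gene body = remainder of the effective span; enhancer-proximal =
center ± 250 bp; enhancer-distal = the longer flank of the span (a
single-interval stand-in for the two-sided remainder — configurable).

**Stratification** ranks regions by an external signal and cuts k
equal-size groups, ties broken by region id; lower quantiles absorb the
remainder.

## Target assignment

An enhancer is assigned a gene iff some contact with padj < 0.01 has one
anchor intersecting the enhancer interval and the other intersecting the
gene's effective span extended by the promoter window on the TSS side
(contact bins cannot separate promoter from proximal region). Anchor
order is irrelevant; assignments are monotone in the threshold. A
responsive enhancer has padj < 0.05 *and* log2FC < 0; genes are reported
in strata 0 / 1 / ≥ 2 responsive enhancers. No distance or TAD cap is
applied by default (knob available).

## The synthetic-data generator

The generator emulates the *inputs* of a spike-in nascent-transcription
experiment, not its sequence content. Study conditions (defaults): 2
chromosomes of 1 Mb; 200 genes (10% inactive — half transcribed but
below TPM 1, half expressed but silent); gene signal = uniform body
density plus a promoter-proximal peak with geometric decay (ratio of
proximal to body mean density = pausing index, default 4); divergent
antisense upstream of 70% of active promoters; 50 intragenic CAT loci
and 50 extragenic loci (80% bidirectional, origin separation < 500 bp)
carrying both enhancer marks, plus 10 + 10 unmarked decoy loci; 8
masked sn/snoRNA-like loci; 20% multi-isoform genes split between
downstream alternative TSSs (active share 15%) and inactive upstream
extensions (share 5%) — the latter make the annotated span reach 5' of
the active promoter, which is what lets a divergent antisense unit
overlap its gene, as in real reference annotations; a spike-in
chromosome with 40 uniform regions receiving reads at a 1:8 ratio to the
primary genome; 400,000 primary reads. Counts are independent Poisson
draws per base; an overdispersion knob gamma-mixes each element's rates
per draw (mean 1, variance = knob), making region counts negative
binomial for the differential tests. Artifact rates (1% mispriming, 1%
intermediates by default; the acceptance scenarios use 5%/2%) are knobs,
not estimates — no published empirical rates exist to anchor them.

Read simulation inverts extraction exactly: each occupancy count becomes
a read whose 5' aligned base is the position and whose alignment strand
is flipped. Genuine UMIs are drawn distinct within a position and are
re-drawn if they happen to equal the adjacent genomic k-mer; planted
mispriming reads get exactly that k-mer. This makes truth labels exact
(the mispriming filter removes all and only planted artifacts) and the
artifact-free round trip an identity — by design, so that pipeline
defects cannot hide behind simulator noise. The cost is a slightly
cleaner world than reality, where a ~10^-6 per-read coincidence rate
exists; tests on the round trip therefore certify the code path, not
that real data are artifact-free.

The perturbation scales promoter-proximal rates by one fold change
(default 1.3) and all body/enhancer rates by another (default 0.3),
emulating a pause-release defect; each enhancer linked to a gene (host
gene for intragenic, nearest active gene for extragenic) deepens that
gene's body loss by a coupling factor (default 0.6 per enhancer), so the
planted effect size correlates with connected-enhancer count. Truth
contacts use feature-centered anchors (enhancer interval; TSS ± 500 bp)
rather than grid bins so each anchor touches exactly one planted
feature and assignment recovery is exactly checkable; decoy contacts
(50% of the total) connect random bins that avoid all transcribed
non-genic loci, half of them significant, plus a few non-significant
enhancer-to-wrong-gene near-misses.

Determinism: one seed fixes everything; each stage draws from its own
`numpy` Generator at a fixed offset (genome +0, occupancy +1,
perturbation +2, reads +3, contacts +4) in a fixed element order, so
identical configurations are byte-identical and stages can re-run
independently.

**What passing tests do and do not show.** The generator has no sequence
bias, no mappability structure, no alignment errors, no cross-species
read misassignment, and its elements are placed with safety margins that
real genomes violate (overlapping genes are off by default; enhancers
never sit inside termination zones). Recovery at ~100% sensitivity and
precision on these conditions certifies the *rules* — boundary behaviour,
bookkeeping, normalization arithmetic — not expected performance on real
chromatin, where signal-to-noise, annotation error and mark quality
dominate.

## Problem sizes

The test suite and the acceptance script run on one CPU in well under a
minute: the default genome is 2 Mb + spike chromosome at 400k reads
(region-level analyses), read-level scenarios use 10–45k reads, oracle
comparison uses 100 toy genomes of ≤ 50 kb, and the calibration study
uses 1,000 null plus 300 alternative regions at 3 vs 3 replicates. These
sizes were chosen so that every stochastic check operates with comfortable
statistical margins while iteration stays fast.
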