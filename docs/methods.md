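# Methods

This note documents the models, the numerical choices, and the synthetic
data that the test suite and `scripts/acceptance.py` exercise, in the order
the pipeline runs them.

## Coordinates, formats, and channels

All internal coordinates are 0-based half-open; VCF, MAF, and the simple
five-column text dialect (sample, chrom, 1-based pos, ref, alt) are
converted at the I/O boundary, and `chr` prefixes are stripped on both
mutations and tracks before matching. Signal tracks (BED/bedGraph, wiggle,
bigWig, bigBed) load into a sorted, non-overlapping interval set; where
input intervals overlap, the value of each elementary segment is the
arithmetic mean of the covering intervals, which preserves average-signal
semantics. The BED value column is column 5 when numeric, else column 4
when numeric, else 1.0 — this accommodates narrowPeak-like files,
4-column bedGraph, and plain presence/absence BED3.

Channels follow the COSMIC spellings. For ID-83 the final label field
counts repeat copies *besides* the event itself: a 1 bp deletion inside a
homopolymer of total length k is `1:Del:{C,T}:min(k-1, 5)`; an insertion
records the pre-existing adjacent copies of the motif; deletions of ≥ 2 bp
with no full flanking copy fall back to the longest partial flanking
homology (`M` classes). Mutations whose context contains an N are excluded
and counted in a QC report. A reference-allele mismatch is a hard error
(wrong genome build), not an exclusion.

## Context-preserving simulation

The simulator indexes, per chromosome, every position by its
pyrimidine-oriented trinucleotide (SBS), canonical doublet (DBS), or —
lazily, per channel — by the ID-83 channel a 1 bp indel would produce
there. A simulated mutation is drawn uniformly from the candidate list of
its context on its own chromosome; ref/alt are rewritten in the orientation
of the sampled site, and the source's channel and signature probabilities
are carried over, so per-chromosome per-channel counts are conserved by
construction and attribution is unchanged. Design choices:

* the real position remains an allowed candidate (excluding it would bias
  small genomes);
* duplicate positions within one (sample, replicate, chromosome) are
  re-drawn up to 10 times, then accepted (prevents livelock on tiny
  genomes);
* multi-bp indels are placed by rejection sampling on the target ID-83
  channel (≤ 200 candidate sites per replicate; on failure the real
  position is reused and counted in the manifest). Matching is at channel
  resolution, not exact indel length; the manifest records
  `id_matching: channel-level`;
* replicate r draws from an independent stream seeded `seed + r`, so the
  output is invariant to scheduling and reproducible from (cohort, seed,
  n);
* with region restriction, only positions inside the regions or their
  10 kb flanks are indexed (the local-background null); with
  transcription-strand matching, candidates are further filtered to the
  source's class (transcribed / untranscribed / bidirectional /
  intergenic), for the indexed context kinds.

## Attribution and selection

`p_s ∝ A[m,s] P[c,s]`, normalized per (sample, channel); a zero denominator
marks the mutation unattributable. The ≥ 90% filter is applied per
mutation, with a guard that the mean probability over each signature's
selected set also meets the threshold — the stricter of the two readings of
an "average probability" filter, and the deterministic one. A signature
enters an analysis only with at least `min_selected_mutations` selected
records (default 100; fixture-scale runs lower it to 50 via config since a
5000-mutation cohort split over two signatures sits well above either
floor). Strand-coordinated analysis needs one label per mutation and uses
the argmax signature among those passing the threshold, ties broken
lexicographically.

## Occupancy

Per offset in ±W (default 1 kb), SUM accumulates the track value at every
covered mutation-flank position and COUNT the number of covered positions;
the profile is SUM/COUNT with zero where COUNT = 0. The scalar test
statistic is the mean of the profile within ±100 bp of the mutation
(configurable): it captures "at the mutation" occupancy while damping edge
noise; the published summaries do not name their exact window, so the width
is exposed in `Config`. The z-test compares it to the replicate
distribution (sd floored at 1e-12; an observation identical to every
replicate short-circuits to z = 0, p = 1, which keeps degenerate constant
tracks exact). The default cohort mode is one pooled test per
(signature, feature) — Fisher's method over k = 1 is the identity — and a
per-sample mode combines per-sample z-test p values with Fisher's method.
Profiles are computed against a base-resolution expansion of the track
chromosome (~9 MB per 2 Mb chromosome), appropriate for the desk-scale
genomes the package targets.

## Replication timing and strand

The Repli-seq track (high = early) is resampled onto 1 kb steps by
overlap-weighted averaging, smoothed with an odd-width moving average
(default 20 kb; an odd kernel is phase-neutral), and reconstructed from the
discrete-wavelet approximation whose scale is nearest `wavelet_scale_bp`
(default 100 kb, the scale of replication domains). The default wavelet is
`bior3.5`: biorthogonal spline filters are (near-)linear-phase, and in
testing asymmetric Daubechies filters displaced the extrema of a synthetic
wave by 5–12 kb while `bior3.5` localized them to within half a step.
Peak/valley detection uses a prominence floor of 10% of the chromosome's
signal range (wavelet ripples otherwise register as domains); consecutive
same-kind extrema are collapsed to the most extreme one so peaks and
valleys alternate.

Timing analysis ranks the smoothed step records in descending order and
splits them into equal-count bins (± 1 record), bin 1 earliest; per-bin
density is mutation count over valid (non-N) bases, normalized to the
maximum (so the largest bin density is exactly 1). The identical
computation per replicate yields the mean and 95% band of the null.

Strand regions: valley→peak spans (signal rising left-to-right) are
leading, peak→valley spans lagging; spans under 10 kb are dropped and 25 kb
is trimmed from the valley (termination) end of each retained span — the
trim is applied to the span end adjacent to the valley, the less ambiguous
reading of "the last 25 kb of replication termination zones". A mutation's
region label is flipped when its pyrimidine representation reads off the
minus strand, which makes flipping every orientation swap the
leading/lagging totals exactly (a tested involution). The per-subtype 2×2
(real vs simulation-expected × lagging vs leading) is tested with Fisher's
exact test; pooled replicate counts are rescaled by 1/n and rounded so both
rows are integer counts. The odds ratio is oriented lagging-vs-leading
(OR > 1 = shifted toward lagging), matching how such biases are reported;
significance requires q ≤ α and OR beyond 1.10 in either direction.

## Transcription strand

Gene footprints are full spans (introns count as genic). With the
pyrimidine on a plus-strand gene's coding strand the mutation is
untranscribed; mirrored for minus-strand genes; overlap with genes on both
strands is "bidirectional" — excluded from the strand comparison (no
defined template strand; the conservative choice) but genic in the
genic/intergenic comparison. Tests mirror the replication-strand setup.

## Strand-coordinated mutagenesis

Within one sample and signature, a group is a maximal run of consecutive
SBS records sharing the reference-strand substitution (C>T distinct from
G>A) with every adjacent gap ≤ 10 kb. "Consecutive" means adjacent in the
position-sorted list of that signature's selected substitutions: an
interleaved same-signature mutation of a different reference-strand subtype
breaks the run; mutations of other signatures do not. A strict mode
(any interleaved SBS breaks) and a span-bound mode (10 kb bounds the whole
group) are available as switches. Counts per (signature, length) pool
across samples; the upper-tail z-test asks whether clustering exceeds the
context-preserving null, with BH over all cells.

## Statistics

Fisher's exact test is two-sided under the "sum of tables at most as
probable" convention (verified against full hypergeometric enumeration for
every table with margins ≤ 30); the all-zero table reports OR = 1, p = 1,
and zero-cell sample odds ratios fall back to the Haldane–Anscombe
corrected estimate. BH is one family per analysis type per run. The
z-test's empirical size at α = 0.05 is verified to lie in [0.03, 0.08]
under the null.

## Synthetic data and what it does (not) show

The fixture generator emulates the assays at desk scale: two 2 Mb
chromosomes at GC 0.41; a 190 bp raised-cosine nucleosome track; a
Repli-seq wave of 200 kb wavelength (≥ 10 waves per chromosome, with
analytically known extrema — fixture-driven analyses therefore set the
wavelet scale to 25 kb instead of the genome-scale 100 kb default);
alternating-strand 25 kb genes covering half the genome; and a cohort from
two channel-disjoint signatures (C>T-uniform and T>G-uniform, so
attribution probabilities are exactly 1 and the selection filter is
exercised without ambiguity). Planted biases multiply the placement weight
of candidate sites: `1 + (ratio − 1)·lateness` for replication timing, and
ratio-weighting of lagging-strand or transcribed-strand placements for the
second signature. Clusters are injected as same-strand C>T runs with gaps
drawn from 1–5 kb.

Chosen problem sizes: bias-recovery runs use 5000 mutations with n = 20
replicates; the cluster-recovery run uses a sparse 300-mutation background
(at 5000 mutations over 4 Mb the inter-mutation distance is ~1.6 kb, so
background runs are common and five extra groups are statistically
invisible — a property of the statistic, not of the implementation); the
null calibration runs 20 unbiased seeds at 1000 mutations and n = 10.
"Monotone" density recovery is asserted as a monotone trend (Spearman
ρ ≥ 0.9 across the ten bins) plus the late/early ratio, because per-bin
sampling noise at 500 mutations/bin makes strict adjacent monotonicity a
coin flip even under a perfect planted gradient.

What passing these tests shows: the machinery recovers known biases of
realistic magnitude and stays quiet on null data at these scales. What it
does not show: behavior on real chromatin (no CpG/mutation-rate
heterogeneity, no real nucleosome phasing or replication-domain geometry is
emulated), performance at human-genome scale, or correctness of any
specific biological claim.

## Known limitations

* Cohorts are held in memory; no tabix streaming of very large inputs.
* Occupancy expands tracks to base resolution per chromosome — fine at
  megabase scale, memory-hungry for full human chromosomes.
* ID simulation matches the ID-83 channel, not the exact indel length.
* Transcription-strand matching during simulation covers the indexed
  context kinds (SBS, DBS, 1 bp ID); multi-bp indels place unmatched.
* No de novo signature extraction; the signature and activity matrices are
  inputs.
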