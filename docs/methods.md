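# Methods

## Background and scope

Knockout-controlled ChIP-seq identifies procedure-driven false positives:
loci enriched both in wild-type chromatin and in chromatin from mutants
that do not express the profiled antigen. The package derives a catalog of
such loci from WT/mutant peak-set pairs, characterizes it, and screens
arbitrary peak sets against it. Read mapping, background subtraction of
tag densities, motif discovery and genome-browser visualization are out of
scope; the pipeline starts from peak sets (BED) and binned coverage tracks
(bedGraph/wiggle).

## Coordinate and interval conventions

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted at the I/O boundary, and chromosome names
are taken verbatim. Merging at `min_gap = 0` joins overlapping *and*
abutting intervals. The midpoint of an even-width interval is the lower
median, `(start + end) // 2`. Strand is carried but ignored by all
interval algebra; only gene-model annotation interprets it.

**Overlap criterion.** "Query overlaps subject by ≥ k bp" is evaluated per
query interval against the *merged* subject: a query qualifies iff a
single merged subject interval shares at least k bases with it. This
convention is used uniformly — replicate consensus, WT∩mutant commonality,
catalog screening — with k = 50 bp throughout (k = 1 for the HDR
diagnostic, where no threshold convention exists and 1 bp is the most
conservative flagging).

## Peak calling and consensus

The built-in caller targets fixed-width punctate enrichment. ChIP and
input tracks (default 25 bp bins) are first scaled to a common total of
10^6 (per-million library-size normalization). Sliding windows of
`peak_width` (default 200 bp) at one-bin stride are scored by ChIP signal;
the expected signal is `max(local input mean over ±5 kb, genome-wide input
mean) × window bins`, guarding against both local accessibility bias and
zero-input regions. A window is a candidate iff the Poisson upper tail
P(X ≥ obs | expected) < 1e-4 — computed via the regularized incomplete
gamma function, which extends the integer tail smoothly to the fractional
counts that normalization produces — and obs/expected ≥ 4. Candidates are
reduced to non-overlapping peaks greedily by decreasing fold, ties broken
leftmost (determinism). All downstream stages accept externally produced
BED peak sets, so any other caller can be swapped in.

Replicate profiles (e.g. different antibodies against the same factor) are
combined by single-linkage chaining on the pairwise ≥ 50 bp overlap
relation; a chained group supported by at least `min_support` distinct
replicates emits one consensus peak — a fixed-width window centered on the
score-weighted mean of member centers, scored by the mean member score.
`min_support` is an explicit argument. Under the reference study
conditions (3 replicates, 10% dropout) all-replicate support retains only
0.9³ ≈ 73% of true loci, so the pipeline's study condition is majority
support (2 of 3), which retains ≈ 97% per genotype while still requiring
independent confirmation.

## Catalog derivation and the HDR diagnostic

`common_peaks(wt, mutant)` returns the WT peaks with a qualifying mutant
overlap (Venn counts are per-profile peak counts, so one anchor must be
fixed; WT is used and documented). `build_catalog` merges the union of the
per-factor common sets (merge gap 0 by default) and records, per merged
locus, every factor label contributing an overlapping member; the result
is order-independent.

High read density regions are the top input-coverage bins. The threshold
is rank-based: the k-th highest bin value with k = max(1, ⌊f·n⌋) over all
genome bins including zeros, ties included — a plain rank rule rather than
an interpolated quantile, so "top 1% of 1010 bins" selects exactly the 10
highest (plus ties). Selected bins are merged; because high bins cluster,
the merged-region genome fraction exceeds the bin fraction. Catalog loci
overlapping HDRs are reported (and optionally filtered), separating
immunoprecipitation-stage artifacts from copy-number/accessibility
artifacts; by default the catalog is left intact.

## The reference-constrained overlap test

Screening conditions on the shared promoter preference of query and
catalog. Reference regions default to the merged union of 4 kb windows
centered at every TSS. Under the null each query peak is independently
relocated, width preserved, to a uniformly random allowed start — the
positions where the full peak fits inside a single reference region.
Observed peaks outside the reference are still relocated into it: the
asymmetry deliberately asks "would this much overlap arise among
promoter-resident peaks anyway?". Peaks wider than every reference region
are excluded and reported rather than failing the batch.

For each width the allowed-start space is enumerated exactly and the
qualifying starts (≥ min_overlap with a merged catalog locus: start x
qualifies for locus [s, e) iff s + k − w ≤ x ≤ e − k, ranges merged across
loci) are precomputed, so a permutation is an integer draw plus a table
lookup and the per-peak success probability q_w is exact. The permutation
p-value uses the add-one estimator; the analytic cross-check is the exact
Poisson-binomial upper tail of the observed count under the per-width
q_w's (a plain binomial when widths are uniform). Batch screening reports
Benjamini–Hochberg-adjusted p-values in a separate column, but profile
flagging (> 20% overlap at p < 0.05) uses the plain permutation p.

**Discreteness.** The overlap count T is integer-valued. When the catalog
is sparse relative to the reference (small q_w), the null pmf places
non-negligible mass on single values of T and no valid permutation test
can reject at exactly the nominal rate — the achievable size is the
nearest attainable tail below it, i.e. the test is conservative, never
anticonservative. Calibration experiments therefore use a promoter-like
calibration catalog dense enough (q ≈ 0.2) that the 5% level is
resolvable, with n_perm = 999 so the p-value grid (1/1000) resolves the
threshold; the sparse-catalog regime is checked separately for
conservativeness. Seeds fix all permutation draws; identical seeds give
identical p-values.

## Annotation

Feature assignment is midpoint-based with fixed priority promoter > TTS >
exon > intron > intergenic, so category fractions partition to 1 (the
pie-chart convention). Promoter and TTS windows are TSS ± 1000 bp and
TTS ± 1000 bp (half-open); the half-width is a parameter because the
"region of 1000 bp around the TSS" convention is ambiguous between ±500
and ±1000. Ties between genes are broken by smaller |distance to TSS|,
then lexicographic gene id. TSS-window localization counts locus midpoints
inside the merged 4 kb-window union. Expression quintiles rank genes
ascending and split them into five equal groups, remainder to the lower
bins; per group the fraction of genes whose promoter window contains a
catalog-locus midpoint is reported, genes without expression values being
excluded and tallied. Histone-mark co-occurrence is a binary loci × marks
matrix (≥ 1 bp default); the TF-count profile counts distinct overlapping
TF labels per locus, and loci with strictly more than 8 distinct factors
are HOT, following the published convention for high-occupancy target
regions.

## DamID derivation

Probes scoring at or above the rank-based top-fraction cutoff (default top
1%, ties included; at least 100 probes required) become intervals of total
width `extend_to` (default 1 kb) centered on the probe position — symmetric
extension, since probe positions are strand-undefined points — clipped at
zero (clipping shortens rather than shifts), then merged. Comparison
against a catalog delegates to the reference-constrained test. The
percentile is computed per probe table.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
sequencing reads. Defaults define the reference study conditions used by
the test suite and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 1 Mb chromosomes | desk-scale stand-in for a fly-sized genome |
| genes | 500, non-overlapping, 2–4 exons | ~4 kb spacing, strand random |
| expression | log-normal(μ=1, σ=1) | arbitrary units, rank is what matters |
| sticky propensity | logistic(−4 + 5·rank_pct) | active promoters are stickier; ≈ 25% of genes |
| sticky locus | 200 bp at the TSS | placed exactly at the TSS so promoter fractions are analytically predictable |
| genuine loci | 100 per factor | uniform over space clear of sticky loci |
| replicates | jitter N(0, 20 bp), dropout 0.1 | antibody-to-antibody variation |
| background peaks | 5 per Mb per replicate | spurious calls, placed clear of planted loci so ground truth stays identifiable |
| coverage | Poisson, 10 reads/bin; HDRs ×10; ChIP +10× at loci | 25 bp bins |
| HDRs | 1% of the genome in 1 kb regions | accessibility/copy-number proxy |
| DamID | probes every 100 bp, N(0,1) + 4 at targets | tiling-array proxy |

All randomness flows from one root seed; per-stage child generators are
derived by hashing stage names (CRC-32 into a SeedSequence), so each
artifact is reproducible in isolation and stages are statistically
uncoupled.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mappability and GC bias, duplicate reads,
fragment-size effects, chromatin-state-dependent shearing, antibody
cross-reactivity structure, and peak-width variability. The planted truth
is clean by construction; real catalogs inherit every upstream calling
artifact.

## Problem sizes and runtime

The test suite and acceptance script run the full derivation on the 2 Mb /
500-gene world (seconds per stage), calibrate the permutation test with
500 null replicates of 200 peaks at n_perm = 999, grade the interval
kernel against per-base oracles on 1000 random ≤ 10 kb instances, and
check quintile monotonicity over 20 seeds of a 1 Mb / 250-gene world.
These sizes were chosen so the whole suite completes in about a minute on
one CPU while every contract is still statistically sharp.

## Known limitations

* The reference-constrained null treats query peaks as independent;
  clustered query peaks (e.g. broad domains split into fixed-width calls)
  inflate the effective count and make the test anticonservative for such
  inputs. Screening is intended for punctate profiles.
* The analytic cross-check assumes the same independence; it is a
  Poisson-binomial tail, not a corrected family-wise bound.
* The fixed-width caller is a defined stand-in, not a reimplementation of
  any published caller; variable-width and broad-domain signals are out of
  scope.
* `common_peaks` is WT-anchored; peak-count asymmetries between WT and
  mutant profiles shift Venn counts but not the merged catalog bases.
* The rank-based top-fraction rule includes all ties at the threshold, so
  heavily tied score distributions can select more than the nominal
  fraction.
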