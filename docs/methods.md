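# Methods

This note documents the models and procedures implemented in `tgct`, the
parameters that matter, what the synthetic-cohort generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Variant quality filtering

Somatic SNV calls pass through two predicate filters before any statistic
is computed.

**Oxidation-artifact filter.** 8-oxoguanine damage during library
preparation produces spurious C>A/G>T calls that are strand-biased and of
low quality. An SNV is retained only if it has at least one supporting
read on *each* strand, mean Phred base quality strictly greater than 26,
mean mapping quality of at least 50, and a reference alignability score of
exactly 1.0 (compared within 1e-9). The boundary semantics are deliberate
and tested: base quality 26.0 fails, mapping quality 50.0 passes. Failure
reasons enumerate every violated criterion. Indels bypass this filter —
the artifact mechanism is specific to single-base oxidation — but remain
subject to the germline filter.

**Common-germline-SNP filter.** Calls recorded in population panels at a
minor allele frequency strictly above 0.25 are removed as mis-subtracted
germline polymorphism; a missing annotation (absent from every panel)
retains the call. The two filters commute; they are applied
oxidation-first only so that failure-reason lists are reproducible.

## Landscape statistics

*Mutation rate.* Per-sample rate = qualifying calls / target size (Mb);
the default qualifying set is the non-synonymous consequences {missense,
nonsense, splice, frameshift, inframe, other}, and the default target is
the 37 Mb capture. Zero-variant samples enter at rate 0; the cohort s.d.
uses the n−1 denominator. All samples share a single target size; the
cohort mean therefore equals the pooled-count rate.

*Spectrum.* Each SNV maps to one of six pyrimidine-reference classes
(purine-reference substitutions are replaced by their reverse complement),
and proportions are reported over {C>A, C>G, C>T, T>A, T>C, T>G}. An empty
input reports all proportions as missing rather than zero.

*Recurrence.* Per gene: distinct mutated samples, total qualifying
mutations, percent of cohort, and per-histology percentages. Percentages
are rounded to one decimal, half away from zero.

*Age association.* Pearson correlation of per-sample rate with age, plus a
two-sided equal-variance t-test of rates between patients above and at or
below 40 years. Degenerate inputs (no rate variance, all ages equal)
report a missing correlation rather than NaN.

## Driver statistics

The recurrence null is binomial: each of the n tumours independently
mutates a given gene with probability

    p_bg = 1 − (1 − μ·10⁻⁶)^L,

the per-base background rate μ·10⁻⁶ (μ in mutations/Mb) compounded over a
gene footprint of L bp (default 1,500 bp, a typical coding footprint; the
parameter is exposed because published per-gene footprints vary). The
pipeline uses the cohort's own measured non-synonymous rate for μ. The
test p-value is the exact upper binomial tail, evaluated as a log-space
sum; no normal approximation is used anywhere, because with n = 42 and a
genome-wide threshold of 5×10⁻⁶ the relevant probabilities sit deep in the
tail.

Cohort detection power for a driver at population frequency f is computed
in two exact steps: k_min is the smallest mutated-sample count whose tail
probability under p_bg reaches the genome-wide threshold, and power is the
upper tail of Binomial(n, f) at k_min. With the package defaults (μ =
0.51/Mb, L = 1,500 bp, α_gw = 5×10⁻⁶, n = 42) this gives k_min = 4 and
powers of 0.16 / 0.62 / 0.89 at f = 5% / 10% / 15% — high power above 15%
frequency and little power at 5%, the qualitative regime the study
describes. At μ = 0.50 the significance count flips to k_min = 3 and the
low-frequency power rises to 0.35; the power landscape is sensitive to the
assumed background, which is why both μ and L are configuration, never
constants.

Independent experiments are combined with Fisher's method: −2Σln p is
χ²-distributed on 2k degrees of freedom under the global null. For k = 2
the closed form pq(1 − ln pq) is used as a test oracle.

## CNV calling

**Log-ratios.** Per-exon tumour depths are scaled by total-normal /
total-tumour (library-size normalization; median-ratio normalization is
available behind the `normalization` parameter), then log2((t·s + c)/(n +
c)) with pseudocount c = 0.5 for zero-depth robustness. Bins with zero
normal depth are flagged unusable and excluded from segmentation. A
consequence of library-size scaling worth knowing: in a genome-rich sample
(many gains) neutral bins sit slightly below ratio 1; thresholds are far
enough from 1 that calls are unaffected at the simulated event sizes.

**Segmentation.** A simplified, non-pruned circular-binary-segmentation
variant. On a segment of n bins the candidate changes are circular arcs
[i, j) compared against their complement with a pooled two-sample
t-statistic, restricted to (a) arcs of min_bins ≤ length ≤ max_arc_bins at
any anchor and (b) arcs anchored at the left boundary of any length
(ordinary binary splits); arcs ending at the right boundary are excluded
as complements of prefix splits, so every candidate partition has a single
representation and every resulting piece is empty or at least min_bins
long. Short interior arcs are what detect a 3-bin amplification in the
middle of a 3,000-bin chromosome — a statistic comparing only left-vs-right
means is essentially blind to it — while boundary-anchored splits catch
large-scale level shifts, which recursion then refines.

The maximal-|t| candidate is accepted when it beats a permutation null:
the segment's values are permuted (seeded generator, blocks of 150) and
the candidate is accepted when fewer than ⌈α·B⌉ of B = 1,000 permutation
maxima reach the observed maximum (α = 0.01). Two sequential shortcuts
keep this affordable without changing decisions materially: permutation
stops early once the exceedance budget is spent (the split can only be
rejected), and a candidate with zero exceedances after 300 permutations is
accepted early (the point estimate of its p-value is then at most ~1/300,
well under α). Accepted arcs recurse into up to three sub-segments;
recursion stops when no candidate is accepted or a segment is shorter than
2·min_bins. `max_arc_bins` (default 20) is a sensitivity/runtime
trade-off: events longer than the cap are still found, through splits, but
interior arcs above it are not scanned directly.

**Calling.** Segment mean ratio is 2^(mean log2 ratio). Gain requires
ratio strictly above 1.3, loss strictly below 0.7. Each non-neutral call
carries a specificity score: the segment mean is standardized against a
null Normal(median, σ_MAD/√n_bins) fitted on all usable bins of the sample
(σ_MAD = 1.4826·MAD), and specificity = 1 − P(|Z| ≥ |z|). Calls below the
required specificity (default 0.9999, i.e. a score that prints as 1.0 at
four decimals — literal equality is unattainable for a continuous score)
are downgraded to neutral with a `low_specificity` flag. This score is
this package's own formulation of a "specificity confidence" for a
segment; it is deliberately simple and documented rather than borrowed.

**LOH.** At germline heterozygous sites with tumour depth ≥ 8, the tumour
alt depth is tested against B-allele frequency 0.5 with an exact two-sided
binomial test; a site is LOH when p < 10⁻³ *and* the tumour BAF leaves
[0.3, 0.7]. A segment is flagged LOH when strictly more than half of its
covered sites are LOH. All four thresholds are configuration; the defaults
are conservative choices for ~70× exomes, not published constants.

## CNV landscape

* **Scale.** Non-neutral segments of length ≥ 3 Mb are large-scale,
  shorter ones focal (the boundary itself is large-scale).
* **Arm/chromosome summary.** An arm is gained (lost) when gain (loss)
  segments cover ≥ 90% of its length; a chromosome event requires both
  arms, except on acrocentric chromosomes (14, 21, 22, Y here) where the
  q arm alone decides, since the p arm carries no usable probes.
  Isochromosome 12p is flagged as 12p gained without a 12q gain.
* **Chromothripsis.** An arm is flagged when strictly more than 20
  non-neutral segments lie fully within it; segments spanning the
  centromere count toward neither arm.
* **Genome CNV fraction.** Union length of non-neutral segments over
  genome length, overlaps counted once.
* **Unstable-sample exclusion.** Samples whose focal-CNV count exceeds
  mean + 2 s.d. of the cohort (single pass) are excluded from recurrence
  analysis; cohorts under 3 samples are never filtered. The study
  identifies its unstable tumours descriptively; the 2-s.d. rule is this
  package's operationalization and recovers exactly the constructed
  outliers on the fixture.
* **Gene mapping and artifact removal.** Focal events map to every gene
  whose coding span they overlap by ≥ 1 bp (one event per gene–segment
  pair). Events grouped by identical segment interval across samples are
  removed when the group spans ≥ 3 samples *and* contains both gains and
  losses — the signature of probes with unstable coverage rather than true
  alteration. The "≥ 3 samples" quantification of "frequently" is a
  package default, exposed in configuration.
* **Recurrence ranking.** Counts are events, not samples (a tumour with
  two separate amplifications in one gene contributes two). Genes with
  identical event footprints collapse into a single row (this is how an
  amplified multi-gene cluster reports as one region). Rows with total ≥ 5
  are kept, sorted by total then region.
* **Focal significance.** Exact binomial upper tail on distinct affected
  samples. The per-sample background probability of a chance hit is
  estimated from the cohort itself: mean focal events per retained sample
  × (mean event length + gene span)/genome length, capped at 1 — a
  deliberately simple empirical default, exposed as an argument because no
  published value exists for it. Meta-analysis against an external cohort
  delegates to Fisher's method.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, on
a reduced genome: ten chromosomes (1, 2, 6, 7, 12, 14, 21, 22, X, Y) with
published hg19 lengths and centromere positions scaled down 10×,
acrocentric annotations preserved, and an exome probe grid of 200 bp bins
every 4 kb (~34,400 bins, chosen so that an 8–9 kb focal amplification
covers exactly 3 bins = the minimum segment size). The normal genome is
male: X and Y run at single copy, so tumour/normal ratios keep their
usual thresholds.

Per sample: non-synonymous counts are Poisson around rate × target (37 Mb
default), with a configurable indel share (default 0.14 of non-synonymous
calls) and synonymous calls at 0.61 per non-synonymous; substitution
classes are drawn from the configured six-class weights (defaults 0.31 /
0.27 / 0.23 on C>A / C>T / T>C, remainder split evenly); driver spikes
place mutations in distinct samples honoring VAF ranges and histology
restrictions; oxidation artifacts violate at least one filter criterion
each; common SNPs carry population MAF > 0.25. Depth is Poisson per exon
around 73.6× (tumour) and 69.0× (normal) — the configured means apply to
the diploid autosomal baseline, so genome-wide means sit lower on account
of the sex chromosomes — with negative-binomial overdispersion behind a
configuration knob. CNV spikes multiply tumour depth over their interval;
chromothriptic samples receive 26 alternating gain/loss spikes of 4 bins
on one arm. Germline het sites are Binomial(depth, 0.5) in the normal
(ascertained into a 0.2–0.8 BAF band) and skewed to BAF 0.15 where a copy
is lost in the tumour.

The **paper fixture** is a fixed-seed bundle whose truth ledger
transcribes the study's printed counts: 42 samples (16 seminoma / 18
non-seminoma / 4 mixed / 4 indeterminate), 795 non-synonymous calls (111
indels) and 484 synonymous SNVs distributed near-uniformly, KIT in 6
tumours (5 seminomas; 5 in the exon-17 analogue, 1 in exon 11), CDC27 in 5
at VAF 0.08–0.14, PRKRIR 4/2, one KRAS, one XRCC2 in the single
treatment-refractory sample, 33 common SNPs, one oxidation artifact per
tumour, the large-scale events 12p×30 (25 isochromosome-pattern: p-arm
ratio 1.8 with neutral q; 5 whole-chromosome at 1.5), X×16, 7×15, 21×12,
22×11, Y-loss×10 arranged so exactly 35 tumours carry a large-scale event,
FSIP2 amplifications (7 events, 6 tumours, 8.5 kb at ratio 3) plus 2
FSIP2 deletions, a 0.4 Mb 18-gene Xq28 amplification in 6 tumours, a
bidirectional coverage-artifact region, and 3 chromothriptic samples.
Genes without a home chromosome in the reduced genome (KIT, CDC27,
PRKRIR) are placed at fixed synthetic coordinates; FSIP2, KRAS, XRCC2,
AKAP4 and the Xq28 cluster sit on their real (scaled) chromosomes.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: read-level noise (no FASTQ/BAM), GC and
mappability bias in coverage (depth is exchangeable Poisson, which is why
no GC correction stage exists), trinucleotide context in the spectrum,
clustered/kataegis mutations, tumour purity and subclonal structure beyond
per-variant VAF labels, and the paper's per-sample rate dispersion (the
fixture matches printed totals and per-gene counts; its rate s.d. is
necessarily far below the published 0.24 because per-sample counts were
never printed).

## Problem sizes and determinism

The fixture analysis (42 samples × ~34k bins, 1,000-permutation CBS) runs
in a few minutes on one core; the recovery study (50 seeded simulations)
and the 100-seed segmentation oracle run in under a minute. Every
stochastic component takes an explicit seed: cohort generation from
`CohortConfig.seed`, segmentation from per-sample seeds spawned
deterministically from the pipeline seed. Identical (config, seed) pairs
produce byte-identical outputs; the fixture itself is seed-fixed by
definition.

## Known limitations

* The CBS variant is the simplified recursive form: no pruning of
  breakpoints, no undo step, and interior arcs longer than `max_arc_bins`
  are only found via recursive splits. On desk-scale instances the
  ≤20-bin exhaustive oracle pins its behaviour exactly; on real 100k-probe
  exomes a production implementation (e.g. DNAcopy's) would be preferred.
* The specificity score assumes an exchangeable per-bin null; waviness or
  GC structure in real coverage would inflate it.
* Focal-recurrence significance depends on the empirical background
  estimate above; it is a ranking aid, not a calibrated genome-wide test.
* Absolute copy number, ploidy and purity are out of scope throughout;
  calls are relative tumour/normal ratios.
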