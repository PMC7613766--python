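# Methods

## Scope and model

The package analyzes the chromatin geometry and knockdown response of a
repressor complex in which one factor (GFI1-like) binds DNA through a
sequence motif and two partners (HMG20B- and LSD1-like, CoREST components)
co-occupy chromatin beside it. Its measurements are built from four
primitives: peak summits (single-base positions of maximal pileup), summit
windows on binned signal tracks, strength cohorts (equal-size deciles of
peaks ranked by pileup), and a preranked gene-set enrichment score. All
coordinates are 0-based half-open internally; MACS2 `.xls` 1-based inputs
are converted at the boundary.

## Peak operations

Filtering retains peaks with pileup ≥ 50 and fold enrichment over input ≥ 5
(both configurable) after removing any peak whose *interval* shares a base
with a blacklist region — blacklists flag artifact regions, not points, so
summit-only exclusion would be too permissive. narrowPeak carries no
fold-enrichment column, so peaks read from narrowPeak get `+inf` fold
enrichment (never filtered on it) unless a MACS2 `.xls` sidecar supplies it
by name. A summit offset of −1 falls back to the interval midpoint.

Cohort assignment sorts by pileup, breaking ties by fold enrichment, then
chromosome, then start, and discards the `N mod 10` weakest peaks so all ten
cohorts have exactly `⌊N/10⌋` members (with 18,385 peaks: 1,838 per cohort,
5 discarded; distributing the remainder would produce mixed 1,839/1,838
cohorts and unequal ANOVA group sizes).

Annotation classifies the *summit* (not the whole interval) with precedence
promoter > 5'UTR > 3'UTR > exon > intron > TTS > intergenic. The promoter
window is strand-aware, 1 kb upstream to 100 bp downstream of the TSS, and
the TTS window mirrors it; these are conventional annotator defaults. Gene
tables without exon structure collapse the gene body to intron.

## Co-localization and distances

Two summits co-locate when separated by ≤ 100 bp on the same chromosome.
Matching takes, per anchor peak, the nearest partner summit (equidistant
ties to the smaller coordinate; identical coordinates to the
lexicographically smaller name); matching is not forced one-to-one. Triples
anchor on strong GFI1 peaks (pileup floor configurable, default 300 in
pileup units) and require the HMG20B and LSD1 partners within 100 bp of the
anchor *and* of each other. Signed distances (partner − anchor) preserve the
side structure, so the HMG20B→GFI1 vs LSD1→GFI1 correlation measures side
consistency; distributional summaries (mean, SEM, median, IQR) use absolute
distances, compared by one-way ANOVA with Tukey HSD. Pearson correlations
are reported with Spearman alongside. By construction
`signed(H→L) = signed(H→G) − signed(L→G)` for every triple.

## Motif positional curves

Consensus scanning is exact IUPAC matching on both strands (overlaps
included); an occurrence is anchored at `start + len//2` so curves are
symmetric under strand collapse. The positional curve reports, per offset
`o ∈ [−W, W]` (default W = 250 bp), the fraction of summits with ≥ 1
occurrence centered at `summit + o`, smoothed by a centered 5-bp moving
average. Background is the mean smoothed probability over the outer flanks
(|o| ≥ 0.8 W); the enrichment threshold is background + 2 flank standard
deviations (both knobs surfaced). Width is the maximal contiguous
above-threshold run containing the global maximum. Apex candidates are
local maxima of the smoothed curve above the threshold anywhere on the
curve — not only inside that run, because with near-zero background a
single empty offset can split the run and would silently drop the
opposite-side apex that bimodality reporting exists to capture. Each apex
is then refined to the raw-curve maximum within the smoothing half-window:
the smoothed curve locates the peak region, the raw counts give the modal
offset (this removes the ±2 bp plateau quantization a 5-bp average
introduces on sharp curves). The curve is bimodal when apexes on both sides
of zero each reach 70% of the global maximum; both signed offsets are then
reported. Enriched-region widths depend on the scanner and smoothing
settings, so only their ordering across factors (anchor narrowest) is
meaningful, not their absolute values.

## Signal windows and cohort statistics

Signal tracks are uniform bins (default 10 bp); a window statistic is the
mean of bins whose *centers* fall in `[summit − h, summit + h)` with
h = 300 bp for factor ChIP ratios and h = 1000 bp for acetylation fold
changes. Edge windows use the available bins; a window narrower than one
bin uses the summit's bin. Fold change and ratios add a pseudocount
ε = 0.5 signal units (configurable) to numerator and denominator; cohort
means are on the plain FC scale, matching how such panels are usually
axis-labelled. Cohort comparisons use one-way ANOVA plus Tukey HSD; a
cohort is called "affected" when its Tukey contrast against *every* bottom-
five cohort is significant (α = 0.01) with a consistent sign. Tukey already
adjusts within the contrast family, so no further correction is layered on.

The GFI1 anchor is a single global scalar `α = Σ NTC / Σ KD` over all peak
windows of the anchor factor, not a per-peak rescaling — per-peak anchoring
would cancel the locus-level LSD1 biology the ratio analysis measures. The
simulator's knockdown depth artifact is track-wide, so the pipeline applies
α to all knockdown-condition factor window signals (LSD1, GFI1, HMG20B)
before ratio-change and absolute-loss analyses; anchoring only LSD1 while
GFI1 remained scaled would leave the LSD1:GFI1 ratio biased by the
technical scale. With noise off this normalization is exact: every
anchored GFI1 cohort ratio equals 1 to floating-point precision.

## The simulator and what it does (not) emulate

Sites sit on a jittered grid guaranteeing ≥ 2 kb spacing (so ±1 kb windows
never overlap), ≥ 1 kb from chromosome ends. Per site: side `s` uniform on
{−1, +1}; distance `d` = 9 bp modal + truncated normal noise (sd 2 bp,
d ≥ 0); each partner adds independent ±2 bp uniform jitter. One exact
realization of the IUPAC consensus (default `TAAATCACWGC`, an explicitly
arbitrary GFI1-like 11-mer — chosen, not measured) is written into the
genome centered on the anchor summit, random strand. 95% of sites are
co-located; at the rest the partners are displaced 300–800 bp to opposite
sides, out of matching reach. Strengths are floor (50) + lognormal
(μ = ln 40, σ = 1) with a Gaussian copula (ρ = 0.9) across factors —
chosen so pileup magnitudes, strong-peak thresholds and cross-factor
strength correlations sit in the range typical of deep ChIP-seq peak
tables. Tracks render each site as a Gaussian bump (sd 75 bp ≈ a ChIP
fragment-size footprint) of height proportional to strength, with optional
per-bin Poisson noise.

Knockdown biology is keyed to the HMG20B strength rank: retention 0.4 for
HMG20B and 0.6 for LSD1 at the strongest 40% of sites (1.0 below — the
published analyses find effects confined to strong peaks, but report no
quantitative retention values, so these are qualitative mimics);
acetylation gain (+100%) at the strongest 30%; H3K27Ac/ATAC baseline
amplitude inversely proportional to strength above the 70th percentile; a
flat H3K4Me1-like mark; and a CEBPA-like control factor whose acetylation
scales with its own strength but ignores the knockdown. `lsd1_coupled=False`
removes the LSD1 response entirely — the uncoupled null for the loss–loss
correlation. Alternatives were measured and rejected as nulls: iid or
permuted per-site retention still makes cohort *absolute* loss proportional
to cohort mean strength (lognormal), hence strongly correlated with the
HMG20B loss profile, and a disjoint mid-strength deficit band produces a
systematic anti-correlation (r ≈ −0.6).

Genes: 60% receive a TSS within ±500 bp of a distinct site, the rest are
placed > 5 kb from any site; two 300-bp exons and 100-bp terminal UTRs give
the annotator its full category set. The gene nearest each strong
(top-30%) site scores `+3` plus unit Gaussian noise; others pure noise; an
FPKM ≥ 0.25 expressed-gene filter (lognormal FPKMs) is applied before
ranking, ties broken by gene identifier.

Not emulated: read-level data (no FASTQ/BAM), fragment-length and GC
biases, duplicate reads, overlapping peaks, copy-number structure,
condition replicates, and any enhancer–gene wiring beyond nearest-TSS.
Passing tests therefore demonstrate estimator correctness under the planted
statistical structure, not robustness to those real-data complications.

## Enrichment engine

Preranked GSEA with gene-set permutation (the standard null when the input
is a ranked list rather than per-sample expression): ES is the signed
maximum deviation of the weighted KS running sum (weight p = 1); the
positive extreme wins sign ties only when strictly larger in magnitude,
with a 1e-12 tolerance so exact mathematical ties cannot flip on summation
order. The null is `n_perm` size-matched random gene sets; NES divides ES
by the mean |same-sign null ES|; nominal p is one-sided with the +1
small-sample correction; FDR q is the standard pooled-NES ratio, clamped to
[0, 1] and made monotone non-increasing in |NES| within each sign by a
least-to-most-extreme running minimum. Nearest-gene mapping replaces
GREAT's basal-plus-extension regulatory domains deliberately: the target of
the cohort analysis is the cohort-level enrichment pattern, which
nearest-TSS mapping preserves, not per-gene regulatory assignments (which
no desk method gets right for enhancers).

## Problem sizes and numerical choices

The test suite validates on 600-site simulations (3 Mb genome); the
positional/distance recovery runs at 5,000 sites on 16 Mb, and the
knockdown cohort analyses at the generator default of 2,000 sites with
rendered tracks — sizes at which every planted effect is comfortably
over-powered while a full run stays in the tens of seconds. Determinism:
every operation draws from `default_rng([seed, salt])` with a fixed salt
per operation, so identical configurations give byte-identical outputs and
operations are insensitive to call order. Degenerate inputs are errors
(empty peak sets for selection/matching, < 3 points for correlations,
windows entirely off-chromosome, gene sets disjoint from or equal to the
ranked list) rather than silent NaNs; zero-triple and comment-only-file
cases return typed empty results.
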