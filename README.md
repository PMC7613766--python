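# cooccupy

Genome-wide co-occupancy analysis for transcription-factor complexes, built
around the chromatin biology of the GFI1–LSD1–HMG20B repressor axis in
leukemia cells: a sequence-specific anchor (GFI1) binds its consensus motif,
and partner proteins (the CoREST components LSD1 and HMG20B) co-occupy
chromatin a few base pairs to one side of it. The package provides, as an
importable library:

- **Peak handling** — ENCODE narrowPeak and MACS2 `.xls` dialect I/O,
  blacklist exclusion, the stringent threshold filter
  (pileup ≥ 50 ∧ fold enrichment ≥ 5), strong-peak selection, ten-cohort
  strength grouping, and summit-based genomic annotation
  (promoter/UTR/exon/intron/TTS/intergenic).
- **Summit co-localization** — nearest-summit matching within ±100 bp,
  Venn/overlap fractions, cross-factor strength correlation, and the
  anchored triple analysis: signed inter-summit distances
  (HMG20B→GFI1, LSD1→GFI1, HMG20B→LSD1), their correlations, and
  mean/SEM distance comparisons by one-way ANOVA with Tukey HSD.
- **Motif positional curves** — IUPAC consensus scanning on both strands and
  CentriMo-style positional-probability curves around summits, with
  enriched-region width, apex offset(s) and bimodality metrics.
- **Knockdown cohort statistics** — windowed signal aggregation (±300 bp /
  ±1 kb around summits), per-cohort fold change and LSD1:GFI1 ratio change
  with ANOVA + Tukey contrasts (top cohorts vs bottom five), the
  GFI1-anchored normalization (a single global scalar equalizing total GFI1
  signal across conditions), cohort-level loss–loss correlation, and
  strength-vs-mark boxplot statistics.
- **Gene-set enrichment** — nearest-TSS peak-to-gene mapping, per-cohort
  gene sets split into promoter vs enhancer peaks (GMT output), and a
  preranked GSEA engine: weighted Kolmogorov–Smirnov running-sum ES,
  gene-set-permutation null, NES, nominal p and NES-ratio FDR.
- **A ground-truth simulator** — genomes, motif-anchored triple sites with
  side-consistent offsets (side `s ∈ {−1,+1}`, distance `d ≈ 9 bp`),
  copula-correlated lognormal peak strengths, Gaussian-bump signal tracks
  with Poisson noise, knockdown retention restricted to strong sites, an
  inverse strength–acetylation relation, a strength-neutral control factor,
  and knockdown-responsive genes with an RNK ranked list — all recorded in a
  truth table so every estimator can be validated against known parameters.

## The statistics at the core

For a peak set ranked by MACS2 pileup `s₁ ≥ s₂ ≥ … ≥ s_N`, cohort `k`
(k = 1 strongest) holds peaks `(k−1)·⌊N/10⌋ < i ≤ k·⌊N/10⌋`. For a per-peak
statistic `xᵢ` (e.g. fold change `FC = (KD+ε)/(NTC+ε)` over a summit
window), cohorts are compared by one-way ANOVA with Tukey HSD. The anchor
factor is `α = Σᵢ NTCᵢ(GFI1) / Σᵢ KDᵢ(GFI1)`, applied multiplicatively to
knockdown-condition factor signals. The enrichment score of a gene set in a
ranked list of N genes with N_h hits is the signed maximum deviation of the
running sum with hit increments `|rⱼ|^p / Σ_hits |rⱼ|^p` and miss decrements
`1/(N − N_h)`.

## Worked example

`examples/` holds one short script per capability. Running
`examples/03_summit_colocalization.py` and
`examples/04_motif_positional_curves.py` (2,000 synthetic sites, seed 1)
prints:

```
HMG20B peaks with a GFI1 summit within 100 bp: 94.9%
... with an LSD1 summit: 94.9%  (either: 94.9%)
HMG20B vs LSD1 peak strength: Pearson r = 0.83 (p = 0, n = 1898)

triples anchored on the strongest GFI1 peaks: 380
corr(signed HMG20B->GFI1, LSD1->GFI1) = 0.975
corr(signed HMG20B->LSD1, HMG20B->GFI1) = 0.040
mean absolute inter-summit distances (bp):
             mean   sem  median
hmg20b_lsd1  1.67  0.06     2.0
hmg20b_gfi1  8.94  0.11     9.0
lsd1_gfi1    9.05  0.12     9.0

consensus TAAATCACWGC: 2003 occurrences on both strands (2000 planted)
   gfi1: enriched width 5 bp, single apex at 0 bp
 hmg20b: enriched width 37 bp, bimodal apexes at (-9, 9) bp
   lsd1: enriched width 36 bp, bimodal apexes at (-9, 8) bp
```

Reading: 94.9% of HMG20B peaks co-locate with the other two factors (95%
planted); partner→anchor distances are strongly mutually correlated while
partner→partner distances are small and uncorrelated — the signature of
HMG20B and LSD1 sitting together on one side of GFI1; and the motif curves
recover the planted geometry from sequence alone — the anchor's curve peaks
on its own summit, the partners' curves are bimodal with apexes at the
planted ±9 bp offset. `examples/05_knockdown_cohort_analysis.py` shows the
knockdown side: acetylation gain detected in exactly the three strongest
cohorts, LSD1:GFI1 ratio reduction in exactly the four strongest, a flat
CEBPA-like control, and cohort LSD1 loss tracking HMG20B loss at r ≈ 0.999.

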