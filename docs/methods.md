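# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `calq`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All genomic coordinates are 0-based, half-open (BED convention); an
interval `[start, end)` covers `end − start` bp, and abutting intervals do
not overlap. Overlap queries are strand-blind; strand matters only for
5′→3′ orientation (TSS derivation, meta-profile bin order). The TSS of a
minus-strand gene is `end − 1`, the 5′-most base *inside* the half-open
gene interval. Symmetric windows around a TSS are clipped to
`[0, chromosome length)`; a window that clips to nothing is dropped with a
warning. Overlap means ≥ 1 shared bp with a single interval of the other
set (shared bp are not pooled across intervals); `min_bp` raises that
requirement. Nearest-neighbour distance is 0 for any overlap (including
half-open abutment, where the gap is 0 bp), otherwise the gap between
closest ends; ties break toward the lower start coordinate, then the lower
input index, so results are independent of input ordering.

## Spike-in calibration

The estimand is signal per cell. With cell mixing fraction *c* and
per-sample mixing jitter, the control ratio α = s/m cancels the jitter
because doubling the spike-in cell input doubles both s (spike reads in the
control) and the spike material in the ChIP, leaving D = S/α proportional
to sequencing depth per target cell. Subsampling with p = min(D)/D uses the
*minimum* corrected depth as reference — the only choice that never
requires upsampling (all p ≤ 1). Fragments, not read pairs, are the
counting unit. Spike-in fragments are dropped after factor computation;
they carry no further information. Subsampling uses one RNG stream per
sample, keyed `(seed, crc32(sample name))`, so adding a sample to an
experiment never changes another sample's subsample. Duplicate removal and
blacklist filtering are assumed already applied upstream; an optional
blacklist interval filter is provided for convenience.

Coverage tracks are exact run-length-encoded pileups (the track integral
equals the sum of fragment lengths, asserted in tests). Ratio tracks bin
both inputs to a common fixed bin (default 50 bp, mean depth per bin)
before `log2((a + pc)/(b + pc))` with pseudocount 1.

## Quantification

Two counting semantics coexist deliberately. Region counting is
any-overlap (a fragment counts in every region it touches), matching
standard region-quantitation tools; per-kb densities are
`log2(count/kb + 1)`. Bin assignment uses the fragment midpoint, so bins
that partition the genome conserve the total fragment count exactly —
required for the chromosome-scale profiles (250-kb bins) and the
state fold-change analysis (default 10-kb bins). Per-state fold-change
distributions are summarized by quartiles with 1.5×IQR whiskers; the
baseline is the median LFC of bins in the intergenic state, i.e. the
genome-wide change. Swapping conditions negates every LFC exactly.
Meta-profiles average track depth in equal bins across anchor-centered
windows (mean, or median for assays with very broad dynamic range such as
total Pol II); minus-strand anchors are reversed; windows are clipped at
chromosome ends with a warning, and fully-outside bins are excluded from
the statistic. Replicates merge only when all pairwise Pearson
correlations of `log2(count/kb + 1)` exceed 0.9.

## Calibrated differential expression

Counts follow `K_gi ~ NB(mean = s_i q_gc, dispersion α_g)` with
`Var = μ + α μ²`. Size factors come from the spike-in gene block after
dividing each sample by its gDNA spike/target ratio ρ (which cancels
cell-mixing variation), by median-of-ratios: for genes positive in every
sample, the median of `count / geometric mean`, with the median taken on
the ratios themselves. Applying spike-derived factors to target genes is
what lets a global transcriptional shift survive normalization —
target-derived factors would place the shift into the size factors and
report no change.

**Dispersion.** The raw per-gene estimate is method-of-moments,
`α̂ = (v − μ̄)/μ̄²`, on size-factor-normalized counts with v the pooled
*within-condition* variance (m = n − #conditions residual df), clipped to
`[1e-8, 10]`. Because v is approximately `σ²χ²_m/m`, `log α̂` carries a
Jensen bias of `log(m/2) − ψ(m/2)`, corrected before shrinkage. A
mean–dispersion trend is fitted log-log through bin means taken in linear
space (20 quantile bins of log mean; a linear-space mean avoids the
geometric-mean downward bias), falling back to the overall mean dispersion
when the means carry no spread. The final estimate shrinks the
bias-corrected raw value toward the trend with an empirical-Bayes weight
`w_g = τ²/(τ² + V_g)`, where the sampling variance
`V_g = ψ′(m/2)·(1 + 1/(α μ̄_g))²` follows from the delta method (the MoM
transform amplifies the χ² noise; genes in the Poisson regime carry almost
no dispersion information and shrink fully), and
`τ² = max(mean(resid²) − mean(V), 0)` is the moment-matched true
gene-to-gene spread. When all genes share one dispersion, estimates
collapse onto the trend, which also removes the selection effect of noisy
small estimates producing small Wald errors.

**Testing.** Per-condition means q̂ are NB maximum-likelihood estimates —
a few Newton steps on the score for log q, started from the closed form
ΣK/Σs (already exact for equal size factors or zero dispersion). The Wald
statistic is `log2(q̂_B/q̂_A)/se` with
`se² = (1/I_A + 1/I_B)/ln²2`, `I_c = Σ_i s_i q̂_c/(1 + α s_i q̂_c)`,
referred to a standard normal, two-sided. Genes zero in one condition get
a half-count continuity offset (finite LFC, large se); genes zero
everywhere are NA and excluded from the Benjamini–Hochberg m. BH is
step-up with enforced monotonicity; NAs pass through.

**Shrinkage.** Reported fold changes are posterior means under a
zero-centered normal prior, `lfc·τ²/(τ² + se²)`. The prior variance is
matched to the upper tail of the MLE distribution,
`τ² = max(q95(lfc² − se²), 1e-6)`: under the prior `E[lfc_g²] = τ² + se_g²`,
and an upper-quantile match keeps the prior wide enough that genuine large
effects — including a global shift shared by most genes — are not crushed,
while pure noise still shrinks hard. (A central moment match about the
mean fails exactly in the global-shift case this package exists for: the
variance about the mean sees only noise and the prior collapses.)
Significance requires BH-adjusted p < 0.05 *and* fold change > 1.5 (on the
shrunken LFC by default; a flag switches to the MLE).

**Expression threshold.** RPKM is computed from replicate-averaged
size-factor-normalized counts, `RPKM = mean count / (length_kb ×
total/10⁶)`; the pseudocount of 1 is added to RPKM before the log2
transform (the alternative placement is exposed as a parameter). The
expressed/not-expressed threshold is the antilog of the local minimum of a
Gaussian KDE between the two highest modes of the `log2(RPKM+1)`
distribution; modes must have prominence ≥ 5% of the peak density so KDE
wiggles do not count, and a unimodal distribution falls back to a
user-supplied threshold with a warning.

## Inferential summaries

The two-sample t-test is the classical pooled-variance Student form (not
Welch), with paired and one-sample variants and one-sided alternatives;
zero-variance inputs return NaN rather than raising so callers can report
the failure. The Fisher overlap test is one-sided enrichment
(`P(overlap ≥ observed)` under the hypergeometric null) on the 2×2 table
over a stated gene universe; two-sided is exposed. Correlation matrices
report Pearson r with pairwise NA dropping and the per-cell n; cells with
fewer than 3 shared items are NA.

## The synthetic-data generator

The generator emulates the design features that matter for calibration
logic: two conditions with replicates; a fixed spike-in cell fraction
(default 0.04, mirroring a ~25:1 target:spike cell mix) with per-sample
lognormal mixing jitter (σ = 0.15); a genome-wide occupancy multiplier in
the perturbed condition; per-state fragment enrichments over a
genome-tiling segmentation; matched inputs sharing the sample's cell mix
but uniform occupancy; NB gene counts with known size factors and LFCs; a
spike-in gene block scaling only with depth × jitter; and gDNA ratios
proportional to the true mixing. Each sample sequences a fixed total
fragment count (default 2×10⁵), split between genomes in proportion to
their material — so a genome-wide gain shows up as a *lower* spike-in
share at constant depth, exactly the signature calibration reads.

Deliberately not modeled: read-level sequence, fragment-length
distributions (fixed 200 bp), mappability and GC bias, PCR duplicates,
overdispersion of the mixing beyond the lognormal jitter, multi-factor
designs. Passing tests therefore demonstrate the correctness of the
calibration arithmetic and inference under the stated model, not
robustness to alignment artifacts or batch structure in real data.

Problem sizes are desk scale by default — target genome 2 × 5 Mb,
spike-in 1 × 2 Mb, 2×10⁵ fragments per sample, 2000 genes — chosen so
every benchmark has tight sampling error (e.g. ~1000 10-kb bins with
~100–200 fragments each) while the full suite runs in well under a minute
per stage.

Annotation fixtures place genes on a regular grid (≥ 10 kb spacing) so
promoter windows of neighbouring genes never collide and every planted
overlap is unambiguous; decoy peaks carrying only one of ATAC/H3K27ac are
planted and must not be called elements; some promoters carry only one of
RING1B/SUZ12 (must stay non-PcG) and some NMI-free promoters carry both
(must stay non-NMI).

## Benchmark designs

* ChIP shift recovery: uniform enrichment, shift 2, one replicate per
  condition plus matched inputs, 2×10⁵ fragments/sample; median LFC over
  10-kb bins, calibrated vs naive equal-library scaling.
* RNA calibration necessity: 2000 genes all at LFC −1, 500 spike-in genes,
  dispersion 0.05, 3v3; median MLE LFC under spike-derived vs
  target-derived size factors.
* Operating characteristics: 10 independent simulations of 2000 genes,
  3v3, dispersion 0.05. Null runs measure raw-p type-I error at p < 0.05.
  Mixed runs plant 800 DE genes (400 up, 400 down, |LFC| = 1, baseline
  500) — a global-perturbation fraction (40%) of the kind calibrated
  designs target — and measure empirical FDR and power among genes called
  at BH-adjusted p < 0.05. For reference, the theoretical power ceiling of
  this design with exactly known dispersion is ≈ 0.92 (|z| ≈ 3.74 against
  a BH threshold near 2.3), so measured power sits close to the
  information bound.

## Known limitations

* The NB test is two-group only; no GLM for covariates or interactions,
  and no Cox–Reid adjustment of the dispersion (the EB trend shrinkage
  stands in for it).
* Wald inference with a normal reference is slightly liberal at very small
  replicate numbers; with 3v3 the measured type-I error is ≈ 0.05 but a
  2v2 design will be less well calibrated.
* The subsampling reference is the shallowest sample; one very shallow
  library degrades every sample to its depth (report table makes this
  visible before committing).
* `nearest_within` and region counting are O(n·log n)–O(n·k) desk-scale
  implementations; they are exact but not tuned for hundreds of millions
  of fragments.
* The RPKM library-size denominator uses total size-factor-normalized
  target counts; with spike-derived factors this is one of several
  defensible choices and is isolated in one function.
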