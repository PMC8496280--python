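# Methods

Statistical definitions, parameter defaults, and numerical choices. All
defaults live in `mpeqtl.config.AnalysisConfig` and can be overridden per
run; the values below are the package's operating points for a
four-founder *C. elegans* mpRIL panel with ~200 lines, ~9000 markers and
~12000 expressed genes, but every stage is size-agnostic.

## Data model and preprocessing

Genotypes are binary founder alleles (markers × lines, `NaN` for missing),
sorted by (chromosome, position) with chromosome order I < II < III < IV
< V < X. Each marker carries an SDP (SNP distribution pattern) label: the
partition of the four founders into carriers/non-carriers. A subset and
its complement are indistinguishable, leaving 7 classes; the canonical
label is the pair containing JU1511 (`12` = JU1511+JU1926, `13` =
JU1511+JU1931, `14` = JU1511+JU1941) or the singleton's isolate name.

Expression processing, in order:

1. **Detection filter**: keep genes with mean log2 fpkm strictly above
   −5 across all samples (computed on raw fpkm with pseudocount, below).
2. **Depth normalization**: each sample column is scaled so its fpkm sum
   is 10⁶ (computed over the kept genes).
3. **log2 layer**: log2 of fpkm with a pseudocount of 2⁻¹⁰ added only to
   exact zeros (so nonzero values are untouched).
4. **log2-ratio layer**: the log2 layer minus each gene's mean, i.e.
   gene-centered log2 ratios. Mapping, heritability and PCA QC run on
   this layer; parental DE and transgression run on the log2 layer.

Parents contribute exactly two replicates each; mpRILs one sample per
line (enforced at construction).

## Parental differential expression

Per gene, a one-way ANOVA over the four parental lines (2 replicates
each, within-group df = 4) feeds Tukey–Kramer adjusted p-values for all
six pairs: q = |mean_i − mean_j| / sqrt(MSE/2 · (1/n_i + 1/n_j)), with
p from the studentized range distribution (k = 4 groups). A gene is a
DEG when any pair has p < 0.001. Degenerate cases: a 0/0 statistic
(identical values) gives p = 1; a nonzero difference with zero
within-group spread gives p = 0.

The DEG-count FPR permutes the eight parental line labels
(`deg_fpr_permutations`, default 10) and reports mean permuted count /
observed count (NaN with a warning when the observed count is 0). Note
that with df = 4 the α = 0.001 critical value is q ≈ 16.8 — roughly an
8.4-noise-SD mean difference — so small or noisy datasets legitimately
report zero DEGs.

The studentized-range survival function is evaluated by a custom
vectorized Gauss–Legendre (160-point, on the range statistic) ×
Gauss–Hermite (80-point, on the common reference value) quadrature,
validated against `scipy.stats.studentized_range` to ~1e−14; scipy's own
implementation integrates adaptively per value and is several orders of
magnitude too slow for genome-wide permutation use. Inputs are processed
in blocks of 2000 to bound memory.

## Transgression

Per gene, the parental envelope is [min line mean − k·SD, max line mean
+ k·SD] with SD pooled over within-line replicate variation (df = 4) and
k = 2 by default. mpRILs strictly outside are counted (`n_over`,
`n_under`); a gene is transgressive when the total strictly exceeds
`transgression_count` (default 50). The FPR redraws 8 random samples as
pseudo-parents (4 lines × 2 replicates) per permutation, with the rest
acting as mpRILs, and reports mean permuted transgressive count /
observed count.

## Kinship and narrow-sense heritability

Kinship K[i,j] is the allele-sharing proportion: the mean over
pairwise-complete markers of 1 − |x_i − x_j|. Missing-data normalization
can make K slightly indefinite; negative eigenvalues are clipped at zero.

Per gene, the mixed model y = μ + g + e with g ~ N(0, σ_g² K),
e ~ N(0, σ_e² I) is fitted by profile REML over λ = σ_g²/σ_e², reusing
one eigendecomposition of K for all genes and permutations. After
rotating by the eigenvectors, −2·restricted-log-likelihood(λ) =
(n−1)·ln RSS(λ) + Σ ln D_i + ln Σ x̃_i²/D_i with D_i = λ s_i + 1 is
minimized per gene by a vectorized 101-point log₁₀ grid on λ ∈ [10⁻⁵,
10⁵] followed by 45 golden-section iterations (bracketing one grid step
around the best point, with an explicit comparison against both grid
extremes so boundary optima are kept). h² = λ/(1+λ). Validated against a
dense-grid direct-matrix oracle to ≤ 1e−3 in h².

Significance uses per-gene permutation thresholds: each gene's values
are permuted across lines `h2_permutations` (default 100) times, and the
threshold is the empirical 0.95 quantile of permuted h² — the 5th
largest of 100, rank floor((1−q)·n_perm) — with significance requiring
the observed h² to strictly exceed it. Under the null this flags a gene
with probability 5/101 ≈ 0.0495 by exchangeability (verified by a
calibration test against the binomial 99% band).

## eQTL mapping

Each gene's log2-ratio profile is regressed on one binary marker at a
time by OLS; the p-value is the F(1, n−2) slope test, computed from the
correlation via the regularized incomplete beta function, floored at
1e−300 (−log10 p capped at 300). Markers with fewer than
`eqtl_min_class` = 5 lines in either genotype class score 0; markers
with missing genotypes are handled per marker over their complete lines.
Fully observed markers go through one dense matrix product, so a
2000-gene × 1000-marker scan is sub-second.

The peak (one eQTL per gene) is the most significant marker, ties broken
by chromosome order then lowest position. The genome-wide threshold is
chosen from one round of per-gene permutations: the smallest grid value
T (step 0.05) where (permuted peaks ≥ T, averaged per round) / (observed
peaks ≥ T) drops below `eqtl_fpr_ratio` = 0.01. When no T achieves the
ratio — the expected outcome on null data — a `ThresholdNotFound` error
carrying the best achievable ratio is raised; a threshold override is
available for comparison runs. One round is noisy by construction; the
API accepts several stacked rounds with false positives averaged.

A significant peak is **cis** when it lies on the gene's chromosome
within 1 Mbp (inclusive) of the gene start, else **trans**. Counts are
tabulated per SDP × chromosome × type with marginal totals.

## Trans-band detection

Trans-bands are detected per SDP, per chromosome, by greedy peak
extraction: repeatedly take the marker (of that SDP) harboring the most
not-yet-assigned trans-eQTL peaks within ±`window` (1 Mbp); if the count
strictly exceeds `trans_band_min_count` (default 100) it founds a band
and claims the eQTLs in its window; stop otherwise. Ties go to the
lowest position. Band borders are peak ± window, clipped at the
chromosome ends; when two same-SDP bands on one chromosome overlap, the
boundary is the midpoint between their peaks (lower band gets the floor,
upper band the next base pair), keeping membership a partition.

Greedy extraction (rather than merging contiguous candidate runs) is
deliberate: two genuine hotspots of the same SDP closer than two window
widths must remain separate bands, yet every marker between them is
itself a candidate, so run-merging would always collapse them. Greedy
extraction keeps them apart while absorbing satellite candidates that
merely overlap a hotspot's window.

Band member genes are tested for GO-term over-representation with the
upper-tail hypergeometric test. The population is the expressed-gene
background restricted to annotated genes (N), successes are a term's
genes in that universe (m), draws are the annotated test genes (n) — all
four counts are taken from the same population, which keeps p ≤ 1 in
every edge case. Terms are reported when p < 1e−5 and m > 3 (strict).

## Cross-study comparison

External experiments are reduced to per-gene peak calls from their own
significance profiles (peak strictly above 3.5 in −log10 p, cis/trans by
the same 1-Mbp rule with that study's marker map and annotation).
Overlap is on gene identity per type, reported as 100 · |shared| /
|reference study's calls| — deliberately asymmetric.

## Synthetic data generator

Genomes: per line and chromosome, Poisson(1.5) breakpoints at uniform
positions tile the chromosome into founder segments (uniform founder per
segment). Markers are allocated proportionally to chromosome length
(defaults: I 15.1, II 15.3, III 13.8, IV 17.5, V 20.9, X 17.7 Mbp), each
drawing an SDP from configurable weights that default to the asymmetry
of the real panel (many JU1511-, JU1941- and `14`-pattern markers, few
JU1926); a marker's alleles are its SDP's carrier pattern read through
each line's mosaic. Planted effects pin the SDP of the marker nearest
their locus.

Expression (log2 scale) per gene: baseline N(3, 2) — 5% of genes
low-expressed at N(−7, 1) to exercise the detection filter — plus
planted genetic effects, plus loading × developmental covariate
(loading ~ N(0,1) per gene, covariate ~ N(0, 0.3) per line), plus
N(0, noise_sd = 0.5) noise; fpkm = 2^value. Parental replicates share
genetics and covariate and differ only in noise. Effect sizes are in
units of the residual SD (unit 1 when noise_sd = 0, so a planted effect
of size d separates genotype classes by exactly d). `cis` effects
relocate the nearest gene onto the locus and affect only it;
`trans_band` effects affect `n_targets` random genes on other
chromosomes (or an explicit gene list). The ground-truth ledger records
mosaics, founder alleles, realized targets/markers, and true per-gene h²
= V_genetic / (V_genetic + loading²·0.3² + noise²) over the mpRIL lines.

All randomness derives from named substreams of one master seed
(`default_rng([seed, crc32(name)])`), so stages are independently
reproducible and the pipeline is byte-identical under reruns.

## Known limitations

- **Compositional bleed**: depth normalization divides by per-sample
  totals, so planted effects that shift a large fraction of a small
  synthetic transcriptome leak into every other gene as a spurious
  trans signal at the planted marker. This is a property of
  normalization, not a bug; realistic proportions (hundreds of affected
  genes out of ~12000) make it negligible, and test configurations keep
  planted targets a small fraction of genes.
- **Single-marker model**: no multi-QTL, interaction, or
  founder-probability (haplotype) mapping; a binary SNP model only.
- **One permutation round** for the eQTL threshold is noisy; on null
  data the unattainable-ratio error is the typical but not guaranteed
  outcome for a single round (the observed and permuted maxima are
  exchangeable), which is why the API supports stacked rounds.
- **GO associations are used as given**: no ontology-graph propagation.
- The generator's mosaics use a Poisson/uniform breakpoint process
  without interference or selection, and founder segments are drawn
  uniformly — adequate for validating the statistics, not a population-
  genetic simulator.
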