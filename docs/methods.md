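# Methods

## Cohort model and stratification

The unit of analysis is a synovial tissue sample with a swollen joint
count over 66 assessed joints (SJC66), sex, age (years) and a binary
DMARD-use indicator. Stratification is exact on integer joint counts:
SJC66 ≥ 9 → *high*, 1–8 → *low*, 0 → *excluded*. The two verbal forms of
the low-group rule ("< 8" and "8 or less") differ only at SJC66 = 8;
since joint counts are integers and the boundary sample class belongs to
the low group, the package fixes low ⇔ 1 ≤ SJC66 ≤ 8.

All differential tests share one covariate design: intercept, sex
(female = 0, male = 1), mean-centred age, DMARD use, and the high-group
indicator. Age is centred purely to stabilise the intercept; the group
coefficient is unchanged. Covariates constant across retained samples are
dropped with a warning rather than producing a singular fit. Sex
confounding is handled twice, as in the study design this mirrors: sex is
a covariate, and all allosome genes/CpGs/DMRs are removed before testing.

## Transcript testing and Lancaster aggregation

Counts are normalised with median-of-ratios size factors computed over
transcripts with all-positive counts. The per-transcript test is ordinary
least squares of log2(normalized + 1) on the design, with the group
column's t statistic and two-sided p. This is a deliberate, documented
stand-in for a negative-binomial Wald test: the computation this package
exists for is the *aggregation*, and the transcript test sits behind the
`gde.test_transcripts` surface so an NB fit can be substituted without
touching anything downstream. Zero-residual (perfectly separated) fits
are flagged and their p floored at the smallest positive float rather
than reported as 0.

Gene-level combination uses the Lancaster method with the transcript's
base expression (mean normalized count) as weight:
`T = Σ G⁻¹(1 − p_i; w_i/2, scale 2)`, `p = 1 − G(T; Σw_i/2, scale 2)`.
The gamma quantile is evaluated through the survival inverse so small p
retain precision. Transcripts with weight ≤ 1 normalized count are
excluded from aggregation (near-zero shapes make the gamma transform
numerically meaningless); the floor is configurable. A single retained
transcript returns its p unchanged, and all-weights-2 reduces exactly to
Fisher's method — both properties are regression-tested against a
chi-square oracle. FDR control is Benjamini–Hochberg (step-up), strict
inequality q < 0.05 for the call. Aggregated p-values are mildly
anti-conservative under the global null (≈ 7–9% of genes below 0.05)
because transcripts of a gene share sampling noise, violating the
independence the combination assumes; the rate stays inside the binomial
99% band asserted by the calibration test.

## DMR-to-gene annotation

A DMR links to a gene when it overlaps, by ≥ 1 bp, the window extending
5,000 bp upstream and 1,000 bp downstream of the gene, strand-aware
(upstream is rightward for − genes). Overlap — not containment — is used
because observed DMRs can exceed 15 kb and no containment window is
plausible at that scale. Two alternatives are exposed as configuration:
anchoring the window on the TSS instead of the gene body, and requiring
the DMR *midpoint* inside the window, since annotation tooling differs on
both points. Coordinates are 1-based inclusive internally; BED input is
converted exactly once at the read boundary. All qualifying genes are
reported (no nearest-gene collapsing). The production path uses an
interval tree; an O(n·m) brute-force twin with identical semantics exists
solely as a testing oracle.

## GDEM intersection and concordance

GDEMs are the genes in both the GDE set and the DMR-linked set. Exact
duplicate DMR×gene links are collapsed with a log line (duplicate
reporting rows are an artifact, not signal). Concordance is voted only by
transcripts individually significant at BH FDR < 0.05 across all tested
transcripts: if both signs occur among them the gene is *opposite*,
otherwise *concordant*; a GDEM with no individually significant
transcript is labelled concordant and flagged. All-transcript voting is
available by ignoring the significance column.

## eQTM

For a DMR×transcript pair, the point estimate is the Pearson correlation
between per-sample **median** % methylation over the region's constituent
CpGs (CpGs need ≥ 1 read to contribute; a sample with no covered CpG is
missing and the pair-wise complete samples are used) and
log2(normalized + 1) expression. The pseudocount is configurable; 1 is
the default.

*Bootstrap.* 95% CIs come from the percentile method over 1000 resamples
of the samples with replacement. Degenerate resamples (either vector
constant) are discarded and redrawn; if more than half of the initial
draws are degenerate the data are pathological and the pair errors out.
Percentile CIs under-cover at n = 17 (measured ≈ 90–93% at ρ = 0.8 in the
coverage simulation) — they are reported as computed, not corrected.

*Permutation null.* 1000 windows of the same number of consecutive CpGs
as the observed region are drawn uniformly from the autosomal CpG
universe (each window wholly on one chromosome, windows overlapping the
observed DMR excluded, sampling without replacement unless fewer valid
windows exist, in which case it warns and samples with replacement). Each
window's median methylation is correlated with the same expression
vector. The default comparison is two-sided on |r|: the literal
one-sided rule ("proportion of correlations higher than observed") gives
p ≈ 1 for every negative correlation, which contradicts reported strongly
negative pairs with tiny p; the literal rule remains available as
`tail="greater"`. p = 0 is written as 0 with a companion display field
`< 1/N`. This null preserves CpG spacing, coverage and within-window
dependence, which an independent-shuffle null would destroy; it does not
model long-range autocorrelation beyond the window length.

## Synthetic-data generator

The generator's defaults are the study conditions the pipeline is
validated under: 17 samples (9 high, 8 low, 0 zero-count), a sex confound
(75% of the high group male, mirrored in the low group), 60 autosomal
genes with 1–5 transcripts (plus 2 genes on the synthetic allosome chrSX
carrying a real sex effect so the allosome filter removes something), 20
planted GDEMs of which 4 discordant, 10 expression-only and 10
methylation-only genes, a 30-percentage-point methylation shift over runs
of 10–50 consecutive CpGs injected at target-gene promoters, |log2 fold
change| = 2 for directly planted transcripts, coupling magnitude
ρ = 0.9, mean WGBS depth 30×, NB dispersion 0.1, and a background CpG
about every 120 bp (≈ 35k CpGs over the ≈ 4 Mb synthetic genome).

Noise model: baseline methylation is a bimodal beta mixture
(0.55·Beta(0.8, 6) + 0.45·Beta(6, 0.8)); read totals are
Poisson(depth) and methylated counts Binomial(total, p) — WGBS counts
are binomial given depth. Planted regions additionally get a per-sample
Gaussian random effect (sd 4 points) so regional methylation varies
continuously within groups; every CpG falling inside a planted interval
shifts, including background CpGs.

Coupling: for a concordant planted GDEM, the designated transcripts'
latent log2 mean is `base − a·(ρ·z_m + √(1−ρ²)·ε)` with `z_m` the
standardized realized median methylation of the gene's region,
`ε ~ N(0,1)` and amplitude `a = lfc/2`. Because the methylation shift
separates the groups, this single mechanism induces both the group
expression difference and the target correlation; the sign is negative
(promoter methylation represses) by default. Realized |r| is attenuated
below ρ by count noise — typically 0.7–0.9 at the defaults. Discordant
genes instead get two transcripts with direct ±lfc effects.

What the generator does *not* emulate: read-level data, bisulphite
conversion error, realistic exon structure, CpG islands/shores,
long-range methylation autocorrelation outside planted regions, and
between-sample correlation structure beyond the group labels and the
planted regions. Passing tests therefore demonstrate correctness of the
computations and calibration under this model, not performance on real
tissue data.

## Validation problem sizes and numerical choices

The validation suite (shared by the tests and `scripts/acceptance.py`)
uses: 1000 random p-vectors for the Lancaster–Fisher oracle (agreement
to < 1e−10), 100 random instances for the BH and annotation oracles, a
200-gene null study with 1000 permutation windows per gene for KS
uniformity of the permutation p (1% level), 500 bivariate-normal
replicates for bootstrap coverage (≥ 85% at ρ = 0.8, n = 17), the default
60-gene study for planted-GDEM recovery (≥ 80%) and concordance accuracy
(100%, conditioned on both discordant transcripts being recovered), and
20 independent studies for planted-eQTM power (perm_p ≤ 0.05 for ≥ 90% of
pairs). These sizes keep a full run around half a minute while leaving
Monte-Carlo error well inside each margin.

Other numerical choices: p-values entering the Lancaster transform are
clamped to the smallest positive double with a warning when exactly 0;
Pearson r is clipped to [−1, 1] against floating-point overshoot;
windows whose correlation is undefined (constant median) count as
non-exceedances in the permutation tally; per-stage RNG seeds are derived
from the global seed by hashing the stage name, so stages re-run in
isolation reproduce the pipeline's results exactly.

## Known limitations

* The transcript-level test is Gaussian on log counts, not an NB GLM;
  with 17 samples and moderate dispersion it is slightly conservative for
  low counts, and aggregated gene p-values inherit within-gene
  dependence (see above).
* The eQTM is unadjusted for covariates by design; sex or age structure
  in both data types will appear in r.
* Permutation p granularity is 1/1000 at the default setting; smaller
  p-values require raising `n_permutation`.
* Bootstrap CIs are percentile, not BCa; they under-cover at n = 17.
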