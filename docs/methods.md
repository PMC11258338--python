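# Methods

This note documents the models, conventions and design choices behind
`wgdtx`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and segment conventions

Segment and gene files use 1-based, closed intervals; a segment with
`start == end` covers one basepair and lengths are `end − start + 1`. This
matches common copy-number caller exports. Sex chromosomes are excluded
everywhere ("autosomal" is meant literally); rows with missing
allele-specific copy number are dropped at load; samples with tumour
purity below 0.3 are excluded at load (configurable), since allele-specific
copy number is unreliable below that.

## WGD status and timing

A sample is called whole-genome duplicated when the length-weighted
fraction of its **covered** autosomal genome with major copy number ≥ 2
exceeds 0.5 (strict inequality). The denominator is the covered length,
not the assembly length, so sparse profiles are not penalised for
missing coverage.

Timing uses the heuristic dichotomy over total-copy-number-2 regions:
duplication before the bulk of losses leaves those regions heterozygous
(1+1, both post-WGD copies of one parental allele lost); duplication after
losses doubles hemizygous regions into homozygous 2+0 states. The call
compares aggregate 1+1 length against aggregate 2+0 length. An exact tie
classifies as *late* — the conservative, non-headline class — and the
tie-break is a keyword argument. Timing is undefined (an error) when a WGD
sample has no total-CN-2 segment at all.

## Per-gene copy-number log-ratio (cnlr)

A gene takes the total copy number of the single overlapping segment with
the largest overlap (deterministic: leftmost segment on an exact tie);
genes with no overlapping segment are flagged missing and dropped
per-sample in the regression, never imputed. The log-ratio is

```
cnlr_gs = log2( (p·CN_gs + 2(1−p)) / (p·P_s + 2(1−p)) )
```

with `p` the tumour purity and `P_s` the sample's length-weighted mean
total copy number (ploidy). The numerator is the purity-mixed copy number
at the gene — tumour copies diluted by diploid stroma — and the
denominator is the same mixture at the sample's average. Referencing to
the sample's own ploidy, rather than to 2, reproduces what a
coverage-based caller measures: sequencing depth is a *relative* quantity,
so a genome-doubled tumour's log-ratio is centred near its modal state,
not uniformly elevated. This choice is load-bearing. Expression measured
as counts-per-million is composition-normalized in exactly the same way,
so a diploid-referenced covariate would carry a genome-wide component that
the expression values cannot contain, biasing the WGD coefficient of every
gene; the ploidy-referenced covariate matches the measurement scale of the
response. For a diploid-background profile (`P_s = 2`) the definition
reduces to the familiar `log2(mixed CN / 2)` and is 0 for (1,1) segments
at any purity.

## Normalization

TMM factors follow the published procedure: the reference sample is the
one whose upper-quartile of scaled counts is closest to the mean
upper-quartile; M-values are trimmed 30 % per tail and A-values 5 % per
tail (the published defaults, since no parameters are given in the
analyses this mirrors); surviving M-values are combined with
inverse-asymptotic-variance weights; factors are rescaled to geometric
mean 1. The implementation is checked against edgeR's `calcNormFactors`
on fixed tables to 1e-9. Log-CPM uses a 0.5 prior count and an
effective-library offset of 1, so values are finite for zero counts.
Genes with zero counts in all samples are dropped; the post-filter set is
the gene universe downstream. A `filterByExpr`-style minimum-count filter
is available (`dge.filter_expressed`) but not applied by default: the
gaussian fit proved well calibrated without it on the synthetic cohorts,
and aggressive filtering removes strongly down-regulated genes whose
expression collapses in half the cohort.

Precision (voom-style) weights are deliberately **not** computed: the
per-gene model regresses the normalized log value with a plain gaussian
likelihood, and whether the original analyses carried such weights is not
documented; the weightless model is the stated one here.

## The per-gene gaussian GLM

Each gene is fitted by ordinary least squares (gaussian GLM with identity
link — mathematically identical, numerically simpler) of normalized log2
expression on: a 0/1 WGD indicator, an HR-deficiency exposure (min-max
scaled to [0,1] per cohort, since the natural scale of a copy-number
signature exposure is arbitrary), tumour purity, and the gene's cnlr. The
WGD coefficient, its standard error, and a two-sided t-test with `n − 5`
degrees of freedom are reported. Significance defaults to |coef| ≥ 1.5 and
BH-adjusted p < 0.05; a raw-p mode exists because analyses in this area
are often ambiguous about which scale the 0.05 refers to. A sensitivity
mode refits without the copy-number covariate.

Per-gene failures (rank-deficient designs, too few usable samples) are
flagged with a status string, excluded from the BH adjustment, and
reported; the run aborts only if more than half the genes fail. A
zero-residual fit (constant response) returns p = 1 rather than a
spurious certainty. Model diagnostics follow the tertile convention:
for the genes nearest the 1/3, 2/3 and 3/3 quantiles of mean expression,
the KS test of standardized residuals against N(0,1), the count of
|z| > 3 outliers, and the residual-variance ratio between WGD groups.

The cross-cohort intersect keeps genes with BH-adjusted p < α in both
cohorts and the same coefficient sign, with **no** magnitude requirement,
so small concordant validation effects count.

## Enrichment

Candidate lists are built per direction with asymmetric coefficient
filters (default ≥ 1.0 in the discovery cohort, ≥ 0.5 in validation, to
admit enough genes from the noisier validation side). Per-gene p-values
are merged with Brown's method: the Fisher statistic `−2Σ ln p` referred
to a scaled χ², with scale and degrees of freedom moment-matched to the
empirical covariance of the `−2 ln p` columns across the candidate set
(identity covariance recovers Fisher; perfectly duplicated cohorts
collapse toward df 2). Zero p-values are clamped to the smallest positive
float with a warning. Genes are ranked by merged p, ties broken by gene id
for determinism.

Each pathway is scored by the ranked hypergeometric statistic: the minimum
over prefixes of the ranked list of P(X ≥ overlap) under the
hypergeometric law with the fitted-gene universe as population. The
minimum is reported unpenalized for prefix selection — the convention of
the tool family this mirrors — and is therefore anti-conservative as a
stand-alone p-value; pathway-level adjustment uses Holm by default
(configurable to BH). Up- and down-regulated lists are tested separately.

## Survival

Kaplan–Meier product-limit curves per timing group and the k-group
log-rank test (observed − expected with hypergeometric variance,
df = k − 1) are delegated to lifelines; ties are handled in single
risk-set steps. Multivariate proportional-hazards modelling is out of
scope.

## The synthetic-cohort generator

The generator emulates the statistical structure the chain assumes, with
truth recorded for every planted quantity.

**Copy-number histories.** Autosomes follow an approximate human
chromosome-arm scaffold; the atomic unit is a half-arm (88 units). Losses
remove one allele copy of whole- or half-arms until a target fraction of
the genome (`loss_rate`, default 0.3) is hit — aggregate lengths are what
the timing heuristic consumes, so finer breakpoint detail would add
nothing. Arm `early` doubles first (2+2 background) and loses both doubled
copies of one parental allele in lost regions (1+1); arm `late` loses
first and doubles (2+0 in lost regions); arm `none` stays diploid with
hemizygous losses. A configurable fraction of lost units (default 5 %)
flips zygosity ("contradictory" segments), exercising the tie-break and
robustness paths and keeping timing recovery below a trivial 100 %.

**Recurrent-loss landscape.** Each cohort draws one per-unit loss
affinity; WGD samples select lost units by Gumbel-perturbed logits
`loss_bias · affinity` (default `loss_bias = 2.5`, an inclusion-odds range
of ≈ e^2.5 ≈ 12 across units, of the order of observed LOH recurrence
heterogeneity in this tumour type, where the most recurrent arm losses
approach fixation against a ~30 % background), while non-WGD samples lose
uniformly. This matters: with i.i.d. placement, the realized per-gene
copy-number contrast between groups and the within-group residual
variance inflate together and the t-test self-calibrates, so *no*
covariate would be needed. Only a systematic, shared landscape creates
the gene-level CN–WGD confounding that the copy-number covariate exists
to absorb, and the generator must contain it for that claim to be
testable.

**Expression.** Per gene, a tumour baseline and a stromal baseline are
drawn once per cohort from N(5, 1.5²) log2 units (typical of expressed
genes in filtered bulk data). The per-sample mean is

```
log2 μ_gs = log2( p_s·2^base_g + (1−p_s)·2^stroma_g )
            + β_CN · cnlr_gs + β_WGD · 1[s early] · 1[g ∈ module]
```

followed by a log-normal library depth (σ = 0.25) and gamma-Poisson
(negative-binomial) sampling with dispersion 0.1 (a biological CV of
~0.3, at the benign end of human cohort estimates). The purity mixture
applies to the *baseline*: the stromal compartment dilutes what level a
gene sits at, while the purity dilution of the copy-number *dose* is
already encoded in the cnlr definition itself (its numerator is exactly
the tumour-with-diploid-stroma mixture). Applying the mixture a second
time around the dose term would double-count purity and make the gaussian
model badly misspecified, which is observable as a wildly anti-conservative
null — the calibration tests in the suite pin this down. The planted
module effect (default −2 log2 units on 20 genes, in early-WGD samples
only, reflecting the timing-specific biology the chain is built to
detect) is defined on the bulk measurement scale, i.e. it is the
coefficient the model should recover.

**Purity, covariates, survival.** Purity is Beta(8, 3) (mean 0.73,
matching reported cohort medians in the 60–70 % range); the HR exposure is
an uninformative Gamma(2, 0.25) nuisance; survival is exponential with
per-group hazards (defaults 0.2/month for early vs 0.1 for late and none —
a twofold hazard ratio) under independent exponential censoring
(0.05/month).

**Cohort defaults** are 30 early / 20 late / 30 none samples and 2,000
genes — a desk-scale stand-in for a discovery cohort of ~80 tumours — and
a validation cohort shares the gene universe and module membership but
redraws samples, baselines and noise. The generator does **not** emulate:
focal amplifications or subclonal copy number, realistic breakpoint
processes, mutational signatures, batch structure, gene–gene correlation
beyond the shared copy-number and composition structure, or single-cell
data. Passing tests therefore demonstrate internal statistical
correctness of the chain under its stated assumptions, not robustness to
everything real cohorts contain.

## Problem sizes and numerical choices

The test suite and acceptance script use: 1,000 random profiles for the
exact per-basepair oracle; 200 tumours for timing recovery (loss rate
0.2); 5,000-gene cohorts of 80–120 samples for calibration and
confounding; 2,000 genes for effect recovery; the 80 × 2,000 default for
the end-to-end run — sizes chosen so the whole suite completes in well
under a minute of compute while keeping binomial noise on estimated rates
near ±0.005. Determinism: every draw descends from one `numpy`
`default_rng` seed; reports are written with sorted keys and fixed float
formatting, so a rerun under the same seed and configuration is
byte-identical. Degenerate cases are handled explicitly: zero-residual
fits return p = 1; p-values of 0 entering Brown's merge are clamped with
a warning; empty candidate lists yield p = 1 pathway rows rather than
errors; TMM raises a named error for a sample sharing no expressed genes
with the reference.

## Known limitations

The ranked hypergeometric minimum is anti-conservative and interpretable
only relative to its own adjustment convention. The gaussian GLM on
log-CPM is approximate for very low counts (the optional expression filter
exists for that regime). The timing heuristic is aggregate and cannot
resolve complex histories (repeated duplications, chromothripsis). The
WGD coefficient in mixed-timing cohorts estimates a weighted average of
timing-specific effects — on the default cohort the early-only planted
effect appears diluted by the late group's share, which is why the
pipeline's discovery step leans on the intersect and enrichment stages
rather than a single-cohort magnitude threshold.
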