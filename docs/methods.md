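# Methods

This document records the statistical models, parameter conventions and
numerical choices implemented in `myotime`, and the scope of the synthetic
data generators used to validate them.

## Study design

The reference design (`simulate.DesignSpec`) is two cell lines sampled at
days 0–5 with three replicates per condition: 36 samples, sample ids
`line{c}_day{d}_rep{r}`. Day is treated as the biological covariate of
interest; cell line is an adjustment (batch-like) covariate throughout.

## Normalization

**TMM factors** (`normalization.tmm_factors`). Trimmed mean of M-values
with the edgeR conventions: the reference sample is the one whose
75th-percentile count fraction is closest to the mean across samples;
per-gene log-ratios (M) and average log-abundances (A) are computed on
library-size-scaled counts restricted to genes positive in both samples;
the upper and lower 30% of M and 5% of A are trimmed by rank (average
ranks for ties); the remaining M-values are averaged with inverse
approximate-variance weights; factors are rescaled to have geometric
mean 1. On tie-free data this equals the straightforward sort-based
definition, which the test suite verifies exactly using matrices of
distinct prime counts (unique factorization guarantees tie-free ratios).

**CPM / log-CPM** (`normalization.cpm`). Counts per million on effective
library sizes (library size × TMM factor). Log output uses
log2(CPM + prior) with a sample-specific prior
`prior_count * eff_j / mean(eff)` (default prior_count 0.5), matching the
edgeR convention. This prior maps an all-zero gene to the same log-CPM in
every sample regardless of depth differences; it is *not* invariant to
jointly rescaling all counts.

**Batch removal** (`normalization.remove_batch`). Fits a linear model per
gene with sum-to-zero contrasts for the batch factor alongside the
preserved covariate (day), and subtracts only the fitted batch component.
A rank-deficient design (batch confounded with the preserved covariate)
raises an error rather than silently absorbing signal. Z-scoring uses
ddof = 1 and flags constant rows, which map to 0.

Normalization chains as TMM → log-CPM → batch removal (preserving day) →
per-gene z-scores (`normalize_chain`), with the reached stage recorded on
the returned object.

## Differential expression

Counts are modeled as negative binomial. GLMs are fit with statsmodels
(`NegativeBinomial` family with fixed per-gene alpha; Poisson when
alpha < 1e-8). Offsets are log effective library sizes.

**Dispersion** (`diffexp.estimate_dispersions`). Method-of-moments per
gene on normalized counts, then shrinkage of log-alpha toward a smooth
mean–dispersion trend with weight 0.6. All-zero genes are excluded and
flagged.

**LRT** (`diffexp.nb_lrt`). Full model: intercept + cell line + day as a
factor (6 levels); reduced model drops day. The statistic is
2(llf_full − llf_reduced) with df = 5, referred to chi-squared.
Per-feature status is `ok`, `excluded` (all-zero) or `failed`
(non-convergence); p-values of non-ok rows are NaN and pass through BH
untouched.

**Windowed trends** (`diffexp.nb_trend`). Within a day window (e.g. 0–3
or 3–5; at least 3 distinct days required) the model is intercept + cell
line + linear day, and the reported `beta` is the day coefficient
converted to log2 per day. Wald tests with BH adjustment.

**BH adjustment** (`diffexp.bh_adjust`) implements the step-up procedure
with NaN passthrough and matches `statsmodels.multipletests` on complete
vectors.

## Temporal clustering

Significant genes (LRT padj ≤ alpha, default 0.01) are summarized as
per-day means of z-scored log-CPM (`temporal_profiles`), clustered with
Ward linkage into k = 5 clusters, and cluster centroids are labeled by
rules on the z-trajectory (threshold θ = 0.5): precedence
UpDown → EarlyDown → EarlyUp → Down → Up; if two centroids claim the same
label the larger-margin centroid keeps it and the loser becomes Mix;
centroids matching no rule are Mix. Noiseless canonical shapes receive
their intended label exactly.

## Differential transcript usage

**Filtering** (`dtu.filter_features`) follows the DRIMSeq-style rules
with study defaults: an isoform needs count ≥ 5 in ≥ 18 samples and
usage proportion ≥ 0.05 in ≥ 18 samples; its gene needs total count ≥ 10
in ≥ 18 samples; genes left with fewer than two isoforms are dropped. A
removal report gives the first failed rule per feature/gene. Thresholds
exceeding the sample count, or filters that remove everything, raise
errors.

**Usage test** (`dtu.test_usage`). Per isoform, counts y out of gene
totals n are modeled beta-binomially with a logit-linear mean in cell
line + day (factor). Dispersion uses a moderated two-pass scheme:

1. Pass 1 fits the reduced model with free precision γ per isoform,
   converts to an intraclass correlation with a degrees-of-freedom
   correction, pools per gene by median, and shrinks log-ρ toward the
   across-gene median with weight 0.8.
2. Pass 2 refits full and reduced mean models at the fixed per-gene γ
   and forms a likelihood-ratio statistic with df = (number of days − 1).

This stabilizes per-isoform dispersions at n = 36 and gives calibrated
null p-values (KS-uniform in the test suite).

**Stage-wise decisions** (`dtu.stagewise_adjust`). Gene screening
p-values are Šidák-combined minima of member isoform p-values, BH-adjusted
and screened at alpha (default 0.05). Confirmation applies Holm within
screened genes at level alpha·R/G (R screened, G tested genes), so the
overall false discovery rate across the two stages (OFDR) is controlled
at alpha. Confirmed isoforms are always within screened genes.

**Dirichlet-multinomial** (`dtu.fit_dm`) estimates per-group isoform
proportions and a common precision γ by maximum likelihood; in the
multinomial limit γ diverges. `classify_die_dynamics` labels gene-level
isoform trajectories as inverse / single_dominant / cumulative / other
from within-window changes (dominance fraction 0.75).

## Gene-set scores and validation

Composite scores are per-sample means of member-gene z-scores; the trend
test is OLS of score on day with the exact t-based p-value. ORA is the
hypergeometric upper tail `sf(k−1; N, K, n)` on the intersection with an
explicit background, BH-corrected across sets; it matches exhaustive
enumeration over small universes. qPCR quantification implements
2^−ΔΔCt; the result is invariant to shifts of the reference gene.

## Annotation and confidence triage

Transcript models are compared to a reference by splice junctions: FSM if
the full junction chain matches a reference transcript of the same gene
locus (with end tolerance for boundary exons), NIC if all junctions are
individually known but the chain is novel, NNC if any junction is novel
(novel junctions are reported). Strand mismatches are NNC;
transcripts on chromosomes absent from the reference are flagged.
Coding triage: no ORF → noncoding; mean pLDDT > 0.7 → high-confidence
coding, with the boundary value 0.7 itself classed low; missing
structure predictions are flagged.

## Network

Screening n candidate proteins against each other plus homodimers gives
n(n+1)/2 pairs (`pair_count`; 50 → 1275). iPTM tables are validated
(ids, range, NaN) and symmetrized by the pairwise maximum. Edges require
iPTM strictly > 0.7. Components are reported sorted by (size descending,
lexicographic members) and match brute-force union-find.

## Simulation scope

The generators plant: NB totals with per-gene mean, dispersion and one of
five deterministic temporal shapes (Down, EarlyDown, EarlyUp, Up, UpDown)
plus random-walk Mix; DTU genes as 2-isoform proportion swaps with exact
total-variation distance `dtu_swap`, interpolated linearly to a switch
day, with Dirichlet-multinomial splitting at precision γ; annotations
with generator-known FSM/NIC/NNC truth (at novel_fraction = 1 the
reference is empty, so classification cannot recover the planted
categories — the classifier then reports `other`/unknown chromosome);
confidence tables with planted pLDDT/iPTM structure. All generators take
explicit integer seeds and are bitwise reproducible.

## Known limitations

- NB Wald/LRT p-values are asymptotic; with very few replicates (2 per
  condition) the empirical FDR of BH at 0.05 sits near, and for some
  seeds slightly above, 0.07.
- The dispersion trend is a simple smooth fit, not an empirical-Bayes
  posterior; it is adequate for the 36-sample design it targets.
- The batch remover assumes an additive batch effect on the log scale.
- Structural classification uses junction identity only; it does not
  model intron retention as a separate category.
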