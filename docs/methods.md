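# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `multiregion`. The package operates on multi-sample
somatic variant tables of a single patient (several tumor regions plus a
matched normal) and on a bundled simulator that generates such tables
with known clonal ground truth.

## Variant model, filtering, recovery

A variant is a site-level record (chrom, pos, ref, alt, gene, coding
effect, annotation flags) with per-sample read support (depth, alt
reads, AF = alt/depth). Presence in a sample is a *filter state*:
a call passes when AF ≥ `min_af` (0.05), total depth ≥ `min_depth` (10)
in the tumor **or** the matched normal column, alt reads ≥
`min_alt_reads` (2), no strand-bias or blacklist flag, AF >
`homopolymer_min_af` (0.10) if in homopolymer context, population AF <
`max_population_af` (0.01), non-synonymous effect when required
(missense, nonsense, frameshift), and — when census rescue is active —
the variant is either known somatic or lies in a cancer-census gene.
Annotation flags are inputs: the upstream callers and databases that
produce them are out of scope. All failing rules are recorded per call;
the filter log reports the first in a fixed order. Cross-sample
*recovery* then re-admits calls that failed **solely** the AF rule in
samples of a patient where the variant passes elsewhere at AF ≥ 5%;
recovery never removes calls and is idempotent.

The neutrality analysis deliberately uses rules with
`require_nonsynonymous=False`, since synonymous passengers carry signal
about the subclonal frequency spectrum.

TMB is passing non-synonymous variants per megabase of panel. MSI
classification partitions the instability-score percentage as MSS
(< 10), MSI-L ([10, 30]), MSI-H (> 30); the closed MSI-L interval is a
documented decision — the conventional verbal definition of the bands is
ambiguous at the boundaries.

## Cancer cell fraction and clonality

For alt reads a out of depth d, purity ρ, tumor copy number CN_t and
normal copy number CN_n (2 unless stated):

    VAF = a/d
    m   = clamp(round(VAF·(ρ·CN_t + (1−ρ)·CN_n)/ρ), 1, CN_t)
    CCF = VAF·(ρ·CN_t + (1−ρ)·CN_n)/(ρ·m)

The multiplicity estimator m (nearest integer, clamped) is a pragmatic
choice; CCF is capped at 1.5 for reporting and at 1 conceptually for
classification. The 95% CI is the exact Clopper–Pearson interval on a/d
mapped through the same linear transform — conservative by construction;
a variant is *subclonal* iff the transformed upper bound is < 0.95, and
*not assessable* at zero depth. Because m is re-estimated from VAF, the
CCF point estimate is monotone in alt reads only within a fixed-m
regime; at an m transition the scale resets (this is inherent to any
integer multiplicity estimator).

Per-patient ("pooled") clonality sums read counts over all tumor
samples, zeros included for covered-but-absent regions, with
depth-weighted mean ρ and CN; pooling read counts (rather than averaging
CCFs) keeps the exact binomial CI meaningful for the virtual single
sample. Variants clonal in ≥ 1 sample but subclonal pooled are flagged
as clonal illusions.

### Balance factor and samples needed

The apparent-clonal curve C(n) is the mean, over random size-n subsets
of regions (exhaustive when ≤ 200 subsets exist, else Monte Carlo with
100 draws), of the number of variants present in every subset member.
It is non-increasing by construction. It is fit by bounded least squares
(three starts g₀ ∈ {0.2, 0.5, 0.8}) with

    C(n) = c_inf + (C(1) − c_inf)·g^(n−1),  g ∈ (0,1), 0 ≤ c_inf ≤ C(1).

A constant curve is degenerate (g unidentifiable) and returns g at the
lower boundary with c_inf = C(1). The probability of correctly
identifying the truly clonal set with n samples is modeled as

    P_correct(n) = 1 − g^n,   n_needed = ceil(ln(1−p)/ln(g)).

This one-parameter operationalization reproduces the published
probability bounds at the published g values (g = 0.56: P(5) = 94.5% >
90%; g = 0.2, n = 10 and g = 0.01, n = 4 both > 98%), but note that at
g = 0.56 it already reaches 90% at n = 4; the cited sampling frameworks
do not print their functional form, so the model is documented as a
choice, with the subset-resampling curve as its empirical counterpart.

## Neutral-evolution test

Under neutral growth the cumulative number of subclonal mutations with
frequency ≥ f is M(f) = μ/β·(1/f − 1/f_max). VAFs enter *uncorrected*
for purity (purity rescales all of a sample's frequencies alike, so
correction does not sharpen the test), variants with estimated
multiplicity ≥ 2 are excluded as likely gene-doubled, and both
synonymous and non-synonymous passing variants are included. Pooled mode
uses each variant's mean AF over all tumor samples (zeros included) to
mitigate spatial sampling bias.

Inside the fit window [f_lower, f_upper] (defaults [0.1, 0.25], the
subclonal band below the diploid clonal peak; the bounds are
configurable because the appropriate band depends on depth and purity),
evaluation points are the observed in-window VAFs, M is counted within
the window, and a through-origin least-squares fit of M against
x = 1/f − 1/f_upper gives the slope estimate of μ/β. R² is computed
about the mean of M (so a structureless M scores 0, and the statistic is
comparable to the conventional R² ≥ 0.98 neutrality criterion; values
are clipped to [0, 1]). The Kolmogorov distance is the maximum absolute
difference between M(f)/M(f_lower) and x(f)/x(f_lower), both normalized
to 1 at f_lower — a descriptive distance, not a test with a p-value,
because the evaluation points are not independent draws. Fewer than 12
in-window mutations yields "insufficient" rather than a verdict.
Hypermutated samples whose clonal peak covers the window can be excluded
from the panel explicitly; the panel summarizes the mean and standard
deviation of the Kolmogorov distance across assessable samples.

## Region phylogenies

Variants become binary presence characters over regions; the matched
normal is an all-zero outgroup, so somatic state 0 is ancestral.
Duplicate patterns are collapsed with weights. Maximum parsimony is
solved exactly for ≤ 12 regions by stepwise leaf addition with
branch-and-bound: a partial tree's weighted Fitch length (computed on
patterns restricted to the leaves placed so far) never decreases when
leaves are added, so partial trees scoring above the incumbent are
pruned; this partial-score bound is used instead of a
character-incompatibility bound for simplicity, and correctness is
checked against exhaustive enumeration in the tests. All co-optimal
topologies are returned, canonically (lexicographically) ordered for
reproducibility. Variants whose support set matches a clade are assigned
to the branch above it; homoplasious variants (support set matching no
clade of the optimal tree) are reported as *unresolved* rather than
forced onto a branch. Newick output uses branch lengths as assigned
variant counts and is validated by a dendropy round trip.

CCF ordering constraints (tolerance ε = 0.1 on the CCF scale, roughly
the CI half-width at typical depths): X may be ancestral to Y iff
CCF_X ≥ CCF_Y − ε in every sample; X, Y may be siblings under Z iff
CCF_X + CCF_Y ≤ CCF_Z + ε in every sample; pairs admissible in neither
direction are *crossing*. These checks replace a full lineage-tree
construction; manual CNV placement on trees is out of scope.

## Simulator

The generator emulates the statistical structure of a multiregional
exome experiment, not tumor growth: a root clone (cell fraction 1
everywhere) carrying `n_clonal` truncal mutations; user-declared
subclones, each with a per-region cell fraction (subtree-inclusive, so a
parent's fraction bounds the sum of its children's); per clone, a
neutral tail of Poisson(μ_eff·(1/f_min − 1/f_max)) passenger mutations
with within-clone frequency drawn by inverse CDF from the 1/f² density
truncated to [f_min, f_max] — region-independent within the host clone,
because the neutrality analysis is per sample, not spatial. Reads:
expected AF = f_cell·m·ρ/(ρ·CN_t + (1−ρ)·2), depth ~ Poisson(mean 200 by
default, typical of exome panels), alt reads ~ Binomial. Multiplicity is
1 except inside declared copy-number events, where it equals the event's
major copy number. Defaults (5 regions, purity 0.8, μ_eff = 10,
frequency window [0.05, 0.4], ~35% synonymous) are chosen to resemble a
moderately mutated microsatellite-stable tumor.

"Truly clonal" in the truth table means membership in the root's
founding mutation set (cell fraction 1 in every region); neutral-tail
draws hosted by the root are *not* flagged, since they sit below
fixation by construction.

What the simulator does **not** model: spatial growth or sampling
geometry, selection dynamics beyond declared clone fractions, sequencing
artifacts (the annotation flags exist but default to clean), mutational
signatures, and region-confined singleton excess (tail draws share their
host clone's region set, so per-region private mutation counts are lower
than in real spectra unless region-confined subclones are declared).
Passing tests therefore demonstrate correctness of the statistics under
a faithful read-sampling model, not robustness to artifact-laden real
data.

A separate truth-level generator draws subclonal region membership
i.i.d. with probability g, for which the apparent-clonal curve is
exactly truncal + S·g^n; it provides ground truth for balance-factor
recovery (recovered within ±0.1 in the tests).

## Numerical choices and degenerate inputs

* Clopper–Pearson via the beta-distribution form (statsmodels); an
  independent exact-binomial oracle (scipy) checks it in the tests.
* Balance fit: `scipy.optimize.least_squares` with box bounds and
  multi-start; residual reported as the RMS-equivalent norm.
* R² clipped at 0; KS is exactly 0 when the empirical and theoretical
  curves agree at every evaluation point.
* Degenerate inputs have defined behavior rather than exceptions where
  the field expects it: zero depth → not assessable; zero passing
  variants → empty spectrum with undefined percentages; constant
  apparent-clonal curve → boundary g. Genuine contract violations
  (overlapping sample groups, oversubscribed clone fractions, out-of-range
  scores) raise typed errors naming the offender.
* Problem sizes in tests and the acceptance script (100 seeds × 1000
  mutations for the neutrality criterion; 100 random ≤ 6-region matrices
  for the parsimony equivalence; 20 seeds × 8 regions for balance
  recovery) were chosen as the smallest sizes at which the Monte-Carlo
  medians are stable.

## Known limitations

* Exact parsimony is limited to 12 regions; no heuristic search.
* The multiplicity estimator ignores subclonal copy number.
* Pooled purity/CN are depth-weighted means; if regions differ wildly in
  purity the virtual-single-sample CCF is only approximate.
* The sampling-requirement model is a one-parameter summary; tumors
  whose sharing structure is far from geometric will be summarized
  coarsely by g.
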