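# Methods

This note documents the statistical models implemented in `tagblock`, the
design choices made where several defensible options existed, the synthetic
data the test suite runs on, and the limits of what those tests show.

## Genotype representation

The panels this package targets are near-homozygous inbred lines, so calls
are stored as a single allele-class index per line and locus rather than a
diploid genotype. Missing calls use a sentinel (−1); the rare heterozygotes
that survive upstream filtering are kept in a packed code carrying both
class indices. Allele-frequency tallies count a heterozygote as half an
observation of each class — this matters for loci near MAF filter
boundaries.

Two encodings bridge the multi-allelic tag-level (TL) representation and
bi-allelic methods:

- **Six-symbol recoding.** Classes are ranked once by descending observed
  frequency (ties keep first-seen order) and mapped to A, C, G, T, +, −;
  classes ranked 7th and later pool into the sixth symbol. The ranking is
  not repeated after pooling.
- **Bi-allelic compression.** For loci with more than two classes, the most
  frequent class becomes the reference and all others pool into one
  alternate. Already-bi-allelic loci pass through unchanged, which makes
  the operation idempotent. Note that when no single class reaches 50% the
  pooled alternate is the *more* frequent compressed allele; the
  minor-allele frequency is always defined as one minus the largest current
  class frequency and therefore stays in [0, 0.5].

Marker filters take an explicit comparison mode because published filter
descriptions mix strict and inclusive thresholds (">15% MAF" vs
"MAF ≥ 0.2"): `maf_strict=True` means MAF > t, `False` means MAF ≥ t.
Missingness is filtered at ≤ t and heterozygosity at < t.

## Map placement

Candidates are placed on a fixed framework map by two-point recombination.
For each candidate–framework pair, within each RIL population, lines
missing or heterozygous at either locus are dropped, parental phase is
fixed as the more frequent coupling, and the recombinant count is the
smaller coupling class. Counts — not fractions — are pooled across
populations, weighting populations by information content. A pair is
informative only when both markers segregate among the jointly-called
lines.

The two framework markers with lowest pooled r̂ become the flanks (ties:
smaller cM gap, then id). The placed position interpolates linearly between
the flank positions with weights inversely proportional to the two r̂
values, so a candidate with r̂ = 0 to one flank snaps to it, and equal r̂
places it midway. No map-function correction is applied to r̂: ranking and
relative interpolation are invariant to monotone transforms of r, and the
framework positions themselves are never modified. Flanks on different
linkage groups leave the candidate unplaced with an ambiguity flag.

Bins are half-open 1-cM intervals anchored at the floor of the group's
minimum position; spans are max − min, with negative positions legal.

## Haplotype blocks

Pairwise |D′| is computed on bi-allelic inbred calls (phase is known;
missing and heterozygous calls dropped pairwise). The 95% confidence
interval uses a likelihood grid: the multinomial likelihood of the observed
2×2 haplotype counts is evaluated at |D′| ∈ {0, 0.001, …, 1} with allele
frequencies held at their observed values and D carrying the sign of the
observed disequilibrium, normalized to sum to one; the lower/upper bounds
are the smallest grid values whose cumulative mass reaches 5% and 95%.
Classification uses the printed thresholds exactly and strictly: strong LD
requires upper > 0.98 **and** lower > 0.7; recombination requires
upper < 0.9; anything else is uninformative. Pairs with fewer than 10
informative lines (configurable) or a monomorphic locus are uninformative.

A block is a contiguous run of mapped markers whose outermost pair is
strong-LD and in which at least 95% of informative pairs (strong + recomb)
are strong-LD, with at least one informative pair. The "95% of markers"
phrasing in the block-rule literature is read as 95% of informative
*pairs* — the original Gabriel formulation. Candidate intervals are
enumerated inside a sliding window (50 markers or 10 cM, whichever is
larger) using 2-D prefix sums over the pair-class matrix, then accepted
greedily by descending cM length, descending marker count, leftmost start,
skipping overlaps. This makes block assignment deterministic and invariant
to marker input order. Two-marker blocks are allowed — published
per-chromosome summaries show many blocks of 0 cM (cosegregating markers).

Block diversity is Nei's unbiased estimator Ĥ = n/(n−1)·(1 − Σ pᵢ²), with
n the number of lines complete at every member marker and the sum running
over block haplotypes with frequency ≥ 0.02. Frequencies keep the
complete-line denominator; they are *not* renormalized after excluding the
rare tail (whether the original analyses renormalized is not documented; we
record this as our convention).

## Mixed-model GWAS

Kinship is centred identity-by-state on markers with MAF ≥ 0.2:
K = (M − 2P)(M − 2P)ᵀ / (2Σ pₖ(1−pₖ)) with M the minor-allele dosage matrix
(missing filled at 2p̂). Structure covariates are the leading principal
components of the mean-filled dosage matrix restricted to markers with
MAF > 5% and missing < 20%; the default of 3 components is configurable
(the number used by the original analyses is unpublished).

The scan is P3D: variance components of the null model
y = μ + PCs·γ + u + e, u ~ N(0, σ²g·K), are estimated once by REML via the
spectral decomposition of K (one 1-D optimization over δ = σ²e/σ²g), and
every marker is then tested by generalized least squares in the whitened
basis with those components fixed. Multi-allelic TL loci enter as
allele-class dummies against the most frequent class (heterozygotes
contribute 0.5 to each of their classes) with a joint F-test on the class
degrees of freedom; incidence-matrix columns are tested one at a time as
quantitative regressors. Markers collinear with the null design get NA
p-values. With K = I the procedure reduces exactly to ordinary
fixed-effects regression, which the tests verify to 1e−8.

The CL haplotype incidence matrix has dimension i × ((b×k) − m): each block
with k observed haplotypes contributes k − 1 columns for its non-major
haplotypes; a line carrying the major haplotype is 0 across the block's
columns; lines incomplete at the block are missing and subsequently imputed
by k-nearest-neighbour over lines (k = 10, Euclidean distance on shared
observed columns, inverse-distance weights), giving probabilities in [0, 1].

Bonferroni thresholds are −log₁₀(α/n) per marker system, so systems differ
only through their marker counts. The hit filter discards a significant
marker when the class driving the effect (largest absolute effect column)
has frequency below 1%, or when re-testing with heterozygous calls set to
missing loses the hit (including the marker becoming untestable without its
heterozygotes). The exact heterozygote criterion used originally is not
operationalized in print; this two-part rule is our recorded substitute.

## Selection scan

Markers are standardized and regressed on the leading K principal
components; z-scores are coefficient/SE. Because the components are derived
from the same markers, null z-scores are overdispersed relative to N(0,1);
this is absorbed downstream. The Mahalanobis statistic uses a trimmed
estimate of location and scatter (drop the 5% of markers with the largest
preliminary classical distances, then take the sample mean/covariance) —
deterministic and adequate when outliers are scarce (<5%), in place of a
full minimum-covariance-determinant estimator. A genomic-inflation factor
λ = median(D²)/median(χ²_K) rescales D² before the upper-tail χ²_K p-value;
it is toggleable.

The scree-based choice of K reports explained-variance proportions for
components 1..20 and suggests the largest k whose drop to k+1 exceeds five
times the median successive drop. A literal "drop exceeds the median drop"
rule fires constantly under sampling noise (about half of all plateau drops
exceed the median); the factor of five marks drops clearly above the
plateau scale. The suggestion is advisory — the K actually used is always a
caller decision.

q-values follow Storey: π₀ estimated on the λ-grid 0.05…0.95 and
extrapolated with a cubic polynomial to the grid end; estimation is deemed
unstable — and plain Benjamini–Hochberg (π₀ = 1) used instead — when the
smoothed estimate leaves [0.1, 1] or any raw grid estimate exceeds 1 (a
non-uniform p-value tail). Multi-allelic loci enter the scan after
bi-allelic compression, since the z-score regression needs one dosage per
locus.

## Genomic prediction

Line BLUPs come from y = μ + environment (fixed) + line (random) + e,
fitted by profiled REML over the variance ratio. The implementation
exploits the block structure (one random effect per line), so each
likelihood evaluation is linear in the number of observations; with both
variance components supplied the fit is a single GLS pass and the BLUPs
equal the closed-form shrinkage n_iφ/(1 + n_iφ) times the line's mean
residual, which the tests check to 1e−8.

RR-BLUP fits y = 1μ + Zu + e with u ~ N(0, σ²u I) through the eigenvalue
decomposition of ZZᵀ and a single 1-D REML optimization; marker effects are
the conditional means u = σ²u Zᵀ V⁻¹(y − 1μ̂). With the variance ratio held
fixed this reproduces the closed-form ridge solution exactly, and
predictions agree with the equivalent-kernel form to 1e−8. Accuracy is
always the plain Pearson correlation between predicted and observed values
(not rescaled by h) — matching the "predicted vs observed" definition.
Cross-validation draws independent random calibration/test splits per
iteration without subpopulation stratification.

Two imputation methods are provided. **LD-kNNi**: for each missing call the
l = 30 markers with highest r² to the target marker define the distance
space (r² from globally standardized pairwise-complete cross-products — a
standard approximation to fully pairwise re-standardized correlation);
line-to-line distance is one minus mean IBS over those markers with at
least l/3 comparable; the k = 5 nearest observed lines vote with
inverse-distance weights. Hard calls round to the nearest dosage *observed
at that marker*, so inbred 0/2 markers never receive a heterozygous 1.
**"EM" imputation** is realized as iterative low-rank completion: missing
entries start at marker means and are refilled from a rank-q (default 10)
SVD reconstruction of the centred matrix until the largest change is below
1e−4; observed entries are never altered. The reference EM formulation in
the genomic-selection literature operates on the relationship matrix and
publishes no algorithmic detail; low-rank completion is our recorded
substitute, tested against exact recovery of low-rank matrices.

## The synthetic-data generator

`syndata.simulate_panel` emulates the data a tag-level GBS pipeline emits
for an elite inbred diversity panel. Lines are founder mosaics: eight
founder haplotypes per linkage group, per-locus founder states drawn from
Dirichlet(1.5) class frequencies, and each line copies a founder along the
map, switching founders with probability 1 − exp(−G·d/100) per d cM. The
switch-generations parameter G (`ld_generations`, default 40) sets the LD
decay scale; 40 reproduces the sub-cM haplotype blocks characteristic of
elite panels (published per-chromosome means of roughly 0.2–0.6 cM) —
smaller values give unrealistically long-range LD for a panel with a long
breeding history. Subpopulation structure comes from subpop-specific
founder-usage weights drawn from a Dirichlet with concentration
(1 − f)/f for drift parameter f, blended toward the panel mean by the
admixture proportion. Defaults (497 + 123 lines, drift 0.15, admixture 0.2,
20% missing, 1% heterozygous calls) emulate a two-subpopulation elite oat
panel; the heterozygote rate is a chosen default — upstream pipelines cap
heterozygosity at 8% but do not publish the surviving rate.

Divergently selected loci receive a direct allele-frequency displacement:
the favoured allele is redrawn per line at frequency 0.5 ± δ/2 by
subpopulation. Only loci outside cosegregation clusters are eligible, so
clusters stay intact. For selection-scan conditions the test suite uses
drift 0.05: the oat germplasm this emulates is documented as weakly
structured (intensive germplasm exchange), and a pcadapt-style scan can
only flag loci whose differentiation exceeds the genome-wide background —
under strong drift the ≥0.3-displacement power target is unreachable by
construction for any method of this class.

Each TL allele expands deterministically into 1–3 component SNP calls via a
fixed per-locus lookup generated once (mirroring the dual TL/SNP output of
tag-clustering pipelines); component SNPs carry two-decimal id suffixes and
the parent's map position. RIL populations use Haldane crossovers with the
F∞ adjustment: the parental origin switches between adjacent markers with
probability 2r/(1 + 2r), r = (1 − e^(−2d/100))/2, giving the closed-form
two-point expectation the tests check. Traits are
y = μ + g + env + e with residual variance solved from the across-
environment line-mean heritability, σ²e = n_env·σ²g·(1 − h²)/h²; at h² = 0
the genetic term is dropped, at h² = 1 the residual is zero.

What the generator does **not** emulate: sequencing reads, tag depth,
genotype-calling error beyond the missing/het rates, linked selection,
realistic allele-frequency spectra from demography, genotype-by-environment
interaction (beyond the additive environment effect), or epistasis. Passing
tests therefore demonstrate correctness of the statistical machinery under
a controlled additive, mosaic-LD world — not robustness to every artifact
of real GBS data.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen so the whole
suite completes in a few minutes on one CPU: panels of 150–600 lines and
150–2500 loci, 10–20 seeds per stochastic property, 8–25 CV iterations per
split. REML optimizations bound the variance ratio in [1e−8, 1e8] on a log
scale; likelihood-grid probabilities are clipped at 1e−12; eigenvalues of
kinship/kernel matrices are clipped at zero; marker columns whose residual
norm after projection on the null design falls below 1e−8 of their original
norm are declared collinear. All simulation entry points take explicit
seeds and identical configurations produce byte-identical outputs.

## Known limitations

- Block detection is O(window²) per marker and intended for the desk-scale
  maps the generator produces, not for hundreds of thousands of markers.
- The likelihood-grid CI fixes allele frequencies at their observed values;
  CIs for very small samples are accordingly approximate.
- LD-kNNi recomputes the marker–marker r² matrix densely, which is
  quadratic in marker count.
- The CLI covers the simulate/filter/blocks/scan/cv path; map placement and
  GWAS involve multi-object inputs (several RIL populations, kinship, PCs,
  incidence matrices) and are used through the library API.
- Incidence-matrix kNN imputation loops over missing entries in Python;
  fine for hundreds of columns, slow beyond that.
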