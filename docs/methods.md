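# Methods

This note documents the statistical models in `rileqtl`, the assumptions
they make, the defaults and why, and the choices taken where the design was
genuinely open.

## Population and recombination model

RILs are treated as fully inbred two-state genotypes (Col vs Alt); residual
heterozygosity is not modelled. Meiotic recombination follows Haldane's map
function, r = (1 − e^(−2d/100))/2 for d cM, without crossover interference,
and the apparent recombination fraction between RIL genotypes after repeated
selfing is R = 2r/(1 + 2r). Chromosomes are independent. The same model
drives both the genotype simulator (a two-state Markov chain along each
chromosome, first marker Bernoulli(½)) and the genotype-probability
calculation used by the scans, so the mapper is exactly matched to the
simulated process; with real genotypes the model is the standard one for
selfed RIL populations.

Genotype probabilities are computed on a grid of markers plus pseudomarkers
(default step 2 cM, configurable) from the nearest informative flanking
markers. With agreeing flanks at recombination fractions R₁, R₂ the
probability of matching them is (1−R₁)(1−R₂)/[(1−R₁)(1−R₂)+R₁R₂]; with
disagreeing flanks the left-match probability is
(1−R₁)R₂/[(1−R₁)R₂+R₁(1−R₂)]; a single informative flank gives 1−R, and a
chromosome with no information gives ½ with a warning. Pseudomarker bp
coordinates are interpolated linearly in cM between flanking markers.

## Genome scans

Interval mapping uses Haley–Knott regression: the phenotype is regressed on
the expected Alt dosage at each grid position and scored with
LOD = (n/2)·log₁₀(RSS₀/RSS₁). This is exact at observed markers for inbred
lines and is the standard fast engine when thousands of traits are scanned;
the unit suite checks it against an explicit least-squares oracle at 1e−9
relative tolerance. RSS₁ is floored at 10⁻¹² · RSS₀ and the LOD capped at
50 to guard against exact-fit degeneracies. Lines with missing phenotype
are dropped per trait; at least 4 informative lines are required.

Peak selection is iterative: the global LOD maximum above the threshold is
accepted (leftmost position on ties), ±15 cM around it is masked on its
chromosome, and the search repeats. The 15 cM exclusion window reflects the
number of informative recombinants a ~150-line population can resolve.
Support intervals are the contiguous region around the peak where the LOD
stays within 1.5 of the peak value, reported at grid resolution (no
sub-grid interpolation of the crossing point).

Composite interval mapping takes the IM peak set as cofactors and rescans;
cofactors within 15 cM of the test position (same chromosome) are dropped
from the model at that position, cofactors elsewhere always kept, and the
LOD compares the cofactor model with and without the test-position dosage.
Collinear cofactors are dropped (later ones first) with a warning. CIM is a
single pass over the IM set by default.

One numerical subtlety: the composite curve's active cofactor set changes
discontinuously along a chromosome, and strong QTLs spawn shoulder
cofactors just outside the exclusion window, so LOD-drop intervals read off
the composite curve can collapse to single grid points. The fitted model
therefore takes peak *positions* from the CIM rescan but reads each peak's
1.5-LOD support interval off the smooth IM profile. With this choice,
planted effects at |a|/σ = 1.5 over 158 lines are recovered with ~100 %
support-interval coverage in the validation suite; intervals from the raw
composite curve covered the true position only about half the time.

Additive effects average the phenotype per allele group at the peak,
signed Alt − Col (negative = Col up-regulated). At pseudomarkers lines are
assigned by maximum probability; lines with P(Alt) in [0.45, 0.55] are
ambiguous and excluded from the means. R² per QTL is from one-way ANOVA at
the peak; QTL×QTL interaction R² is the incremental R² of the interaction
term over the two-main-effect model, computed only for traits with ≥ 2
detected QTLs.

## Permutation thresholds and FDR

Phenotypes are permuted across lines with genotypes fixed; the genome-wide
maximum LOD per permutation forms the null. The per-trait threshold is the
95th percentile of that null (default 1,000 permutations; the simple
regression identity RSS₁ = RSS₀(1−r²) lets all permutations reduce to one
matrix product, so even 500 traits × 1,000 permutations run in seconds).
The genome-wide threshold is the 95th percentile of the per-trait
thresholds across a 500-trait random sample; an alternative reading (mean
+ 1.645·sd normal upper bound) is available via `method="normal"`.
Empirical p-values use the +1 correction, p = (1 + #{null ≥ obs})/(1 + N),
so no p is exactly zero. Storey q-values use a fixed λ = 0.5 (no spline):
π₀ = min(1, #{p > λ}/((1−λ)m)), q₍ᵢ₎ = min_{j≥i} π₀·m·p₍ⱼ₎/j. λ = 0.5 is
robust at the m ≈ 500 sample the thresholding uses. The FDR-level p-cutoff
is the largest p with q at or below the level.

## Local/distant classification, bins and hotspots

An eQTL is local when its peak lies on the gene's chromosome within 1 Mb of
the gene's representative position — the midpoint of its annotated feature
(a symmetric choice; probe annotations rarely specify which coordinate to
use). Unannotated traits stay unclassified.

The genome is tiled with 1 Mb bins; a terminal remainder shorter than
500 kb merges into the previous bin, a longer one stands alone. The
trans-hotspot test counts distant-eQTL *peaks* per bin (membership by peak
position, not interval) and compares each bin against the (1−α) quantile
("higher" interpolation, so an integer) of the per-permutation maximum bin
count when every peak is reassigned uniformly at random over all bins
(default 1,000 permutations, α = 0.05). A per-chromosome stratified null is
available behind a flag; the uniform default agrees with the analytic
max-of-Poisson quantile within ±2 counts in the test suite. Density
regressions are ordinary least squares of per-bin eQTL counts on a per-bin
covariate with the ANOVA F-test p-value.

Cross-population comparison declares a trait shared-local when both
populations hold a local eQTL for it with overlapping physical support
intervals on the same chromosome; it reports sign concordance of the
additive effects and both Pearson and Spearman correlations.

## Confounder correction

The correction model is a linear factor model: per trait, intercept and the
known covariate are regressed out; the top-K right singular vectors of the
residual matrix (over lines) serve as hidden factors; each trait is then
regressed on known + hidden factors and the residuals become the corrected
phenotypes. Missing values are mean-imputed per trait before the SVD and
re-masked afterwards. This is a deliberate simplification with the same
interface as richer probabilistic factor models (known factor + K hidden
factors in, residual phenotypes out); it captures the dominant variance
directions but has no ARD-style shrinkage, so the factor count matters.
K is chosen by yield: for each candidate (default 0, 5, 10, 20, 30) the
corrected matrix is scanned on a trait subsample and the K maximizing the
number of traits clearing the FDR-5 % permutation threshold wins, smaller
K on ties. Known risk, measurable in simulation: when a strong trans
hotspot drives many traits, expression-derived factors can absorb that
genuine genetic signal and distant associations are lost; the suite reports
this drop between K = 0 and K = 10 as a diagnostic rather than asserting
it away.

## Two-colour normalization

Per array: flagged spots are excluded; the dye bias is removed by robust
local regression of M on A (statsmodels `lowess`, degree-1 local linear,
default span 0.3 with 4 robustifying iterations — degree-1 is what the
installed smoother provides and removes the planted smooth biases in the
suite to < 0.02 median |M|); then each print-tip block's median M is
subtracted, making block medians exactly zero. No background subtraction is
performed. Dye-swap pairs combine as M̄ = (M₁−M₂)/2, Ā = (A₁+A₂)/2, and
the co-hybridized samples' intensities are (2Ā−M̄)/2 (the sample labelled
green on the first array) and (2Ā+M̄)/2; their sum is 2Ā identically.
Arrays are then shifted additively so each mean intensity equals 8.5
exactly, preserving within-array contrasts. The second loess application
changes M by ~10⁻⁴ median at realistic noise, not machine epsilon: a
degree-1 lowess is not a projection operator.

The parental differential-expression caller is a paired t-test with a
trimmed-variance moderation scheme: gene variances outside the 2.5 %–97.5 %
quantiles are excluded from the shrinkage pool; pool members use a 50:50
blend of their own and the pooled mean variance, excluded genes their own
variance; df = n − 1; Bonferroni over genes at α = 0.05. The blending
scheme is an approximation chosen for simplicity and is configurable; the
tests exercise its calibration (family-wise error under the null) rather
than its fine behaviour.

## Directional allelic-effect test

The genome-wide Col:Alt up-regulation ratio is computed from the signs of
the local-eQTL additive effects (never hard-coded; a gene with several
local eQTLs votes by its strongest). Over-representation of local-eQTL
genes per GO term is an upper-tail hypergeometric test, Bonferroni over
terms. Within significant categories, every term with more than 20 genes
is tested for directional skew, one-sided in the direction of the observed
majority: binomial by default with success probability ratio/(ratio+1),
or the finite-population hypergeometric when genome-wide direction counts
are supplied (the two agree to < 1 % at population 10⁵). The binomial
default exists because published tables rarely print the finite-population
counts behind a ratio like "1.6:1"; at that ratio the all-majority closed
form is (1.6/2.6)ⁿ, giving 0.02, 0.03 and 0.05 at n = 8, 7, 6. GO input
must be pre-propagated (no DAG traversal is performed).

## What the simulations do and do not show

The generator reproduces the *structure* of the study data — map size,
population size, biallelic inbred genotypes, additive architectures,
hotspots, low-rank confounding, dye-swap intensity structure — under
exactly the model the mapper assumes (Haldane, no interference, Gaussian
noise). Passing recovery and calibration tests therefore validates the
implementation, not the model's adequacy for real tissue: real arrays have
heavier-tailed noise, spatial artefacts beyond print-tip offsets,
cross-hybridization, segregation distortion, and residual heterozygosity,
none of which are emulated. Default simulation conditions: 158 lines,
90 markers on 5 chromosomes, residual σ = 0.5 (log2 scale), planted
effects a = 0.75–1.0 (|a|/σ 1.5–2), baseline 8.5.

## Problem sizes

The validation suite uses 500 traits with 200 permutations per trait for
null calibration, 200 planted traits plus a 100-trait hotspot for recovery,
and 1,000 permutations for hotspot thresholds — sizes at which every
quantity of interest is stable (Monte-Carlo s.e. well inside the asserted
bounds) while the whole suite runs in well under a minute for the
statistical core.

## Known limitations

- CIM is one IM→CIM pass; no multiple-QTL model search or epistasis scan
  (interaction R² is only computed for detected peaks).
- The factor correction is an SVD residual scheme, not a full probabilistic
  model; joint factor/QTL inference is out of scope.
- The trimmed-variance estimator is an approximation (see above).
- Support-interval endpoints are grid-resolution; with the default 2 cM
  step that is the dominant quantization of interval coverage.
- Hotspot bins use peak positions only; an eQTL whose interval spans a bin
  boundary contributes to exactly one bin.
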