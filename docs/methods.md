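# Methods

## Models and procedures

### TAV enrichment by permutation

For a trait with per-SNP p-values, a class of *n* SNPs, and a threshold *t*
(default 1e-4, swept over 1e-1 ... 1e-8), the observed statistic is
m = #{class SNPs with p < t} (strict inequality; a SNP exactly at the
threshold is not significant). The null resamples *n* SNPs uniformly
without replacement from the full genotyped panel — including the class's
own SNPs — 1000 times and records the significant count of each draw. The
criticals are the 950th and 50th elements of the ascending sort (for other
permutation counts, the ceil(0.95·B)-th and floor(0.05·B+1)-th positions);
the class is enriched iff m strictly exceeds the upper critical and
depleted iff m falls strictly below the lower one.

Because the draw is uniform without replacement, the null count is exactly
Hypergeometric(N, K, n) with K the panel-wide significant count; the
default implementation draws the counts from that distribution directly,
which is an exact realization of the permutation, not an approximation.
An explicit subset-sampling mode exists and a test verifies the two routes
agree in distribution. Seeds are derived per (class, trait, threshold) from
a master seed by SHA-256 hashing, so extending the analysis never perturbs
existing results.

The per-threshold false discovery rate is FDR = min(1, t·n/m): expected
false positives (t·n) over observed positives, reported NA when m = 0.
Note the m = 0 case is undefined rather than zero — there are no
discoveries to attribute a rate to.

### Joint logistic enrichment

TAV status is binarized (1 iff p < t) and regressed on all binary class
memberships simultaneously, with an intercept. The fit is maximum
likelihood by iteratively reweighted least squares with step-halving
(relative log-likelihood tolerance 1e-8, max 50 iterations). Positive
coefficients mean enrichment net of the other classes; each class gets a
Wald −log10 p computed on the log scale so small p-values remain exact.
Degenerate designs are handled explicitly: constant membership columns are
excluded and listed; exactly duplicated columns raise an error naming the
pair; an exhaustive taxonomy (e.g. intergenic + intragenic covering every
SNP, or CDS exactly covered by synonymous + missense) is collinear with the
intercept, and a minimal set of columns found by pivoted QR is dropped with
a warning. Quasi-separation is detected by coefficient divergence
(|log-odds| > 30 on a binary design) and the affected classes are reported
NA with `converged = False` instead of meaningless huge values. A
drop-class mode refits without chosen classes; removing a parent class that
carries its children's shared signal strengthens the children's
coefficients, which is the expected behaviour for nested annotations.

### GRMs and distances

The GRM uses the standardized allele-count estimator with sample allele
frequencies recomputed per SNP subset (matching the behaviour of GRM tools
run on SNP-filtered input). Missing genotypes are mean-imputed (to 2p_i)
only inside the GRM, contributing zero to the numerator; the stored
genotype matrix keeps its missing values. Monomorphic SNPs are excluded
and listed; a class with no usable SNPs raises a "class unusable for GRM"
error rather than returning a degenerate matrix. Distances between class
GRMs are Frobenius norms of the elementwise difference over the full matrix
(diagonal included); a half-matrix option exists for sensitivity since
whether self-relationships should count is a matter of convention.

### AI-REML

The model y = Xb + Σ_c g_c + e with g_c ~ N(0, G_c σ²_c) is fitted by
average-information REML:

- score_i = ½(y'P G_i P y − tr(P G_i)), AI_ij = ½ y'P G_i P G_j P y, with
  P the projected inverse covariance; tr(P G_i) is evaluated as the
  elementwise sum P∘G_i so no per-component matrix product is needed.
- The AI step is step-halved until the restricted log-likelihood does not
  decrease; if no AI step helps, an EM step (σ²_i ← σ²_i + σ⁴_i(y'PG_iPy −
  tr(PG_i))/n), also step-halved, is taken. Accepted iterations therefore
  never decrease the likelihood.
- Components are floored at 1e-8·var(y). A component at the floor whose
  gradient points further down is frozen out of the AI system for that
  iteration (active-set treatment); without this, clamped AI directions can
  cycle near the boundary.
- Convergence: relative log-likelihood change < 1e-8, max 200 iterations.
  If the covariance matrix fails to factorize, a ridge of 1e-6·var(y) is
  added to the diagonal once and logged.
- Standard errors come from the inverse AI matrix at the optimum,
  constrained (floored) components excluded; SEs of h² ratios use the delta
  method. Heritability per component is reported both as σ²_c over the
  total of all fitted components (the joint-model ratio, used for per-SNP
  variance) and as σ²_c/(σ²_c+σ²_e) for single-GRM reading.

### Random-intergenic comparison and per-SNP variance

A class's single-component h² is compared with five GRMs each built from
the same number of SNPs drawn without replacement from the intergenic set
(replicate seeds are master_seed + index). The class is flagged a
significant increase (decrease) when its h² lies above (below) the
replicate mean by more than 2× the spread (sd, ddof = 1) of the replicate
h² values — the replicate-spread reading of "±2 standard errors".
Non-convergent replicates are excluded; fewer than two survivors yields NA.

Calibration of this rule, established analytically and confirmed by
simulation: when the class is itself a random intergenic subset, the class
estimate X₀ is exchangeable with the replicates X₁..X₅, so
(X₀ − X̄)/(S·√1.2) is t-distributed with 4 df and the false-flag level is
P(|t₄| > 2/√1.2) ≈ 14% — regardless of the correlation the shared phenotype
induces between estimates. Observed levels in simulation are 10–14%
(boundary truncation of h² estimates pulls the rate down). The rule is
therefore more permissive than a nominal 5% test; users wanting a stricter
test should widen the multiplier or increase the replicate count.

Per-SNP genetic variance is (h²/n)·100/1e-4 — heritability as a percent,
per SNP, in units of 1e-4 — so a class with h² = 0.20 over 2000 SNPs scores
100. It makes small information-dense classes comparable with large
classes that capture variance merely by containing many SNPs.

### GWAS stage

The association scan is plain OLS per SNP (Frisch–Waugh residualization
against the fixed-effect design, two-sided t-test on the genotype
coefficient, df = n − rank(X) − 1). Monomorphic SNPs get p = 1 and a flag.
There is no relatedness or structure correction: the stage exists so the
pipeline is closed over synthetic data, where individuals are unrelated by
construction. Real studies should supply externally computed mixed-model
GWAS p-values instead (the readers accept any per-SNP p-value table).

## Synthetic data: what it emulates, and what it does not

`SimScenario` draws per-SNP allele frequencies uniformly from `maf_range`
(default 0.05–0.5), genotypes as Binomial(2, p) per site, and assigns SNPs
to a nested taxonomy with intergenic ≈ 67%, intron 28%, CDS 1.2% (split
2:1 synonymous:missense), UTR 0.8% — proportions patterned on a bovine HD
array census. Phenotypes are y = Xb + Σ_c g_c + e with per-SNP effects
N(0, 1/(2p(1−p))), the standardization implicit in the GRM, so every causal
SNP contributes equal expected variance and single-component GREML is
unbiased for the planted h². Each realized component is rescaled to hit its
target variance fraction exactly; successive components are decorrelated
against the running genetic total within their own genotype span, and the
environmental noise is orthogonalized against all genetic components, so
for disjoint causal classes the realized variance budget is exact (nested
causal classes retain a small residual cross-term). Environmental variance
defaults to (1 − total h²)·varP; `env_fraction=0` produces exactly
deterministic phenotypes for boundary tests.

Deliberately not emulated: linkage disequilibrium (independent sites by
default — an optional block-copying haplotype mode generates within-block
correlation for qualitative experiments), realistic allele-frequency
spectra, genotyping error, and population structure. Consequently, passing
tests demonstrate correctness of the statistical machinery under the
model's own assumptions; they do not certify behaviour under strong LD,
where enrichment of a class can reflect tagging of causal variants outside
it — the standard caveat when interpreting synonymous or intron enrichment.

## Problem sizes and numerical choices in the test-bed

The validation suite uses desk-scale problem sizes chosen so each property
is measured in its informative regime: permutation calibration on a
10,000-SNP genome over 400 null draws; null-distribution checks at class
sizes 100 and 1000; REML grid oracles on ≤30 individuals against a 200×200
(σ²_g, σ²_e) grid; single-component recovery at 800 individuals × 4000
SNPs and two-component recovery at 500 × 2000 over 50 replicates each; the
random-intergenic rule at 400 × 1500 (the smallest size at which replicate
h² estimates are interior rather than boundary-piled); logistic recovery
at 1e5 SNPs. The acceptance script's study is 1000 individuals × 6000
SNPs with h² = 0.35 planted in 24 missense SNPs over a 0.20 background —
small enough to run in seconds, large enough that the planted class yields
a stable TAV count. Its logistic stage binarizes at p < 1e-3 and drops the
CDS class: at this scale the baseline TAV rate at 1e-4 is zero outside the
planted class and every CDS TAV is missense, either of which quasi-separates
the joint fit; the reported configuration is the well-conditioned analogue
of the dense-panel regime (and mirrors the CDS-removed sensitivity fit).

## Known limitations

- The OLS GWAS stage is not valid under relatedness or structure; it is a
  synthetic-data convenience, not a mixed-model association method.
- The ±2·SE random-set rule has a ~10–14% false-flag level (see above);
  it is reproduced as specified, not recalibrated.
- REML solves dense n×n systems; practical up to a few thousand
  individuals, not for hundred-thousand-scale cohorts.
- The FDR is the expected-over-observed count ratio per threshold, not a
  step-up procedure; it is a descriptive quantity attached to each
  threshold choice.
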