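# Methods

This note records the models implemented in `hetvar`, their assumptions, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want explained.

## Codings and relationship matrices

Allele frequencies are always the pooled frequencies over the whole dataset.
A multi-breed panel is thereby modelled as a set of partially inbred lines
descended from one base population at those frequencies; relationship-matrix
diagonals above 1 are expected and carry the inbreeding information. At a
SNP with B-allele frequency `p`:

- additive coding `T = (x − 2p)/√(2pq)` for dosage `x ∈ {0,1,2}`;
- dominance coding `H ∈ {−p/q, +1, −q/p}` for AA/AB/BB.

Under HWE weights these are orthonormal contrasts (`E(H)=0`, `E(H²)=1`,
`E(HT)=0`), so `GRM = TT′/m` and `DRM = HH′/m` attach classical additive and
dominance variance to their components. Orthogonality degrades as genotype
frequencies leave HWE; the practical check is that the additive ratio from
the additive-only and additive+dominance fits agree (asserted on simulated
data at |Δ| < 0.02). The unweighted (Vitezica-style) DRM is available as an
explicitly labelled alternative, never the default.

**Frequency floor.** SNPs with pooled MAF < 1/(2n) (configurable) are
excluded from both codings: the `1/(2pq)` weights diverge there and a SNP
lacking genotype classes has no estimable dominance contrast. The `/m`
divisor counts retained SNPs only, keeping the mean GRM diagonal calibrated
near 1 on single-breed HWE data.

**Missing genotypes.** Default is per-SNP mean imputation for `T` (coded 0)
and HWE-class-average imputation for `H` (also 0, the expectation of `H`
over `q² : 2pq : p²`); a strict mode rejects missing calls. Reference data
for this design are fully imputed panels, so completeness is the normal
case and imputation a convenience for toy inputs.

**Pedigree A.** Tabular (recursive) numerator relationship matrix; the
pedigree is pruned to ancestors within 5 generations (configurable) of the
focal animals before the recursion, so deeper links are treated as unknown.
Diagonals are `1 + F`.

## REML engine

`reml_fit` maximises the restricted log-likelihood
`−½[log|V| + log|X′V⁻¹X| + y′Py]` for `V = Σ_k σ_k² K_k + σ_e² I` by
average-information updates with step-halving; when no damped AI step
improves the likelihood it falls back to an EM-flavoured scaled-gradient
step (`θ + 2θ² s/n`, also halved). Everything is dense; the intended regime
is up to a few thousand phenotyped animals.

Numerical choices:

- **Convergence**: |Δ logL| < 1e−6 together with a maximum parameter change
  < 1e−4 relative to a phenotypic-variance scale, or three consecutive
  iterations with negligible likelihood movement. The stall rule matters on
  flat ridges (nearly collinear kernels, e.g. GRM vs DRM under a null): any
  point on the ridge is a restricted-likelihood optimum, and insisting on
  parameter stability there turns a converged fit into a spurious failure.
- **Boundary handling**: components are floored during iteration; a genetic
  component sitting below 1e−5 of the phenotypic variance for several
  iterations is handed back early, pinned to exactly 0, and the system
  re-solved without it. Zero-dominance traits therefore report an exact
  0.00, never a small negative, and the associated LRT statistic is 0. The
  early hand-back also avoids the classic EM crawl along the zero boundary
  (hundreds of iterations of 1e−5 likelihood gains).
- **Fixed effects**: exactly collinear columns are dropped (first of each
  group kept, dropped names reported); the heterozygosity covariate is
  centred, which leaves its slope β and t-value untouched but keeps the
  intercept interpretable. Restricted likelihood is invariant to the fixed
  parameterisation, which the tests assert under contrast re-coding.
- **SEs** come from the inverse AI matrix at the optimum; for components on
  the boundary they are reported as 0.

BLUP solutions are `û_k = σ_k² K_k Py`; predictions for animals outside the
fitted set use the rectangular cross-block `K[target, fitted]`, which is
identical to carrying them in the matrices with masked phenotypes (asserted
against a direct joint solve). The equivalence of relationship-matrix BLUP
with the per-SNP ridge formulation (`g = Tu`, `Var(u) = Iσ_g²/m`) is checked
at n = 200, m = 500 through the ridge model's own mixed-model equations.

## Dominance GWAS

The scan is two-stage generalised least squares: the no-SNP model
(polygenic kernel + residual) is fitted once by REML, `V` is
Cholesky-factored, and each SNP's dosage and heterozygote indicator are
tested by OLS in the whitened space with Wald t statistics on residual
degrees of freedom. The dominance p-value is conditional on the additive
covariate by construction (joint fit). This background-reuse approximation
is standard for mixed-model association; an exact mode that refits the
variance components per SNP is available (`exact_refit`) and feasible on
subsamples. The polygenic kernel defaults to the pedigree A matrix, with
the GRM as an option.

SNPs with only two genotype classes get an additive-only record with the
dominance effect marked inestimable; constant SNPs are skipped with a
reason. The scan summary counts significant dominance effects at the
configured threshold split by sign of `δ̂`, and carries
`FDR = P(1 − A/T)/[(A/T)(1 − P)]`, which equals 1 when `A = P·T` and may
exceed 1 (read: everything found is noise). `A = 0` returns a flagged
infinity rather than a number. Benjamini–Hochberg is included only as a
labelled extra.

## Epistasis scans

Only lead×genome scans are offered: for a user-supplied lead SNP `j`, every
partner `i` is tested by fitting `l_j`, `s_i` and the elementwise dosage
product `l_j∘s_i` simultaneously as covariates over the same whitened
background, Wald-testing the interaction. All-pairs scans are deliberately
not implemented (multiple-testing containment is the point of the lead-SNP
design). Collinear partners (the lead itself, or perfect LD with it) are
skipped; a monomorphic lead is a configuration error. The 2×2 allele-effect
table reports cell(B,B) = `û + â + m̂` against a (A,A) baseline of 0.

## Cross-validation and validation

Fold assignment is by whole paternal half-sib family: families sorted by
decreasing size (ties broken by a seeded shuffle) go greedily to the
currently smallest fold. Unknown-sire animals are singleton families. This
guarantees no half-sib pair straddles a fold boundary — the structural
requirement for independent validation — at the cost of only approximate
size balance (max/min fold ratio ≤ 1.3 across seeds in testing).

Sign concordance re-estimates each discovery-significant dominance effect
in the validation animals (dropping SNPs without all three genotype classes
there) and χ²-tests the same-direction count against 50%. Prediction
accuracy masks validation phenotypes, fits REML+BLUP on the remaining
folds, and reports within-breed Pearson correlations between out-of-fold
`ĝ` and fixed-effect-corrected phenotypes, record-weighted across breeds
with fewer-than-200-record breeds excluded. The fixed effects used for the
correction are estimated on training folds by default; a `correction="full"`
flag estimates them once from all data, since either convention is
defensible and the difference is worth being able to measure. Breeds whose
predictions are constant are flagged NaN, not zeroed.

## Synthetic-data generator

The generator emulates the *structure* of a multi-breed beef panel: breeds
with breed-specific founder frequencies (Beta(2,2) rescaled into
[maf_floor, 1−maf_floor] by default — a hump-shaped spectrum that keeps
dominance estimable everywhere), paternal half-sib families from
gene-dropping (each sire's offspring split evenly, one unrelated dam per
offspring), within-breed HWE at founding, a pooled-MAF floor enforced by
resampling, and traits composed of dosage-additive effects, heterozygote
dominance deviations (optionally all one sign), lead-anchored
additive×additive interactions, a pedigree-correlated polygenic term and
Gaussian residuals. All randomness flows from one seed through
`SeedSequence` child streams per operation.

It does **not** emulate linkage disequilibrium (SNPs are exchangeable and
unlinked), realistic chromosome maps, genotyping error, selection, or
overlapping generations. Passing tests therefore demonstrate correctness of
the estimators under the model's own assumptions plus family/breed
structure — not robustness to LD between causal and marker loci, which real
panels have and which shifts per-SNP power and FDR.

`truth_from_fractions` builds architectures at target variance fractions on
two scales: `realized` rescales effect classes so the sample variance
decomposition hits the targets exactly (right for generator-contract tests
and demos), while `model` leaves i.i.d. standardized effects at
`σ² = fraction/m` so the *base-population parameters* of the GRM/DRM model
equal the targets (right for estimator-bias studies, since under family
structure realized sample variance and base-population variance differ).
Directional dominance draws `v = |v|`; its mean component is exactly what
the heterozygosity covariate absorbs, so directional traits show a large
`t_He` while `σ_d²` keeps only the variance of deviations around that mean
— the intended semantics of fitting `het` as a covariate.

## Problem sizes in the checks

The acceptance checks run at sizes chosen to make their Monte-Carlo errors
informative on a single CPU in minutes: variance-ratio recovery uses 30
replicates of n = 1000 animals × m = 1000 SNPs in the test suite (15 in the
acceptance script) at the study-typical fractions V_A/V_P = 0.4,
V_D/V_P = 0.1, judged at 3 Monte-Carlo standard errors; GWAS null
calibration uses 10⁵ SNP tests in the suite (5 × 10⁴ in the script); the
boundary LRT null uses 200 replicates (60 in the script). Exact identities
(codings, FDR algebra, brute-force matrix oracles, ridge equivalence) are
size-independent and checked at machine precision or 1e−6.

## Known limitations

- Dense linear algebra throughout: O(n³) per REML iteration, n ≲ 5000.
- No multi-trait REML, no epistatic variance components (Hadamard-product
  kernels), no Bayesian alternatives.
- The GWAS default reuses null-model variance components across SNPs;
  per-SNP refitting is exact but slow, and the adequacy of the
  approximation should be spot-checked with `exact_refit` on subsamples
  when effect sizes are large.
- The simulator's lack of LD means FDR and power figures transfer to real
  panels only qualitatively.
- X-chromosome handling is exclusion (the default filter drops it);
  dosage-compensation models are out of scope.
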