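# hetvar

Non-additive genetic variation in multi-breed SNP panels: dominance variance
partitioning, dominance GWAS, lead-SNP epistasis scans and sire-family
cross-validated genomic prediction — with a gene-dropping simulator that
produces multi-breed half-sib data with known architecture.

## The problem

Livestock genetic evaluation is built almost entirely on additive effects,
yet traits tied to fitness (growth, fertility) routinely show heterosis and
inbreeding depression — signatures of *directional dominance*. Quantifying
dominance from SNP data in a multi-breed population raises three coupled
questions this package answers:

1. **How much phenotypic variance is dominance?** Fit
   `y = 1μ + Xb + het·β + g + d + e` with `g ~ N(0, G σ_g²)`,
   `d ~ N(0, D σ_d²)` by REML, where `G = TT′/m` and `D = HH′/m` are built
   from orthogonal per-SNP codings at pooled allele frequencies
   (`p` = B-allele frequency, `q = 1 − p`):

   | genotype | additive `T` | dominance `H` |
   |---|---|---|
   | AA | `−2p/√(2pq)` | `−p/q` |
   | AB | `(q−p)/√(2pq)` | `+1` |
   | BB | `2q/√(2pq)` | `−q/p` |

   Under HWE weights `E(H) = 0`, `E(H²) = 1`, `E(HT) = 0`, so `σ_d²` is
   classical dominance variance, and the mean-heterozygosity covariate
   `het·β` absorbs the average inbreeding effect (its t-value is an
   SNP-based estimate of inbreeding depression). The model is equivalent to
   per-SNP random regressions `g = Tu`, `d = Hv` with i.i.d. `u, v` — an
   identity the test suite checks numerically.

2. **Which individual SNPs show dominance?** A per-SNP mixed-model scan fits
   the dosage `s` and the heterozygote indicator `w` jointly over a
   polygenic background, testing `δ` conditional on `α`, with the
   expected-false-positive FDR `P(1 − A/T) / [(A/T)(1 − P)]` and a
   sire-family split for sign-concordance validation (no validation animal
   has a paternal half-sib in discovery).

3. **Does any of it help prediction, and do loci interact?** Five-fold
   cross-validation assigns whole sire families to folds and compares
   GRM-only against GRM+DRM prediction of `ĝ = â + d̂` by record-weighted
   within-breed correlation with corrected phenotypes; an
   additive×additive scan tests the interaction `m_ji` between user-supplied
   lead SNPs and every other SNP, fitted simultaneously with both main
   effects.

It is a library first: import it, or use the thin `hetvar` CLI
(`simulate`, `kinship`, `varcomp`, `gwas`, `epistasis`, `crossval`,
`run-all`). The `examples/` directory holds one short narrative script per
capability.

## Worked example

`python examples/03_variance_components.py` simulates 800 animals in two
half-sib-structured breeds at 800 SNPs, with true ratios
`V_A/V_P = 0.40`, `V_D/V_P = 0.10`, and prints:

```
AM   V_A/V_P = 0.349   V_D/V_P = 0.000   V_P = 0.885
ADM  V_A/V_P = 0.353   V_D/V_P = 0.090   V_P = 0.888
LRT for dominance variance: 2*dlogL = 4.22, chi2(1) P = 0.03991
...
directional dominance: t_He = +12.42 (beta = +25.30 trait units per unit heterozygosity)
```

AM (additive-only) and ADM (additive+dominance) agree on `V_A/V_P` because
the codings are orthogonal; the ADM dominance ratio 0.090 recovers the
simulated 0.10 within sampling error, and the likelihood-ratio statistic
4.22 on χ²(1) flags it at P ≈ 0.04. The second block plants all-positive
heterozygote effects and shows them emerging as a strongly positive
regression of phenotype on mean heterozygosity (t = +12.4) — inbreeding
depression measured from SNPs.

`python examples/04_dominance_gwas.py` runs the per-SNP scan (10 planted
dominance QTLs, n = 1000): 8 of 1500 SNPs significant at P < 10⁻⁴, all with
positive δ̂, FDR 1.9%.

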