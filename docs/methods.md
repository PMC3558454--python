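# Methods

## Scores and the shrinkage correlation model

For standardized genotypes **X** (n samples × d SNPs, columns mean 0 and
sample variance 1 with denominator n−1) and a standardized metric phenotype
y, the marginal statistic is the correlation vector r_XY = Xᵀy/(n−1). For a
binary phenotype it is the two-sample t-score vector with pooled within-group
variance (denominator n₁+n₂−2); a SNP with zero pooled variance gets score 0
and a warning rather than an error, since it carries no two-sample evidence.

The correlation-adjusted scores are R^(−1/2) r_XY (CAR) and R^(−1/2) τ (CAT),
where R = λI + (1−λ)R_emp is the shrunk SNP–SNP correlation matrix. The
binary case estimates R from the pooled standardized sample, not within
groups. Squared adjusted scores sum to the plug-in r_YXR⁻¹r_XY (estimated R²)
and τᵀR⁻¹τ (Hotelling's T²) respectively; group importances are within-group
sums of squared scores.

### Matrix-free powers

A thin SVD X = VΣUᵀ gives R_emp eigenvalues Λᵢ = σᵢ²/(n−1) and eigenvectors
U, so R = λ(I + U diag(M) Uᵀ) with Mᵢ = ((1−λ)/λ)Λᵢ and rank m ≤ n−1.
Components with σᵢ ≤ rank_tol·σ_max (rank_tol = 1e-9) are dropped as
numerical rank deficiency. Any power follows from

    R^α = λ^α (I − U(I − (I+M)^α)Uᵀ),

applied to a vector with only d×m and m×1 intermediates. α = 0 and λ = 1
return the input exactly (identity map), with m = 0 permitted at λ = 1.
A dense counterpart (full eigendecomposition, guarded to d ≤ 500) serves as
the test oracle only.

### Shrinkage intensity

The default is λ = 0.1, a setting that works well for exome-scale panels
with strong within-gene LD; it is deliberately fixed rather than estimated so
that replicate analyses share one regularization. The analytic
variance-minimizing estimator λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²
(Schäfer–Strimmer, with Var̂(r_ij) = n/(n−1)³ Σ_k (w_kij − w̄_ij)² for the
standardized cross products w) is available as `lam="auto"`; both sums are
rearranged through the n×n Gram matrix so the estimator also never forms a
d×d array. λ = 0 is outside the admissible range (R would be singular
whenever d > n−1); the allowed range is (0, 1].

## Local-FDR selection

CAR scores are correlations, so the null component is modelled by the exact
null density of an empirical correlation coefficient,
f₀(r;κ) = (1−r²)^((κ−3)/2)/B(1/2,(κ−1)/2), κ > 3 acting as an effective
sample size (equivalently r² ~ Beta(1/2,(κ−1)/2)). CAT scores are first
mapped onto the correlation scale by r = t/√(t²+df), df = n−2. Adjusted CAR
scores can slightly exceed 1 in magnitude (the λ^(−1/2) factor); such
overwhelming signals are folded just inside the open interval before null
fitting, which cannot affect which SNPs are selected.

κ is estimated by maximum likelihood on the scores with |r| at or below
their 75th percentile, treated as a sample from the null truncated to that
interval; the truncation point is fixed (rather than searched adaptively)
for determinism. π₀ = min(1, truncated count / (d · fitted null mass)). The
optimizer works on log(κ−3), and hitting the lower boundary (κ ≤ 3, an
implausibly heavy null for any realistic sample size) is an error.

The observed density enters through its Grenander (monotone nonparametric
ML) estimate evaluated on the null p-value scale p = P₀(|R| ≥ |r|; κ̂):
the null density of p is uniform and the alternative density is decreasing,
so lfdr(r) = min(1, π₀/f̂(p(r))) with f̂ the left derivative of the least
concave majorant of the p-value ECDF (computed by weighted pool-adjacent-
violators with knots forced at 0 and 1). This is the same estimate as a
monotone density fit on |r| — the change of variables through the null CDF
maps one onto the other — and it makes two properties structural rather than
enforced after the fact: lfdr is automatically non-increasing in |r|, and at
r = 0 it equals exactly 1 whenever π₀ = 1, because the terminal slope of a
concave majorant of a CDF on [0,1] can never exceed 1. Scores where f̂
vanishes get lfdr 1. Selection keeps lfdr < cutoff, cutoff 0.5 by default —
the conventional point at which a score is more likely alternative than
null.

## Preprocessing

Pipeline order: additive recoding → standardization → exact-duplicate
removal → synonymous filter, with the column count logged at each stage.
Recoding counts minor-allele copies, flipping any column whose counted
allele has sample frequency above 0.5; sites with more than two alleles and
missing calls are hard errors (no imputation — the intended inputs are
complete matrices). Duplicates are detected by exact integer equality on the
coded matrix (unambiguous, unlike comparisons after scaling); exact
negations are not treated as duplicates. Covariates (e.g. sex, age, smoking)
are removed from the response only, by OLS on an intercept plus the
covariates, and the residuals are standardized; genotypes are standardized
but not residualized. MAF is computed from the analysis sample; MAF < 0.01
is "rare".

## Synthetic mini-exome generator

The generator emulates the structure of unrelated-sample exome benchmark
panels: n in the hundreds, thousands of SNPs partitioned into genes, LD only
within genes, many rare variants, a sparse causal set, and a phenotype with
heritability fixed by design.

- **Genotypes.** Per gene, a one-factor Gaussian copula: latent
  z = √ρ_g·shared + √(1−ρ_g)·noise, thresholded into {0,1,2} to match
  Binomial(2, maf) marginals. Genes are mutually independent. Columns that
  come out monomorphic (likely for maf ≈ 0.001 at n ≈ 700) are redrawn up to
  10 times, then error.
- **MAF spectrum.** A rare/common mixture, log-uniform on (0.001, 0.01) and
  (0.01, 0.5), with a configurable rare fraction.
- **Effect sizes.** |β| ∝ (2·maf·(1−maf))^(−γ/2) with γ = 0.5 and random
  sign — rarer causal variants carry larger per-allele effects, the pattern
  seen in exome benchmark truths. The per-SNP MAFs used for this rule are
  drawn once at design construction and stored on the design
  (`maf_values`), so the design alone determines every downstream draw.
- **Phenotype.** y = X_std β + ε with ε projected orthogonal to the genetic
  component in-sample and scaled so the realized Var(g)/Var(y) equals the
  design heritability exactly (an in-sample, not population, h²). Replicates
  share genotypes; the noise stream for replicate b is seeded from
  seed ⊕ b plus a stream tag that keeps it disjoint from the genotype
  stream. Optional generic covariates (off by default) add sex/age/smoking-
  like terms.
- **Presets.** Q1like (n=697, 39 causal SNPs in 9 genes, h²=0.44), Q2like
  (n=697, 72 causal in 13 genes, h²=0.29, rarer causal variants, a harder
  target), Q4like (no genetic signal), each with B=200 replicates by
  default and configurable d (2,000 for desk scale; 8,020 mirrors the
  full benchmark dimension). Gene sizes average ~20 SNPs (shrinking when d
  is too small to host the required causal genes) with within-gene ρ_g
  uniform on (0.05, 0.6).

What the generator does **not** emulate: real sequence data, between-gene
LD, population structure or relatedness, genotyping error and missingness,
non-Gaussian phenotype noise, covariate–genotype confounding. Passing tests
therefore demonstrate correctness of the algorithms and calibration under
the stated model, not performance on any particular real cohort.

## Evaluation machinery

TP-at-k counts causal SNPs among the top k of a ranking; curves average over
replicates (default grid k = 1..200). Model sizes are summarized by median
and IQR with linearly interpolated quartiles (type 7; the convention is
recorded in the output). Recovery frequency counts, per causal SNP, the
replicates in which it appears in the top K (default 100), rows ordered by
the first method column. The random baseline's expectation is
hypergeometric, k·|truth|/d. When preprocessing drops duplicated causal
columns, the truth set is reduced to the rankable unique columns before
evaluation. Ranking ties are broken by ascending SNP id, making every
ranking deterministic.

## Numerical choices and known limitations

- Sample-variance denominator n−1 everywhere (standardization, correlations,
  pooled t-score variance).
- The plug-in R² = r_YXR⁻¹r_XY is reported without bias correction and can
  exceed 1 when d ≫ n at small λ; it is a relative importance budget, not a
  calibrated variance-explained estimate.
- The lfdr fit needs a reasonable score count (d ≥ 50 recommended) and
  assumes the bulk of scores is null; with a majority of non-null scores the
  75th-percentile truncation contaminates the null fit and π₀ is
  overestimated.
- Model sizes from lfdr thresholding depend on the null-fitting heuristics
  (truncation point, Grenander estimator); other lfdr implementations will
  give similar but not identical counts.
- Problem sizes in the test suite and acceptance script (d up to 50,000 for
  the memory contract, d = 2,000 with B = 20 replicates for ranking
  recovery, d = 5,000 with 20 seeds for null calibration) were chosen as
  comfortable desk-scale settings that still separate the methods clearly.
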