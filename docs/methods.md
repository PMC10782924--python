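# Methods

## The problem

In a randomized pharmacogenomic (PGx) trial a patient's quantitative drug
response Y depends on treatment assignment T ∈ {0,1}, on genotype main
("prognostic") effects, and on genotype-by-treatment ("predictive") effects:

    Y = G β + (G ∘ T) α + ε,    ε ~ N(0, σ²),

where G is the n×m dosage matrix (standardized internally), β the per-SNP
prognostic effects and α the interaction effects.  A PGx polygenic score has
two components, PRS_G = Gβ̂ and PRS_GT = Gα̂, and prediction is assessed with

    E[Y] = b0 + b1·T + b2·PRS_G + b3·T×PRS_GT,

reporting R² (squared correlation of fitted with observed Y) and the
two-sided Wald test of b3 (the PRS-by-treatment interaction).  Methods that
produce only one component reuse PRS_G for the interaction term.

## The Bayesian sampler

`pgxprs.bayes` estimates (β_k, α_k) for K studies (populations) from
summary statistics alone.  Per SNP j and study k, b_jk = (β_jk, α_jk) has a
bivariate normal prior with covariance proportional to a 2×2 matrix M_j
(variances ψ_j, ξ_j, correlation ρ_j) that is **shared across studies** —
this is the cross-population coupling.  M_j carries an inverse-Wishart prior
W⁻¹(4v·diag(δ_j, λ_j), 2v+1), with δ_j ~ G(b1, φ), λ_j ~ G(b2, φ), giving a
hierarchical half-t (horseshoe-like) global-local shrinkage: φ sets the
global scale, ψ_j/ξ_j the local one.  σ_k² has a Jeffreys prior.

All four conditionals are conjugate (see the module docstring for the
formulas) and the model is Gibbs-sampled by LD block.  The likelihood enters
through the standardized marginal cross-products b̂_k = X_k'Y_k/N_k and the
block design second-moment matrix

    D_k = [[R*, r R*], [r R*, r R*]],   R* = (1−λ_R) R + λ_R I,

with R the reference-panel LD per block, r the treated fraction, and λ_R a
ridge (default 0.1) guarding against panel/cohort LD mismatch.  Cross-block
LD is assumed zero.

### Recovering cross-products from reported GWAS estimates

PGx GWAS rows come from per-SNP joint regressions of Y on (1, T, g, g·T),
not from simple marginal regressions.  On the standardized scale the joint
coefficients (β̂*, α̂*) relate to the cross-products through the per-SNP
second-moment matrix [[1, r], [r, r]]:

    b̂_G = β̂* + r·α̂*,     b̂_GT = r·(β̂* + α̂*),

with β̂* = z_G/√((1−r)n) and α̂* = z_GT/√(r(1−r)n) recovered from z-scores
(the joint coefficient variances are σ²/((1−r)N) and σ²/(r(1−r)N); the
residual σ is approximated by 1 on the standardized scale, the usual
summary-statistics approximation).  Feeding joint coefficients directly as
if they were marginals badly corrupts the interaction component — a causal
SNP with β > 0, α = 0 would be imputed α̂ ≈ −β — so this reconstruction is
load-bearing; it is verified against individual-level X'Y/n in the tests.
A single-arm disease GWAS estimate *is* a simple marginal, so b̂_G = z/√n
there.

### The Disease+PGx composite

`compose_disease_pgx` replaces the prognostic component of a PGx
summary-statistics set with the disease GWAS values (allele-aligned),
keeping the interaction component.  The two components then carry different
effective sample sizes; the scalar N generalizes to W = diag(n_G·1, n_GT·1)
applied symmetrically (Σ = σ²W^{-1/2}(D+Ω⁻¹)⁻¹W^{-1/2}, μ =
W^{-1/2}(D+Ω⁻¹)⁻¹W^{1/2}b̂), the σ² update uses n_GT (the PGx cohort defines
the response scale), and the M_j scale uses diag(n_G, n_GT) in place of N.
A `composite_n_mode="pgx_only"` switch offers the naive W = N_pgx·I for
sensitivity analysis.  The original PGx prognostic statistics are kept
alongside the substituted disease values so the interaction cross-product
can still be reconstructed (previous section).

### Numerical choices

* "M" in the σ² conditional's shape M + N/2 is read as m, the number of
  SNPs (the prior for the 2m coefficients contributes σ^(−2m)).
* φ is *not* part of Ω in the coefficient update; it enters only through
  the δ/λ Gamma rates.  This is the only placement that makes all four
  conditionals mutually consistent.
* ρ_j is clipped to |ρ| ≤ 0.999 and the σ² rate clamped below at 1e−8·N to
  avoid numerical degeneracy; 2×2 inverse-Wishart draws use a hand-vectorized
  Bartlett construction.
* Initialization: ψ=ξ=δ=λ=1, ρ=0, σ²=1, b=0.  Defaults: n_iter=1000,
  n_burnin=500, thin=1; replicate experiments use 300/150 (the posterior
  mean stabilizes within ~100 sweeps at the sizes used there).
* Per-population RNG streams are derived from (seed, population label), a
  shared stream drives the pooled M/δ/λ updates; fits are bit-reproducible
  and invariant to population input order.

### Tuning

φ is the consequential tuning parameter.  The grid spans {1e−4, 1e−2, 1,
1e2} (PRS-CS-style); v ∈ {2, 4, 8}, b1 = b2 = 0.5 by default.  Selection is
by 5-fold cross-validation in the target cohort (`cv_tune`, folds stratified
by arm, selection by mean out-of-fold R²) or on an external validation
cohort (`external_tune`).  In sparse architectures the choice matters: with
φ = 1 the null SNPs keep inflated local scales (the coefficient noise feeds
back into the M_j scale), while φ = 100 shrinks them properly — recovery
correlation roughly doubles.  The replicate experiments therefore tune φ
over the grid endpoints {1e−2, 1, 1e2} by external validation.

## Baselines

Clumping+thresholding: greedy retention by ascending p (ties by variant id),
removing within-block neighbors with r² above 0.1 (default); thresholds
{5e−8 … 1}; for PGx inputs the clumping p is min(p_G, p_GT) so
predictive-only signals survive.  CT-Meta applies C+T to per-SNP
inverse-variance fixed-effect meta-analyzed statistics against the *target*
population's panel.  The multi-ethnic blend PRS_0 = π·PRS_a + (1−π)·PRS_b
grid-searches π ∈ {0, 0.05, …, 1} by cross-validated R² (ties to the
smallest π).

## The disease-PRS recoverability bound

For treated subjects and the oracle disease score S_dis = Gβ,

    cor²(S_dis, Y) = h² · [β'R(β+α)]² / (β'Rβ · (β+α)'R(β+α)) ≤ h²,

with equality iff α ∝ β.  `disease_prs_r2_limit` evaluates this analytically
(block-wise quadratic forms); `proportionality_gap` returns 1 − cos² of the
angle between β and β+α in the R metric.  h² is defined as treated-arm
var(genetic)/var(Y), and the generator calibrates to the same definition, so
theory and simulation agree without conversion.  Control-arm and pooled
variants of the bound are out of scope.

## The synthetic-data generator

`pgxprs.simulate` emulates the full study design: per population, an
independent disease cohort (summary statistics only), a PGx base trial, a
target trial, an external validation trial, and a reference sample from
which the LD panel is estimated.

* **Genotypes** — latent-Gaussian AR(1) haplotypes per LD block (default
  ar1_rho = 0.9, block size 50): two independent latent vectors are
  thresholded at Φ⁻¹(MAF) and summed, giving Hardy-Weinberg dosages whose
  LD is the tetrachoric-induced correlation decaying with distance.  MAFs
  are uniform on (0.05, 0.5), drawn independently per population.  This
  replaces haplotype-resampling engines: the methods consume only LD
  structure, not haplotype realism — passing tests say nothing about
  fine-scale features of real LD (long-range LD, MAF-LD coupling,
  population-specific block boundaries).
* **Effects** — spike-and-slab: causal indicators Bernoulli(p_causal)
  (default 0.01); the "separated" mode splits one Bernoulli(p_causal) set
  into disjoint prognostic-only/predictive-only halves so the expected
  causal count matches the correlated mode.  Per causal SNP the vector
  (μ..., γ..., β..., α...) over (cohort, effect-type, population) is
  MVN(0, Σ_C(ρ_C) ⊗ Σ_E(ρ_E) ⊗ Σ_P(ρ_P)).  Defaults ρ_E = 0.5 (moderate
  prognostic/predictive coupling), ρ_P = 0.5 (the main cross-population
  condition), ρ_C = 0.8 (base and target measure the same drug response, so
  high but imperfect transfer).  Unequal-scale modes rescale the dominated
  effect type's variance by 1/9.
* **Phenotypes** — noise variance solved from the realized treated-arm
  genetic variance so var(genetic)/var(Y) among treated equals h² (default
  0.3); Y is returned standardized and each cohort's truth vectors are
  rescaled accordingly.  The disease phenotype is Y = Gμ + ε at the same
  heritability, sharing the base-cohort prognostic effects μ — the package
  has no separate disease-vs-drug genetic-correlation dial, so composite
  comparisons here bound the strategy's best case.
* **Summary statistics** — per-SNP OLS on (1, T, g, g·T) (vectorized normal
  equations; statsmodels is the cross-check in the tests), t-based p-values;
  SNPs without dosage variation in both arms yield null rows with a warning.

## Experiment scales

The study-level experiments (`pgxprs.experiments`, also driven by
`scripts/acceptance.py`) run at desk scale, chosen so a full sweep fits in
minutes on one CPU while preserving the per-SNP signal regime of the
reference conditions:

* Generator calibration and the bound equality case: n = 50 000, m = 1000,
  5 seeds / 1 cohort.
* Strategy comparison: m = 1000, P(causal) = 0.01, disease N = 50 000, PGx
  N ∈ {1000, 10 000}, target n = 1000, 6 replicates, chains 300/150, φ tuned
  over {1e−2, 1, 1e2} by external validation (n = 500).
* Cross-population comparison: m = 200 with P(causal) = 0.05 (preserving the
  ~10 causal SNPs of m = 1000 × 0.01), EUR/EAS sizes one tenth of the
  reference design (disease 5000/1000, PGx 500/100, target 500/100),
  ρ_P = 0.5, 30 replicates.  The joint fit serves a target through the
  π-grid blend of its two per-population scores (how a multi-population
  posterior is reduced to one score is a design choice; the blend is the
  standard one, and with the small population's PGx GWAS at n = 100 its
  own posterior alone is almost fully shrunk).
* Interaction-test calibration: 500 replicates, m = 50, base n = 1000,
  target n = 400, single-component PRS (see limitation below).
* Parameter recovery: m = 500, N = 5000, P(causal) = 0.01, 20 replicates.

Replicate counts this small leave visible Monte-Carlo error in the absolute
R² values; the directional orderings are the stable quantities.

## Known limitations

* **Evaluation-model miscalibration with two distinct score components.**
  The evaluation model omits the PRS_GT *main* effect.  When PRS_GT ≠ PRS_G
  and residual prognostic signal (true Gβ not captured by PRS_G) correlates
  with PRS_GT within a replicate, part of that main effect loads on the
  T×PRS_GT term and the interaction test over-rejects under the null (we
  observe ~0.12 at nominal 0.05 in small cohorts).  With a single component
  (PRS_GT = PRS_G, the disease-PRS convention) the main effect is in the
  model and the test is calibrated; the calibration experiment uses that
  form.  Adding the PRS_GT main effect to the model would fix this but
  changes the published evaluation convention, so it is not the default.
* The composite strategy's summary statistics mix two phenotype scales;
  the z-score route makes both unit-free, but residual-variance differences
  between the two GWAS are absorbed into the approximation σ ≈ 1.
* The generator shares μ between the disease GWAS and the PGx base cohort;
  real disease/drug-response pairs have genetic correlation below 1, which
  would shrink the composite's advantage.
* Binary or survival endpoints, functional-annotation priors, PLINK binary
  input, and liftover are out of scope.
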