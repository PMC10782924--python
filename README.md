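# pgxprs

Polygenic scores for drug response, built from pharmacogenomic (PGx) GWAS
summary statistics.

## The problem

Disease GWAS measure genotype main effects; drug response in a randomized
trial additionally depends on genotype-by-treatment interactions.  For
treated subjects with drug-response heritability h², a PRS built from a
disease GWAS is provably capped at

    cor²(S_dis, Y) ≤ h²,

with equality only when every causal variant's interaction (predictive)
effect α_j is proportional to its main (prognostic) effect β_j.  Capturing
the missing variance requires modeling both effect types from PGx trial
data — which is scarce, small, and mostly European.  `pgxprs` is for
statistical geneticists and trial biostatisticians who need to build,
combine, and evaluate such two-component scores.

## What it provides

* **A Bayesian global–local shrinkage sampler** for the model
  Y_k = G_k β_k + (G_k∘T_k) α_k + ε_k across K studies or populations,
  fit by Gibbs sampling from summary statistics and a block LD panel.  Per
  SNP, (β_jk, α_jk) share a 2×2 covariance M_j across populations
  (inverse-Wishart hierarchy, global shrinkage φ), so a small non-European
  study borrows strength from a large European one.  K = 1 is the
  single-population special case.
* **The Disease+PGx composite strategy**: replace the prognostic component
  of the PGx summary statistics with a large disease GWAS, keep the
  interaction component, and carry per-component sample sizes through the
  posterior.
* **Baselines**: LD clumping + p-value thresholding (PGx and disease
  variants), per-SNP inverse-variance meta-analysis (CT-Meta), and the
  grid-weighted two-population PRS blend.
* **The recoverability bound** cor²(S_dis, Y) ≤ h² with its equality
  diagnostic (proportionality gap).
* **A synthetic-trial generator**: LD-blocked genotypes, spike-and-slab
  effects correlated across effect type (ρE), population (ρP) and cohort
  (ρC), heritability-calibrated phenotypes, and the per-SNP regressions
  producing summary statistics.
* **Evaluation**: two-component scoring, the model
  E[Y] = b0 + b1T + b2·PRS_G + b3·T×PRS_GT with R² and the interaction
  Wald test, stratified cross-validation and external-validation tuning,
  and PRS-based patient stratification.

File formats are plain TSV (summary statistics, LD manifests + matrices,
phenotype/dosage tables) plus VCF genotype input; see
`pgxprs/io.py` for the column dialects.

## Worked example

```python
from pgxprs import (SimScenario, build_scenario, PriorHyper, MCMCConfig,
                    fit_prs_pgx_bayes, posterior_to_weights, compute_prs,
                    evaluate_prediction)

scn = SimScenario(m=200, block_size=50, p_causal=0.05, h2=0.3,
                  n_disease=2, n_pgx_base=3000, n_target=1000,
                  n_external_valid=500, n_reference=1000, seed=3)
bundle = build_scenario(scn)
pop = bundle.populations["EUR"]

post = fit_prs_pgx_bayes(pop.pgx_sumstats, pop.ld_panel,
                         PriorHyper(phi=100.0, v=4.0),
                         MCMCConfig(n_iter=500, n_burnin=250, seed=1))
prs = compute_prs(pop.target, posterior_to_weights(post, bundle.variants))
res = evaluate_prediction(pop.target, prs)
print(f"target R^2 = {res.r2:.3f}, interaction p = {res.p_interaction:.2e}")
```

prints

```
target R^2 = 0.129, interaction p = 2.49e-12
```

— the fitted evaluation model explains ~13% of target-cohort response
variance (the treated-arm heritability here is 0.3, and the base trial has
only 3000 subjects), and the predictive component significantly modifies
the treatment effect.  The scripts in `examples/` walk through each
capability: scenario simulation, the single-population fit, the Disease+PGx
composite, cross-population fitting, C+T with CV tuning, and the
heritability bound.  A thin CLI (`pgxprs simulate|fit|predict|evaluate|tune|blend|bound`)
wraps the same functions for shell use.

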