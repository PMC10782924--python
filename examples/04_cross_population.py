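"""Cross-population shrinkage: borrow strength from a large population.

Fits the K=2 sampler on EUR (large) and EAS (small) PGx summary statistics
with shared per-SNP covariances M_j, and compares prediction in the EAS
target against the EAS-only fit.
"""

from pgxprs import (MCMCConfig, PriorHyper, SimScenario, build_scenario,
                    compute_prs, evaluate_prediction, fit_prs_pgx_bayes,
                    fit_prs_pgx_bayesx, posterior_to_weights)

scn = SimScenario(m=200, block_size=50, p_causal=0.05, h2=0.3, rho_P=0.5,
                  populations=("EUR", "EAS"),
                  n_disease=2, n_pgx_base={"EUR": 2000, "EAS": 400},
                  n_target={"EUR": 1000, "EAS": 400},
                  n_external_valid=300, n_reference=1000, seed=9)
bundle = build_scenario(scn)
eur, eas = bundle.populations["EUR"], bundle.populations["EAS"]
mcmc = MCMCConfig(n_iter=500, n_burnin=250, seed=4)
hyper = PriorHyper(phi=100.0, v=4.0)

posts = fit_prs_pgx_bayesx([eur.pgx_sumstats, eas.pgx_sumstats],
                           [eur.ld_panel, eas.ld_panel], hyper, mcmc)
joint_eas = next(p for p in posts if p.population == "EAS")
solo_eas = fit_prs_pgx_bayes(eas.pgx_sumstats, eas.ld_panel, hyper, mcmc)

for label, post in (("EUR+EAS joint", joint_eas), ("EAS alone", solo_eas)):
    prs = compute_prs(eas.target, posterior_to_weights(post, bundle.variants))
    res = evaluate_prediction(eas.target, prs)
    print(f"{label:14s} EAS-target R^2 = {res.r2:.3f}")
# Sharing the local shrinkage across populations lets the small EAS study
# inherit which SNPs matter from the larger EUR study.
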