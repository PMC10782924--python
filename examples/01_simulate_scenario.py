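"""Generate a synthetic pharmacogenomic trial scenario and inspect it.

Builds a single-population scenario (disease GWAS, PGx base trial, target
trial, validation trial, LD reference) and prints what the generator made.
"""

import numpy as np

from pgxprs import SimScenario, build_scenario

scn = SimScenario(m=200, block_size=50, p_causal=0.05, h2=0.3,
                  n_disease=10_000, n_pgx_base=2000, n_target=1000,
                  n_external_valid=500, n_reference=1000, seed=7)
bundle = build_scenario(scn)
pop = bundle.populations["EUR"]

n_causal = int(bundle.effects.causal.sum())
print(f"SNPs: {scn.m} in {scn.n_blocks} LD blocks; causal: {n_causal}")
print(f"disease GWAS: n={pop.disease_sumstats.n}, "
      f"min p = {pop.disease_sumstats.p.min():.2e}")
print(f"PGx base trial: n={pop.pgx_base.n}, treated fraction "
      f"{pop.pgx_base.T.mean():.3f}")
print(f"target trial: n={pop.target.n}")

# verify the generator hit its treated-arm heritability target
t = pop.target.T == 1
G = pop.target.G
Gs = (G - G.mean(0)) / np.where(G.std(0) == 0, 1, G.std(0))
genetic = Gs @ pop.truth["beta_target_scaled"] \
    + pop.target.T * (Gs @ pop.truth["alpha_target_scaled"])
h2_real = np.var(genetic[t]) / np.var(pop.target.Y[t])
print(f"realized treated-arm heritability: {h2_real:.3f} (target {scn.h2})")
# The last number is the fraction of drug-response variance among treated
# subjects explained by the true prognostic + predictive effects.
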