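"""Synthetic pharmacogenomic trial data with LD, shared effects, and GWAS.

Everything the estimation methods consume can be generated here: LD-blocked
genotypes, spike-and-slab effect sizes correlated across effect type
(prognostic vs predictive, ρE), population (ρP) and cohort (base vs target,
ρC), heritability-calibrated quantitative responses, and the per-SNP marginal
regressions that turn cohorts into summary statistics.

Genotypes come from a latent-Gaussian AR(1) haplotype model: within each LD
block two independent latent Gaussian vectors with corr(z_i, z_j) =
ar1_rho^|i-j| are thresholded at the allele frequency, and the two resulting
haplotypes summed to a Hardy-Weinberg dosage in {0,1,2}.  Adjacent-dosage
correlation is then the tetrachoric-induced value, decaying with distance —
the LD feature the summary-statistics methods actually use.

Effect sizes: per causal SNP the vector v = (μ1..μK, γ1..γK, β1..βK, α1..αK)
(base prognostic, base predictive, target prognostic, target predictive — one
entry per population) is multivariate normal with covariance
Σ = Σ_C(ρC) ⊗ Σ_E(ρE) ⊗ Σ_P(ρP), each factor a 2×2 (or K×K) correlation
matrix.  Phenotypes are Y = Gβ + (G∘T)α + ε with the noise variance solved so
the realized treated-arm genetic variance fraction equals the target h².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import (DiseaseSummaryStats, LDBlock, LDBlockPanel, PGxCohort,
                 PGxSummaryStats, ValidationError, VariantKey)

__all__ = [
    "SimScenario", "ScenarioBundle", "PopulationData", "EffectDraw",
    "simulate_ld_genotypes", "draw_effect_sizes", "simulate_pgx_cohort",
    "simulate_disease_cohort", "compute_pgx_sumstats",
    "compute_disease_sumstats", "estimate_ld_panel", "build_scenario",
    "default_variants",
]


def _as_pop_dict(value, populations):
    if isinstance(value, dict):
        return {p: int(value[p]) for p in populations}
    return {p: int(value) for p in populations}


@dataclass
class SimScenario:
    """Generative configuration for a full experiment.

    Defaults reflect the reference study conditions: heritability 0.3 in the
    treated arm, correlated same-scale prognostic/predictive effects,
    cross-population effect correlation 0.5, disease GWAS of 50 000, PGx base
    GWAS of 5000, 1:1 randomization.  ``sizes`` values may be ints (applied
    to every population) or per-population dicts.
    """

    m: int = 1000
    block_size: int = 50
    ar1_rho: float = 0.9
    maf_range: tuple = (0.05, 0.5)
    p_causal: float = 0.01
    effect_mode: str = "correlated"          # or "separated"
    scale_mode: str = "same"                 # prognostic_dominant / predictive_dominant
    dominance_ratio: float = 9.0             # variance ratio for dominated modes
    rho_E: float = 0.5
    rho_P: float = 0.5
    rho_C: float = 0.8
    h2: float = 0.3
    h2_disease: float | None = None          # defaults to h2
    populations: tuple = ("EUR",)
    n_disease: int | dict = 50_000
    n_pgx_base: int | dict = 5_000
    n_target: int | dict = 5_000
    n_external_valid: int | dict = 1_000
    n_reference: int | dict = 2_000
    treated_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_causal <= 1.0):
            raise ValidationError("p_causal must lie in [0, 1]")
        for name in ("rho_E", "rho_P", "rho_C"):
            if abs(getattr(self, name)) >= 1.0:
                raise ValidationError(f"|{name}| must be < 1")
        if not (0.0 <= self.h2 < 1.0):
            raise ValidationError("h2 must lie in [0, 1)")
        if self.effect_mode not in ("correlated", "separated"):
            raise ValidationError(f"unknown effect_mode {self.effect_mode!r}")
        if self.scale_mode not in ("same", "prognostic_dominant", "predictive_dominant"):
            raise ValidationError(f"unknown scale_mode {self.scale_mode!r}")
        if not (0.0 < self.treated_fraction < 1.0):
            raise ValidationError("treated_fraction must be in (0, 1)")
        if self.m % self.block_size != 0:
            raise ValidationError("m must be a multiple of block_size")
        self.populations = tuple(self.populations)

    @property
    def n_blocks(self) -> int:
        return self.m // self.block_size

    def sizes(self, which: str) -> dict:
        return _as_pop_dict(getattr(self, "n_" + which), self.populations)


@dataclass
class EffectDraw:
    """True effect vectors per population, on the generator scale."""

    causal: np.ndarray                      # bool mask (m,)
    causal_prognostic: np.ndarray           # masks used in "separated" mode
    causal_predictive: np.ndarray
    base_prognostic: dict                   # population -> (m,) μ
    base_predictive: dict                   # population -> (m,) γ
    target_prognostic: dict                 # population -> (m,) β
    target_predictive: dict                 # population -> (m,) α


@dataclass
class PopulationData:
    population: str
    mafs: np.ndarray
    disease_sumstats: DiseaseSummaryStats | None
    pgx_base: PGxCohort | None
    pgx_sumstats: PGxSummaryStats | None
    target: PGxCohort | None
    validation: PGxCohort | None
    ld_panel: LDBlockPanel
    truth: dict = field(default_factory=dict)


@dataclass
class ScenarioBundle:
    scenario: SimScenario
    variants: list
    effects: EffectDraw
    populations: dict


def default_variants(m: int) -> list[VariantKey]:
    """Synthetic non-ambiguous SNP manifest rs1..rsm on chromosome 1."""
    return [VariantKey(f"rs{j+1}", "1", 1000 * (j + 1), "A", "G") for j in range(m)]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def draw_mafs(scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    lo, hi = scenario.maf_range
    return rng.uniform(lo, hi, size=scenario.m)


def simulate_ld_genotypes(n: int, scenario: SimScenario,
                          rng: np.random.Generator,
                          mafs: np.ndarray | None = None):
    """n×m Hardy-Weinberg dosages with AR(1)-blocked LD.

    Returns ``(G, mafs)``; pass ``mafs`` to share allele frequencies across
    cohorts of the same population.
    """
    if mafs is None:
        mafs = draw_mafs(scenario, rng)
    m_b = scenario.block_size
    idx = np.arange(m_b)
    C = scenario.ar1_rho ** np.abs(idx[:, None] - idx[None, :])
    # float32 latents: thresholding only needs ~7 significant digits
    L = np.linalg.cholesky(C + 1e-12 * np.eye(m_b)).astype(np.float32)
    G = np.empty((n, scenario.m), dtype=np.float64)
    thresh = stats.norm.ppf(mafs).astype(np.float32)
    for b in range(scenario.n_blocks):
        sl = slice(b * m_b, (b + 1) * m_b)
        hap1 = rng.standard_normal((n, m_b), dtype=np.float32) @ L.T < thresh[sl]
        hap2 = rng.standard_normal((n, m_b), dtype=np.float32) @ L.T < thresh[sl]
        G[:, sl] = hap1.astype(np.uint8) + hap2.astype(np.uint8)
    return G, mafs


def estimate_ld_panel(G: np.ndarray, variants, block_size: int,
                      population: str = "POP1") -> LDBlockPanel:
    """Empirical per-block correlation matrices from a reference sample."""
    m = G.shape[1]
    blocks = []
    for start in range(0, m, block_size):
        sl = slice(start, min(start + block_size, m))
        sub = G[:, sl]
        R = np.corrcoef(sub, rowvar=False)
        R = np.atleast_2d(R)
        R[~np.isfinite(R)] = 0.0       # monomorphic-in-sample columns
        np.fill_diagonal(R, 1.0)
        R = (R + R.T) / 2.0
        blocks.append(LDBlock([v.id for v in variants[sl]], R))
    return LDBlockPanel(population, blocks, list(variants))


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def _factor(rho: float, k: int = 2) -> np.ndarray:
    F = np.full((k, k), rho, dtype=float)
    np.fill_diagonal(F, 1.0)
    return F


def _effect_cov(scenario: SimScenario) -> np.ndarray:
    """Σ = Σ_C(ρC) ⊗ Σ_E(ρE) ⊗ Σ_P(ρP), index order (cohort, effect, pop)."""
    K = len(scenario.populations)
    sigma = np.kron(_factor(scenario.rho_C),
                    np.kron(_factor(scenario.rho_E), _factor(scenario.rho_P, K)))
    # variance rescaling for unequal prognostic/predictive scales
    sd = np.ones(4 * K)
    if scenario.scale_mode == "prognostic_dominant":
        pred = np.r_[K:2 * K, 3 * K:4 * K]
        sd[pred] = 1.0 / np.sqrt(scenario.dominance_ratio)
    elif scenario.scale_mode == "predictive_dominant":
        prog = np.r_[0:K, 2 * K:3 * K]
        sd[prog] = 1.0 / np.sqrt(scenario.dominance_ratio)
    return sigma * np.outer(sd, sd)


def draw_effect_sizes(scenario: SimScenario, rng: np.random.Generator) -> EffectDraw:
    """Spike-and-slab effects with the cross-population/cohort/type covariance.

    "correlated" mode: one Bernoulli(p_causal) indicator per SNP governs all
    components.  "separated" mode: disjoint prognostic-only and
    predictive-only causal sets, each Bernoulli(p_causal/2), so the expected
    total causal count matches the correlated mode.
    """
    K = len(scenario.populations)
    m = scenario.m
    u = rng.uniform(size=m)
    if scenario.effect_mode == "correlated":
        causal = u < scenario.p_causal
        causal_prog = causal
        causal_pred = causal
    else:
        causal_prog = u < scenario.p_causal / 2.0
        causal_pred = (u >= scenario.p_causal / 2.0) & (u < scenario.p_causal)
        causal = causal_prog | causal_pred

    sigma = _effect_cov(scenario)
    Ls = np.linalg.cholesky(sigma + 1e-12 * np.eye(4 * K))
    V = np.zeros((m, 4 * K))
    n_c = int(causal.sum())
    if n_c:
        V[causal] = rng.standard_normal((n_c, 4 * K)) @ Ls.T
    if scenario.effect_mode == "separated":
        prog_cols = np.r_[0:K, 2 * K:3 * K]
        pred_cols = np.r_[K:2 * K, 3 * K:4 * K]
        V[np.ix_(~causal_prog, prog_cols)] = 0.0
        V[np.ix_(~causal_pred, pred_cols)] = 0.0

    pops = scenario.populations
    return EffectDraw(
        causal=causal, causal_prognostic=causal_prog, causal_predictive=causal_pred,
        base_prognostic={p: V[:, 0 * K + i] for i, p in enumerate(pops)},
        base_predictive={p: V[:, 1 * K + i] for i, p in enumerate(pops)},
        target_prognostic={p: V[:, 2 * K + i] for i, p in enumerate(pops)},
        target_predictive={p: V[:, 3 * K + i] for i, p in enumerate(pops)},
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _standardize_columns(G: np.ndarray) -> np.ndarray:
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    return (G - mu) / sd


def simulate_pgx_cohort(G: np.ndarray, beta: np.ndarray, alpha: np.ndarray,
                        scenario: SimScenario, rng: np.random.Generator,
                        variants=None, population: str = "POP1"):
    """Two-arm trial responses calibrated to the treated-arm heritability.

    Y = Gs·β + (Gs∘T)·α + ε with Gs the column-standardized dosages and the
    noise variance solved from the realized treated-arm genetic variance so
    var(genetic)/var(Y) among the treated equals ``scenario.h2``.  Y is
    returned standardized; the second return value is the scale c = sd(Y)
    that maps generator-scale effects to the returned phenotype scale (β/c).

    Returns ``(PGxCohort, y_scale)``.
    """
    n = G.shape[0]
    if variants is None:
        variants = default_variants(G.shape[1])
    T = (rng.uniform(size=n) < scenario.treated_fraction).astype(float)
    Gs = _standardize_columns(G)
    genetic = Gs @ beta + T * (Gs @ alpha)
    treated = T == 1
    var_g = float(np.var(genetic[treated])) if treated.any() else 0.0
    h2 = scenario.h2
    if h2 > 0 and var_g == 0:
        raise ValidationError("zero genetic variance with h2 > 0: no causal effects")
    sigma2 = var_g * (1.0 - h2) / h2 if h2 > 0 else 1.0
    Y = genetic + np.sqrt(sigma2) * rng.standard_normal(n)
    c = float(np.std(Y))
    if c == 0:
        c = 1.0
    cohort = PGxCohort(population=population, Y=Y / c, T=T, G=G,
                       variants=list(variants))
    return cohort, c


def simulate_disease_cohort(G: np.ndarray, beta_disease: np.ndarray,
                            h2_disease: float, rng: np.random.Generator):
    """Single-arm disease phenotype Y = Gs·β + ε calibrated to h2_disease.

    Returns ``(Y, y_scale)`` with Y standardized.
    """
    Gs = _standardize_columns(G)
    genetic = Gs @ beta_disease
    var_g = float(np.var(genetic))
    if h2_disease > 0 and var_g == 0:
        raise ValidationError("zero genetic variance with h2 > 0")
    sigma2 = var_g * (1.0 - h2_disease) / h2_disease if h2_disease > 0 else 1.0
    Y = genetic + np.sqrt(sigma2) * rng.standard_normal(G.shape[0])
    c = float(np.std(Y))
    if c == 0:
        c = 1.0
    return Y / c, c


# ---------------------------------------------------------------------------
# marginal summary statistics
# ---------------------------------------------------------------------------

def compute_pgx_sumstats(cohort: PGxCohort,
                         treated_fraction: float | None = None) -> PGxSummaryStats:
    """Per-SNP OLS of Y on (1, T, g, g·T): marginal PGx summary statistics.

    Monomorphic SNPs get beta 0, SE 1, p 1 (with a warning) so row alignment
    with the cohort manifest is preserved.
    """
    Y, T, G = cohort.Y, cohort.T, cohort.G
    n, m = G.shape
    if len(np.unique(T)) < 2:
        raise ValidationError("both arms required for PGx summary statistics")
    GT = G * T[:, None]
    ones = np.ones(n)
    # per-SNP 4x4 normal equations, assembled vectorized
    s_g = G.sum(axis=0)
    s_gg = (G * G).sum(axis=0)
    s_gt = GT.sum(axis=0)           # Σ g·T  (= Σ over treated of g)
    s_ggt = (G * GT).sum(axis=0)    # Σ g²·T
    s_T = T.sum()
    A = np.empty((m, 4, 4))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = s_T
    A[:, 0, 2] = A[:, 2, 0] = s_g
    A[:, 0, 3] = A[:, 3, 0] = s_gt
    A[:, 1, 1] = s_T
    A[:, 1, 2] = A[:, 2, 1] = s_gt
    A[:, 1, 3] = A[:, 3, 1] = s_gt
    A[:, 2, 2] = s_gg
    A[:, 2, 3] = A[:, 3, 2] = s_ggt
    A[:, 3, 3] = s_ggt
    c = np.empty((m, 4))
    c[:, 0] = Y.sum()
    c[:, 1] = float(Y @ T)
    c[:, 2] = Y @ G
    c[:, 3] = Y @ GT
    # a SNP is usable only if its dosage varies within both arms; otherwise
    # the (1, T, g, g·T) design is rank-deficient
    treated = T == 1
    mono = (G.std(axis=0) == 0) | (G[treated].std(axis=0) == 0) \
        | (G[~treated].std(axis=0) == 0)
    ok = ~mono
    coef = np.zeros((m, 4))
    se = np.ones((m, 2))
    if ok.any():
        try:
            coef_ok = np.linalg.solve(A[ok], c[ok][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            coef_ok = (np.linalg.pinv(A[ok]) @ c[ok][:, :, None])[:, :, 0]
        coef[ok] = coef_ok
        rss = float(Y @ Y) - np.einsum("ij,ij->i", coef_ok, c[ok])
        dof = n - 4
        s2 = np.maximum(rss, 0.0) / dof
        try:
            Ainv = np.linalg.inv(A[ok])
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A[ok])
        se_g = np.sqrt(np.maximum(s2 * Ainv[:, 2, 2], np.finfo(float).tiny))
        se_gt = np.sqrt(np.maximum(s2 * Ainv[:, 3, 3], np.finfo(float).tiny))
        se[ok, 0] = se_g
        se[ok, 1] = se_gt
    if mono.any():
        import warnings
        warnings.warn(f"{int(mono.sum())} monomorphic SNP(s): null summary rows")
    t_g = coef[:, 2] / se[:, 0]
    t_gt = coef[:, 3] / se[:, 1]
    dof = n - 4
    p_g = np.clip(2.0 * stats.t.sf(np.abs(t_g), dof), np.finfo(float).tiny, 1.0)
    p_gt = np.clip(2.0 * stats.t.sf(np.abs(t_gt), dof), np.finfo(float).tiny, 1.0)
    p_g[mono] = 1.0
    p_gt[mono] = 1.0
    eaf = G.mean(axis=0) / 2.0
    r = treated_fraction if treated_fraction is not None else float(T.mean())
    r = min(max(r, 1e-6), 1 - 1e-6)
    return PGxSummaryStats(
        population=cohort.population, variants=list(cohort.variants),
        beta_G=coef[:, 2], se_G=se[:, 0], p_G=p_g,
        beta_GT=coef[:, 3], se_GT=se[:, 1], p_GT=p_gt,
        n=n, treated_fraction=r, eaf=np.clip(eaf, 1e-6, 1 - 1e-6),
    )


def compute_disease_sumstats(Y: np.ndarray, G: np.ndarray,
                             variants=None) -> DiseaseSummaryStats:
    """Per-SNP simple regression of Y on each dosage column."""
    n, m = G.shape
    if variants is None:
        variants = default_variants(m)
    gc = G - G.mean(axis=0)
    yc = Y - Y.mean()
    sgg = (gc * gc).sum(axis=0)
    mono = sgg == 0
    sgg_safe = np.where(mono, 1.0, sgg)
    beta = (gc.T @ yc) / sgg_safe
    rss = float(yc @ yc) - beta ** 2 * sgg_safe
    dof = n - 2
    se = np.sqrt(np.maximum(rss, 0.0) / dof / sgg_safe)
    se = np.maximum(se, np.finfo(float).tiny)
    tstat = beta / se
    p = np.clip(2.0 * stats.t.sf(np.abs(tstat), dof), np.finfo(float).tiny, 1.0)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, 1.0, se)
    p = np.where(mono, 1.0, p)
    if mono.any():
        import warnings
        warnings.warn(f"{int(mono.sum())} monomorphic SNP(s): null summary rows")
    eaf = np.clip(G.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    return DiseaseSummaryStats(variants=list(variants), beta=beta, se=se, p=p,
                               n=n, eaf=eaf)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def build_scenario(scenario: SimScenario) -> ScenarioBundle:
    """Generate the complete base/target/validation/reference structure.

    Per population: an independent disease cohort (summary statistics only),
    PGx base cohort with summary statistics, target cohort, external
    validation cohort, and an LD panel estimated from a held-out reference
    sample.  Base cohorts carry the base effects (μ, γ); target and
    validation cohorts carry the target effects (β, α), correlated with the
    base effects through ρC.  Deterministic for a fixed ``scenario.seed``.
    """
    root = np.random.SeedSequence([int(scenario.seed) % (2 ** 31), 0xD06E])
    rng_effects = np.random.default_rng(root.spawn(1)[0])
    effects = draw_effect_sizes(scenario, rng_effects)
    variants = default_variants(scenario.m)
    h2_dis = scenario.h2_disease if scenario.h2_disease is not None else scenario.h2

    pops = {}
    for pi, pop in enumerate(scenario.populations):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(scenario.seed) % (2 ** 31), 0xD06E, pi + 1]))
        mafs = draw_mafs(scenario, rng)
        mu = effects.base_prognostic[pop]
        gamma = effects.base_predictive[pop]
        beta = effects.target_prognostic[pop]
        alpha = effects.target_predictive[pop]

        # component sizes below 10 mean "not part of this scenario"
        disease_ss, c_dis = None, float("nan")
        n_dis = scenario.sizes("disease")[pop]
        if n_dis >= 10:
            G_dis, _ = simulate_ld_genotypes(n_dis, scenario, rng, mafs)
            Y_dis, c_dis = simulate_disease_cohort(G_dis, mu, h2_dis, rng)
            disease_ss = compute_disease_sumstats(Y_dis, G_dis, variants)
            del G_dis, Y_dis

        base, pgx_ss, c_base = None, None, float("nan")
        n_base = scenario.sizes("pgx_base")[pop]
        if n_base >= 10:
            G_base, _ = simulate_ld_genotypes(n_base, scenario, rng, mafs)
            base, c_base = simulate_pgx_cohort(G_base, mu, gamma, scenario, rng,
                                               variants, pop)
            pgx_ss = compute_pgx_sumstats(base, scenario.treated_fraction)

        target, c_tgt = None, float("nan")
        n_tgt = scenario.sizes("target")[pop]
        if n_tgt >= 10:
            G_tgt, _ = simulate_ld_genotypes(n_tgt, scenario, rng, mafs)
            target, c_tgt = simulate_pgx_cohort(G_tgt, beta, alpha, scenario, rng,
                                                variants, pop)

        valid, c_val = None, float("nan")
        n_val = scenario.sizes("external_valid")[pop]
        if n_val >= 10:
            G_val, _ = simulate_ld_genotypes(n_val, scenario, rng, mafs)
            valid, c_val = simulate_pgx_cohort(G_val, beta, alpha, scenario, rng,
                                               variants, pop)

        n_ref = scenario.sizes("reference")[pop]
        G_ref, _ = simulate_ld_genotypes(n_ref, scenario, rng, mafs)
        panel = estimate_ld_panel(G_ref, variants, scenario.block_size, pop)
        del G_ref

        pops[pop] = PopulationData(
            population=pop, mafs=mafs,
            disease_sumstats=disease_ss,
            pgx_base=base, pgx_sumstats=pgx_ss,
            target=target, validation=valid, ld_panel=panel,
            truth={
                "mu": mu, "gamma": gamma, "beta": beta, "alpha": alpha,
                "y_scale_disease": c_dis, "y_scale_base": c_base,
                "y_scale_target": c_tgt, "y_scale_validation": c_val,
                "beta_target_scaled": beta / c_tgt if target is not None else None,
                "alpha_target_scaled": alpha / c_tgt if target is not None else None,
            },
        )
    return ScenarioBundle(scenario=scenario, variants=variants,
                          effects=effects, populations=pops)
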