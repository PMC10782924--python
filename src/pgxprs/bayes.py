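"""Bayesian global-local shrinkage of prognostic and predictive SNP effects.

The model: in each of K studies (populations) the drug response follows

    Y_k = G_k β_k + (G_k ∘ T_k) α_k + ε_k,      ε_k ~ N(0, σ_k²),

with per-SNP coefficient pairs b_jk = (β_jk, α_jk) drawn from a bivariate
normal whose 2×2 covariance M_j (entries ψ_j, ξ_j, correlation ρ_j) is shared
across studies.  M_j carries a hierarchical half-t prior built from an
inverse-Wishart with Gamma-distributed scales δ_j, λ_j; the global parameter
φ enters the Gamma rates and controls the overall degree of shrinkage, while
ψ_j, ξ_j set the marker-specific degree.  σ_k² has a Jeffreys prior.

Given marginal summary statistics b̂_k on the standardized scale and the
block design matrix D_k (:mod:`pgxprs.ld`), all four full conditionals are
conjugate and the model is fit by Gibbs sampling, block by LD block:

  1. b_k | ·  ~ MVN(μ_k, Σ_k),  Σ_k = (σ_k²/N_k)(D_k + Ω⁻¹)⁻¹,
                                μ_k = (N_k/σ_k²) Σ_k b̂_k
  2. σ_k² | · ~ iG(m + N_k/2, (N_k/2)[1 − 2 b̂_k'b_k + b_k'(D_k + Ω⁻¹)b_k])
  3. M_j | ·  ~ W⁻¹(B_j + A_j, 2v + K + 1),
                A_j = Σ_k (N_k/σ_k²) b_jk b_jk',  B_j = 4v diag(δ_j, λ_j)
  4. δ_j | ·  ~ G(v + b1 + 1/2, φ + 2v/(ψ_j(1−ρ_j²)))  (λ_j analogous with ξ_j)

where Ω = [[Ψ, P], [P, Ξ]] collects the M_j.  K = 1 recovers the
single-population sampler; the "Disease+PGx" composite replaces the prognostic
component of the PGx summary statistics with a disease GWAS and generalizes
the scalar N_k to per-coordinate weights W = diag(n_G·1, n_GT·1), applied
symmetrically (Σ = σ² W^{-1/2}(D+Ω⁻¹)⁻¹W^{-1/2}, μ = W^{-1/2}(D+Ω⁻¹)⁻¹W^{1/2} b̂).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky as _sp_cholesky, solve_triangular

from .io import DiseaseSummaryStats, LDBlockPanel, PGxSummaryStats, ValidationError
from .ld import DesignCorrelation, build_design_correlation, standardize_marginal

__all__ = [
    "PriorHyper", "MCMCConfig", "EffectPosterior",
    "sample_coefficients_block", "sample_residual_variance",
    "sample_local_covariance", "sample_local_scales",
    "fit_prs_pgx_bayesx", "fit_prs_pgx_bayes", "compose_disease_pgx",
]

_RHO_CLIP = 0.999
_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class PriorHyper:
    """Hyperparameters of the shrinkage prior.

    phi: global shrinkage; small values shrink harder (it is the Gamma rate
        of the local scales δ_j, λ_j).
    v: inverse-Wishart degrees-of-freedom parameter (df = 2v+1 a priori).
    b1, b2: Gamma shapes of δ_j and λ_j.
    """

    phi: float = 1.0
    v: float = 4.0
    b1: float = 0.5
    b2: float = 0.5

    def __post_init__(self):
        if min(self.phi, self.b1, self.b2) <= 0 or self.v <= 1:
            raise ValidationError("require phi, b1, b2 > 0 and v > 1")


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 1000
    n_burnin: int = 500
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_burnin >= self.n_iter:
            raise ValidationError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")


@dataclass
class EffectPosterior:
    """Posterior summaries of (β_jk, α_jk) for one population."""

    population: str
    variant_ids: list[str]
    beta_post: np.ndarray
    alpha_post: np.ndarray
    hyper: PriorHyper
    mcmc: MCMCConfig
    draws_beta: np.ndarray | None = None
    draws_alpha: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# full conditionals
# ---------------------------------------------------------------------------

def _omega_inv_parts(psi, xi, rho):
    """Entries of Ω⁻¹ per SNP: diag blocks a, d and off-diagonal c."""
    # closed form for inv([[psi, rho*s],[rho*s, xi]]), s = sqrt(psi*xi)
    det = np.maximum(psi * xi * (1.0 - rho ** 2), _VAR_FLOOR)
    s = np.sqrt(psi * xi)
    return xi / det, psi / det, -rho * s / det


def sample_coefficients_block(bhat_block: np.ndarray, D_block: np.ndarray,
                              omega_block: tuple[np.ndarray, np.ndarray, np.ndarray],
                              sigma2_k: float, n_weights: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    """One exact draw of (β, α) for an LD block.

    bhat_block: length-2m_b standardized marginal estimates (G then G×T).
    omega_block: (ψ, ξ, ρ) arrays for the block's SNPs.
    n_weights: length-2m_b per-coordinate sample sizes (constant N_k unless
        the composite strategy mixes cohorts).

    Returns the draw, with mean W^{-1/2}(D+Ω⁻¹)⁻¹W^{1/2} b̂ and covariance
    σ_k² W^{-1/2}(D+Ω⁻¹)⁻¹W^{-1/2}.
    """
    psi, xi, rho = omega_block
    m_b = len(psi)
    a, d, c = _omega_inv_parts(psi, xi, rho)
    Phi = np.array(D_block, dtype=float, copy=True)
    idx = np.arange(m_b)
    Phi[idx, idx] += a
    Phi[m_b + idx, m_b + idx] += d
    Phi[idx, m_b + idx] += c
    Phi[m_b + idx, idx] += c
    try:
        L = _sp_cholesky(Phi, lower=True, overwrite_a=True, check_finite=False)
    except np.linalg.LinAlgError as e:
        raise ValidationError("D + Ω⁻¹ not positive definite; increase the LD "
                              "ridge (lambda_R)") from e
    w_sqrt = np.sqrt(n_weights)
    mu = cho_solve((L, True), w_sqrt * bhat_block, check_finite=False) / w_sqrt
    z = rng.standard_normal(2 * m_b)
    noise = solve_triangular(L, z, lower=True, trans="T", check_finite=False)
    return mu + np.sqrt(sigma2_k) * noise / w_sqrt


def sample_residual_variance(bhat: np.ndarray, b_draw: np.ndarray,
                             quad_form: float, n_k: float, m: int,
                             rng: np.random.Generator) -> float:
    """Draw σ_k² from its inverse-Gamma conditional.

    quad_form is b'(D + Ω⁻¹)b accumulated over blocks; the rate is clamped
    below at 1e-8·N_k so numerically negative values cannot occur.
    """
    shape = m + n_k / 2.0
    rate = (n_k / 2.0) * (1.0 - 2.0 * float(bhat @ b_draw) + quad_form)
    rate = max(rate, 1e-8 * n_k)
    return rate / rng.gamma(shape)


def sample_local_covariance(beta_jk: np.ndarray, alpha_jk: np.ndarray,
                            sigma2: np.ndarray, weights: np.ndarray,
                            delta: np.ndarray, lam: np.ndarray, v: float,
                            rng: np.random.Generator):
    """Vectorized inverse-Wishart draw of every M_j.

    beta_jk, alpha_jk: (K, m) current coefficient draws.
    sigma2: (K,) residual variances; weights: (K, 2) per-coordinate sample
        sizes (column 0 for β, column 1 for α; both N_k in the scalar case).
    Returns (psi, xi, rho) arrays of length m with ρ clipped to ±0.999.

    Scale matrix per SNP: B_j + A_j with B_j = 4v·diag(δ_j, λ_j) and
    A_j = Σ_k (1/σ_k²)·[[n_G β², √(n_G n_GT) βα], [·, n_GT α²]];
    df = 2v + K + 1.
    """
    K, m = beta_jk.shape
    wb = weights[:, 0][:, None] / sigma2[:, None]   # (K, m)-broadcastable
    wa = weights[:, 1][:, None] / sigma2[:, None]
    wx = np.sqrt(weights[:, 0] * weights[:, 1])[:, None] / sigma2[:, None]
    S11 = 4.0 * v * delta + (wb * beta_jk ** 2).sum(axis=0)
    S22 = 4.0 * v * lam + (wa * alpha_jk ** 2).sum(axis=0)
    S12 = (wx * beta_jk * alpha_jk).sum(axis=0)
    df = 2.0 * v + K + 1.0

    # M_j ~ IW(S, df)  <=>  M_j = W⁻¹, W ~ Wishart(S⁻¹, df); Bartlett, 2×2.
    detS = np.maximum(S11 * S22 - S12 ** 2, _VAR_FLOOR)
    inv11, inv22, inv12 = S22 / detS, S11 / detS, -S12 / detS
    L11 = np.sqrt(inv11)
    L21 = inv12 / L11
    L22 = np.sqrt(np.maximum(inv22 - L21 ** 2, _VAR_FLOOR))
    c1 = rng.chisquare(df, size=m)
    c2 = rng.chisquare(df - 1.0, size=m)
    z = rng.standard_normal(m)
    # T = L @ A with A = [[sqrt(c1), 0], [z, sqrt(c2)]]
    t11 = L11 * np.sqrt(c1)
    t21 = L21 * np.sqrt(c1) + L22 * z
    t22 = L22 * np.sqrt(c2)
    W11 = t11 ** 2
    W12 = t11 * t21
    W22 = t21 ** 2 + t22 ** 2
    detW = np.maximum(W11 * W22 - W12 ** 2, _VAR_FLOOR)
    psi = np.maximum(W22 / detW, _VAR_FLOOR)
    xi = np.maximum(W11 / detW, _VAR_FLOOR)
    rho = np.clip((-W12 / detW) / np.sqrt(psi * xi), -_RHO_CLIP, _RHO_CLIP)
    return psi, xi, rho


def sample_local_scales(psi: np.ndarray, xi: np.ndarray, rho: np.ndarray,
                        phi: float, v: float, b1: float, b2: float,
                        rng: np.random.Generator):
    """Gamma draws of (δ_j, λ_j) given M_j."""
    one_minus_r2 = np.maximum(1.0 - rho ** 2, 1e-6)
    rate_d = phi + 2.0 * v / (psi * one_minus_r2)
    rate_l = phi + 2.0 * v / (xi * one_minus_r2)
    delta = rng.gamma(v + b1 + 0.5, size=len(psi)) / rate_d
    lam = rng.gamma(v + b2 + 0.5, size=len(xi)) / rate_l
    return delta, lam


# ---------------------------------------------------------------------------
# composite strategy
# ---------------------------------------------------------------------------

def compose_disease_pgx(disease: DiseaseSummaryStats,
                        pgx: PGxSummaryStats) -> PGxSummaryStats:
    """Disease+PGx composite: disease prognostic stats, PGx interaction stats.

    On the variant intersection (allele-aligned to the PGx orientation) the
    prognostic component (beta_G, se_G, p_G) is replaced by the disease GWAS
    values and the per-component sample sizes n_G = disease N, n_GT = PGx N
    are recorded so downstream weighting reflects the two cohorts.
    """
    from .io import _match_orientation  # shared allele logic

    d_by_id = {v.id: i for i, v in enumerate(disease.variants)}
    d_by_pos = {(v.chrom, v.pos): i for i, v in enumerate(disease.variants)}
    keep, d_idx, signs = [], [], []
    for j, v in enumerate(pgx.variants):
        i = d_by_id.get(v.id, d_by_pos.get((v.chrom, v.pos)))
        if i is None:
            continue
        sign = _match_orientation(disease.variants[i], v)
        if sign is None:
            continue
        keep.append(j)
        d_idx.append(i)
        signs.append(sign)
    if not keep:
        raise ValidationError("no variants shared between disease and PGx summary statistics")
    keep = np.asarray(keep)
    d_idx = np.asarray(d_idx)
    signs = np.asarray(signs, dtype=float)
    sub = pgx.take(keep)
    return PGxSummaryStats(
        population=pgx.population,
        variants=sub.variants,
        beta_G=disease.beta[d_idx] * signs,
        se_G=disease.se[d_idx],
        p_G=disease.p[d_idx],
        beta_GT=sub.beta_GT, se_GT=sub.se_GT, p_GT=sub.p_GT,
        n=pgx.n, treated_fraction=pgx.treated_fraction, eaf=sub.eaf,
        n_G=disease.n, n_GT=pgx.n,
        prognostic_source="disease_marginal",
        beta_G_pgx=sub.beta_G, se_G_pgx=sub.se_G,
    )


# ---------------------------------------------------------------------------
# the Gibbs fit
# ---------------------------------------------------------------------------

def _pop_seed(seed: int, label: str) -> list[int]:
    h = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return [int(seed) % (2 ** 31), h]


def _align_to_common(sumstats_list, panels):
    """Intersect SNP sets across populations; order/partition from panel 0."""
    common = set(panels[0].ids())
    for p in panels[1:]:
        common &= set(p.ids())
    for ss in sumstats_list:
        common &= set(ss.ids())
    if not common:
        raise ValidationError("empty variant intersection across populations")
    panels2 = [p.subset(common) for p in panels]
    ref_blocks = [tuple(b.variant_ids) for b in panels2[0].blocks]
    for p in panels2[1:]:
        if [tuple(b.variant_ids) for b in p.blocks] != ref_blocks:
            raise ValidationError("LD block structures differ across populations "
                                  "after harmonization to the common SNP set")
    order = panels2[0].ids()
    aligned = []
    for ss in sumstats_list:
        pos = {vid: i for i, vid in enumerate(ss.ids())}
        aligned.append(ss.take(np.array([pos[vid] for vid in order])))
    return aligned, panels2, order


def fit_prs_pgx_bayesx(sumstats_list: list[PGxSummaryStats],
                       panels: list[LDBlockPanel],
                       hyper: PriorHyper = PriorHyper(),
                       mcmc: MCMCConfig = MCMCConfig(),
                       ridge: float = 0.1,
                       composite_n_mode: str = "per_coordinate",
                       keep_draws: bool = False) -> list[EffectPosterior]:
    """Fit the K-population sampler; returns one posterior per population.

    Inputs must be allele-harmonized to their panels (see
    :func:`pgxprs.io.harmonize`); the SNP intersection across populations is
    taken here and block structure must agree on it.  Posterior means are
    averages of post-burn-in thinned draws; the run is deterministic for a
    fixed seed and invariant (up to relabeling) to population input order.

    composite_n_mode: "per_coordinate" applies W = diag(n_G·1, n_GT·1) when a
    composite carries two sample sizes; "pgx_only" uses the naive W = N_pgx·I.
    """
    if composite_n_mode not in ("per_coordinate", "pgx_only"):
        raise ValidationError(f"unknown composite_n_mode {composite_n_mode!r}")
    K = len(sumstats_list)
    if K == 0 or len(panels) != K:
        raise ValidationError("need one panel per summary-statistics set")
    aligned, panels2, order = _align_to_common(sumstats_list, panels)
    m = len(order)
    designs: list[DesignCorrelation] = [
        build_design_correlation(p, ss.treated_fraction, ridge)
        for ss, p in zip(aligned, panels2)
    ]
    block_sizes = [len(ids) for ids in designs[0].block_ids]
    slices = panels2[0].block_slices()

    std = []
    weights2 = np.empty((K, 2))
    for k, ss in enumerate(aligned):
        if composite_n_mode == "pgx_only":
            ss_eff = ss.take(np.arange(ss.m))
            ss_eff.n_G = ss_eff.n_GT = ss.n
            std.append(standardize_marginal(ss_eff))
        else:
            std.append(standardize_marginal(ss))
        weights2[k] = (std[k].n_G, std[k].n_GT)

    bhat = [np.concatenate([s.bhat_G, s.bhat_GT]) for s in std]  # 2m, G then GT
    n_weights = [np.concatenate([np.full(m, w[0]), np.full(m, w[1])])
                 for w in weights2]

    rng_shared = np.random.default_rng(
        np.random.SeedSequence([int(mcmc.seed) % (2 ** 31), 0x5EED]))
    rng_pop = {ss.population: np.random.default_rng(
        np.random.SeedSequence(_pop_seed(mcmc.seed, ss.population)))
        for ss in aligned}

    # state
    psi = np.ones(m)
    xi = np.ones(m)
    rho = np.zeros(m)
    delta = np.ones(m)
    lam = np.ones(m)
    sigma2 = np.ones(K)
    beta = np.zeros((K, m))
    alpha = np.zeros((K, m))

    n_kept = (mcmc.n_iter - mcmc.n_burnin + mcmc.thin - 1) // mcmc.thin
    sum_beta = np.zeros((K, m))
    sum_alpha = np.zeros((K, m))
    draws_b = np.empty((K, n_kept, m)) if keep_draws else None
    draws_a = np.empty((K, n_kept, m)) if keep_draws else None

    kept = 0
    for it in range(mcmc.n_iter):
        # (1) coefficients, per population per LD block
        quad = np.zeros(K)
        for k in range(K):
            rng_k = rng_pop[aligned[k].population]
            for bi, sl in enumerate(slices):
                m_b = block_sizes[bi]
                coord = np.r_[np.arange(sl.start, sl.stop),
                              m + np.arange(sl.start, sl.stop)]
                draw = sample_coefficients_block(
                    bhat[k][coord], designs[k].D[bi],
                    (psi[sl], xi[sl], rho[sl]),
                    sigma2[k], n_weights[k][coord], rng_k)
                beta[k, sl] = draw[:m_b]
                alpha[k, sl] = draw[m_b:]
                # accumulate b'(D+Ω⁻¹)b for the σ² update
                a, d, c = _omega_inv_parts(psi[sl], xi[sl], rho[sl])
                Db = designs[k].D[bi] @ draw
                quad[k] += float(draw @ Db) \
                    + float(a @ draw[:m_b] ** 2) + float(d @ draw[m_b:] ** 2) \
                    + 2.0 * float(c @ (draw[:m_b] * draw[m_b:]))
        # (2) residual variances
        for k in range(K):
            rng_k = rng_pop[aligned[k].population]
            b_full = np.concatenate([beta[k], alpha[k]])
            sigma2[k] = sample_residual_variance(
                bhat[k], b_full, quad[k], weights2[k, 1], m, rng_k)
        # (3) local covariances, pooling all populations
        psi, xi, rho = sample_local_covariance(
            beta, alpha, sigma2, weights2, delta, lam, hyper.v, rng_shared)
        # (4) local scales
        delta, lam = sample_local_scales(
            psi, xi, rho, hyper.phi, hyper.v, hyper.b1, hyper.b2, rng_shared)

        if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
            sum_beta += beta
            sum_alpha += alpha
            if keep_draws:
                draws_b[:, kept] = beta
                draws_a[:, kept] = alpha
            kept += 1

    out = []
    for k, ss in enumerate(aligned):
        out.append(EffectPosterior(
            population=ss.population, variant_ids=list(order),
            beta_post=sum_beta[k] / kept, alpha_post=sum_alpha[k] / kept,
            hyper=hyper, mcmc=mcmc,
            draws_beta=draws_b[k] if keep_draws else None,
            draws_alpha=draws_a[k] if keep_draws else None,
            diagnostics={"sigma2_final": float(sigma2[k]), "n_kept_draws": kept},
        ))
    return out


def fit_prs_pgx_bayes(sumstats: PGxSummaryStats, panel: LDBlockPanel,
                      hyper: PriorHyper = PriorHyper(),
                      mcmc: MCMCConfig = MCMCConfig(),
                      ridge: float = 0.1, **kwargs) -> EffectPosterior:
    """Single-population special case (K = 1); bit-identical to the K-population
    fit called with one study and the same seed."""
    return fit_prs_pgx_bayesx([sumstats], [panel], hyper, mcmc, ridge, **kwargs)[0]
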