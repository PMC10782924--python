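"""Standardized-scale effects and the joint design second-moment matrix.

The samplers work on the scale where genotypes and phenotype have unit
variance.  On that scale a marginal GWAS estimate for SNP j is recovered from
its z-score as ``z_j / sqrt(n)``, independent of the trait units used by the
contributing study.

For a trial with treated fraction r and treatment randomized independently of
genotype, the uncentred second-moment matrix of the stacked design
``X = [G, G∘T]`` is, per LD block,

    D = [[R, rR], [rR, rR]] = [[1, r], [r, r]] ⊗ R,

since E[T] = E[T²] = r.  Both Kronecker factors are PSD for r in (0,1), so D
is PSD; a small ridge on R guards against reference-panel mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DiseaseSummaryStats, LDBlockPanel, PGxSummaryStats, ValidationError

__all__ = ["StandardizedEffects", "DesignCorrelation", "standardize_marginal",
           "build_design_correlation"]


@dataclass
class StandardizedEffects:
    """Marginal effects on the standardized (correlation) scale."""

    bhat_G: np.ndarray
    bhat_GT: np.ndarray
    n_G: int
    n_GT: int

    @property
    def m(self) -> int:
        return len(self.bhat_G)


@dataclass
class DesignCorrelation:
    """Per-block 2m_b×2m_b second-moment matrices of [G, G∘T].

    Coordinate order within a block: the m_b prognostic coordinates first,
    then the m_b interaction coordinates.
    """

    population: str
    block_ids: list[list[str]]
    D: list[np.ndarray]
    treated_fraction: float
    ridge: float


def standardize_marginal(sumstats: PGxSummaryStats | DiseaseSummaryStats) -> StandardizedEffects:
    """Standardized marginal cross-products b̂ = X'Y/N from GWAS estimates.

    The sampler's conjugate algebra is written in terms of the uncentred
    cross-products of the stacked standardized design X = [G, G∘T] with the
    standardized phenotype.  PGx GWAS report per-SNP *joint* regressions of Y
    on (1, T, g, g·T); on the standardized scale those coefficients
    (β̂*, α̂*) relate to the cross-products through the per-SNP 2×2 second
    moment [[1, r], [r, r]]:

        b̂_G = β̂* + r·α̂*,        b̂_GT = r·(β̂* + α̂*),

    with β̂* = z_G/√((1−r)·n_G) and α̂* = z_GT/√(r(1−r)·n_GT) recovered from
    the z-scores (the joint-model coefficient variances are σ²/((1−r)N) and
    σ²/(r(1−r)N)).  A single-arm disease GWAS estimate is already a simple
    marginal, so b̂_G = z/√n there; in a Disease+PGx composite the
    interaction cross-product is rebuilt from the retained PGx prognostic
    statistics.
    """
    if isinstance(sumstats, DiseaseSummaryStats):
        if np.any(sumstats.se == 0):
            raise ValidationError("zero standard error")
        z = sumstats.beta / sumstats.se
        bhat = z / np.sqrt(sumstats.n)
        return StandardizedEffects(bhat_G=bhat, bhat_GT=np.zeros_like(bhat),
                                   n_G=sumstats.n, n_GT=sumstats.n)
    bad = np.flatnonzero((sumstats.se_G == 0) | (sumstats.se_GT == 0))
    if bad.size:
        raise ValidationError(f"zero standard error at SNP {sumstats.variants[bad[0]].id}")
    r = sumstats.treated_fraction
    z_GT = sumstats.beta_GT / sumstats.se_GT
    alpha_std = z_GT / np.sqrt(r * (1.0 - r) * sumstats.n_GT)
    z_G = sumstats.beta_G / sumstats.se_G
    if sumstats.prognostic_source == "disease_marginal":
        bhat_G = z_G / np.sqrt(sumstats.n_G)
        z_G_pgx = sumstats.beta_G_pgx / sumstats.se_G_pgx
        beta_std = z_G_pgx / np.sqrt((1.0 - r) * sumstats.n_GT)
    else:
        beta_std = z_G / np.sqrt((1.0 - r) * sumstats.n_G)
        bhat_G = beta_std + r * alpha_std
    bhat_GT = r * (beta_std + alpha_std)
    return StandardizedEffects(bhat_G=bhat_G, bhat_GT=bhat_GT,
                               n_G=sumstats.n_G, n_GT=sumstats.n_GT)


def build_design_correlation(panel: LDBlockPanel, treated_fraction: float,
                             ridge: float = 0.1) -> DesignCorrelation:
    """Assemble D = [[1,r],[r,r]] ⊗ R* per block, with R* = (1-λ)R + λI."""
    r = float(treated_fraction)
    if not (0.0 < r < 1.0):
        raise ValidationError(f"treated_fraction must be in (0,1), got {r} "
                              "(r=1 makes D singular by construction)")
    if not (0.0 <= ridge < 1.0):
        raise ValidationError("ridge must lie in [0, 1)")
    mats, ids = [], []
    factor = np.array([[1.0, r], [r, r]])
    for b in panel.blocks:
        m_b = len(b.variant_ids)
        R_star = (1.0 - ridge) * b.R + ridge * np.eye(m_b)
        mats.append(np.kron(factor, R_star))
        ids.append(list(b.variant_ids))
    return DesignCorrelation(population=panel.population, block_ids=ids, D=mats,
                             treated_fraction=r, ridge=ridge)
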