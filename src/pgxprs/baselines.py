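"""Non-Bayesian comparators: clumping+thresholding and multi-population blends.

Four families:

* ``fit_prs_pgx_ct`` — C+T on PGx summary statistics: greedy LD clumping
  driven by a p-value (by default the smaller of the prognostic and
  interaction p so predictive-only signals survive), then per-threshold
  weight vectors for both components.
* ``fit_ct_disease`` — C+T on disease summary statistics only; the single
  prognostic component is reused as the interaction score downstream.
* ``meta_analyze_sumstats`` — per-SNP inverse-variance fixed-effect
  meta-analysis across studies (the CT-Meta input).
* ``combine_multiethnic_prs`` — PRS_0 = π·PRS_a + (1−π)·PRS_b with π chosen
  on a grid by cross-validated R² in the target cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (DiseaseSummaryStats, LDBlockPanel, PGxCohort, PGxSummaryStats,
                 ValidationError, _match_orientation)
from .evaluate import PRSPair

__all__ = ["CTConfig", "ld_clump", "fit_prs_pgx_ct", "fit_ct_disease",
           "meta_analyze_sumstats", "combine_multiethnic_prs"]

DEFAULT_P_GRID = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class CTConfig:
    """Clumping + thresholding settings.

    clump_field: which p-value drives clumping — "min" (elementwise min of
    p_G and p_GT; the default for PGx inputs), "p_G" or "p_GT".
    """

    r2_clump: float = 0.1
    p_grid: tuple = DEFAULT_P_GRID
    clump_field: str = "min"

    def __post_init__(self):
        if not (0.0 < self.r2_clump <= 1.0):
            raise ValidationError("r2_clump must lie in (0, 1]")
        if len(self.p_grid) == 0:
            raise ValidationError("p_grid must be non-empty")
        self.p_grid = tuple(sorted(float(p) for p in self.p_grid))
        if any(not (0.0 < p <= 1.0) for p in self.p_grid):
            raise ValidationError("p-value thresholds must lie in (0, 1]")
        if self.clump_field not in ("min", "p_G", "p_GT"):
            raise ValidationError(f"unknown clump_field {self.clump_field!r}")


def _clump_pvalues(sumstats, clump_field: str) -> np.ndarray:
    if isinstance(sumstats, DiseaseSummaryStats):
        return sumstats.p
    if clump_field == "p_G":
        return sumstats.p_G
    if clump_field == "p_GT":
        return sumstats.p_GT
    return np.minimum(sumstats.p_G, sumstats.p_GT)


def ld_clump(sumstats, panel: LDBlockPanel, r2_clump: float = 0.1,
             clump_field: str = "min") -> list[str]:
    """Greedy LD clumping; returns retained variant ids in retention order.

    Repeatedly take the unremoved SNP with the smallest clumping p-value
    (ties broken by ascending variant id), retain it, and remove every
    unremoved SNP in its LD block with r² above the threshold.  The result is
    independent of input row order because (p, id) is a total order.
    """
    ids = sumstats.ids()
    pvals = _clump_pvalues(sumstats, clump_field)
    order = {vid: i for i, vid in enumerate(ids)}
    block_of = {}
    idx_in_block = {}
    for bi, b in enumerate(panel.blocks):
        for i, vid in enumerate(b.variant_ids):
            block_of[vid] = bi
            idx_in_block[vid] = i
    candidates = sorted((float(pvals[order[vid]]), vid) for vid in ids
                        if vid in block_of)
    removed: set[str] = set()
    retained: list[str] = []
    for p, vid in candidates:
        if vid in removed:
            continue
        retained.append(vid)
        removed.add(vid)
        b = panel.blocks[block_of[vid]]
        row = b.R[idx_in_block[vid]]
        for j, other in enumerate(b.variant_ids):
            if other not in removed and row[j] ** 2 > r2_clump:
                removed.add(other)
    return retained


def _weight_frame(sumstats, w_G: np.ndarray, w_GT: np.ndarray,
                  population: str) -> pd.DataFrame:
    return pd.DataFrame({
        "SNP": sumstats.ids(),
        "CHR": [v.chrom for v in sumstats.variants],
        "POS": [v.pos for v in sumstats.variants],
        "A1": [v.a1 for v in sumstats.variants],
        "BETA_G_POST": w_G, "BETA_GT_POST": w_GT,
        "POPULATION": population,
    })


def fit_prs_pgx_ct(sumstats: PGxSummaryStats, panel: LDBlockPanel,
                   config: CTConfig = CTConfig()) -> dict[float, pd.DataFrame]:
    """C+T on PGx summary statistics: per-threshold two-component weights.

    For each threshold t, weight_G[j] = beta_G[j] if SNP j survived clumping
    and p_G[j] <= t (zero otherwise); weight_GT analogous with p_GT.  Returns
    a mapping from threshold to effect-weight table.
    """
    retained = set(ld_clump(sumstats, panel, config.r2_clump, config.clump_field))
    in_clump = np.array([vid in retained for vid in sumstats.ids()])
    out = {}
    any_nonzero = False
    for t in config.p_grid:
        w_G = np.where(in_clump & (sumstats.p_G <= t), sumstats.beta_G, 0.0)
        w_GT = np.where(in_clump & (sumstats.p_GT <= t), sumstats.beta_GT, 0.0)
        any_nonzero = any_nonzero or bool(np.any(w_G) or np.any(w_GT))
        out[t] = _weight_frame(sumstats, w_G, w_GT, sumstats.population)
    if not any_nonzero:
        import warnings
        warnings.warn("no SNP survives any threshold; all weights zero")
    return out


def fit_ct_disease(disease: DiseaseSummaryStats, panel: LDBlockPanel,
                   config: CTConfig = CTConfig(),
                   population: str = "") -> dict[float, pd.DataFrame]:
    """C+T on disease summary statistics; the prognostic weights double as the
    interaction weights (PRS_GT := PRS_G in the evaluation model)."""
    retained = set(ld_clump(disease, panel, config.r2_clump, "p_G"))
    in_clump = np.array([vid in retained for vid in disease.ids()])
    out = {}
    any_nonzero = False
    for t in config.p_grid:
        w = np.where(in_clump & (disease.p <= t), disease.beta, 0.0)
        any_nonzero = any_nonzero or bool(np.any(w))
        out[t] = _weight_frame(disease, w, w.copy(), population)
    if not any_nonzero:
        import warnings
        warnings.warn("no SNP survives any threshold; all weights zero")
    return out


def _align_study(ref_variants, study) -> dict[str, tuple[int, float]]:
    """Map ref variant id -> (row index in study, orientation sign)."""
    by_id = {v.id: i for i, v in enumerate(study.variants)}
    by_pos = {(v.chrom, v.pos): i for i, v in enumerate(study.variants)}
    out = {}
    for ref in ref_variants:
        i = by_id.get(ref.id, by_pos.get((ref.chrom, ref.pos)))
        if i is None:
            continue
        sign = _match_orientation(study.variants[i], ref)
        if sign is None:
            continue
        out[ref.id] = (i, float(sign))
    return out


def meta_analyze_sumstats(studies: list):
    """Inverse-variance fixed-effect meta-analysis across studies.

    Works on PGx inputs (G and G×T components meta-analyzed separately) or
    disease inputs.  Alleles are aligned to the first study's orientation;
    the output covers the union of SNPs present in at least one study, with
    per-SNP N summed over the contributing studies.
    """
    if not studies:
        raise ValidationError("need at least one study")
    first = studies[0]
    is_pgx = isinstance(first, PGxSummaryStats)
    seen = {}
    ref_variants = []
    for st in studies:
        for v in st.variants:
            key = v.id
            if key not in seen:
                seen[key] = v
                ref_variants.append(v)
    aligns = [_align_study(ref_variants, st) for st in studies]

    def _ivw(betas, ses):
        w = 1.0 / np.asarray(ses) ** 2
        beta = float((w * betas).sum() / w.sum())
        se = float(w.sum() ** -0.5)
        z = beta / se if se > 0 else 0.0
        p = float(min(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
        return beta, se, p

    rows = []
    for ref in ref_variants:
        contrib = [(k, aligns[k][ref.id]) for k in range(len(studies))
                   if ref.id in aligns[k]]
        if not contrib:
            continue
        n_sum = sum(studies[k].n for k, _ in contrib)
        if is_pgx:
            bg, sg = zip(*[(studies[k].beta_G[i] * s, studies[k].se_G[i])
                           for k, (i, s) in contrib])
            bgt, sgt = zip(*[(studies[k].beta_GT[i] * s, studies[k].se_GT[i])
                             for k, (i, s) in contrib])
            eafs = [studies[k].eaf[i] if s > 0 else 1 - studies[k].eaf[i]
                    for k, (i, s) in contrib]
            ns = [studies[k].n for k, _ in contrib]
            mg = _ivw(np.array(bg), np.array(sg))
            mgt = _ivw(np.array(bgt), np.array(sgt))
            rows.append((ref, mg, mgt, n_sum, float(np.average(eafs, weights=ns))))
        else:
            b, s_ = zip(*[(studies[k].beta[i] * s, studies[k].se[i])
                          for k, (i, s) in contrib])
            eafs = [studies[k].eaf[i] if s > 0 else 1 - studies[k].eaf[i]
                    for k, (i, s) in contrib]
            ns = [studies[k].n for k, _ in contrib]
            mb = _ivw(np.array(b), np.array(s_))
            rows.append((ref, mb, None, n_sum, float(np.average(eafs, weights=ns))))

    variants = [r[0] for r in rows]
    n_total = max(r[3] for r in rows)
    if is_pgx:
        r_meta = float(np.mean([st.treated_fraction for st in studies]))
        return PGxSummaryStats(
            population="META",
            variants=variants,
            beta_G=np.array([r[1][0] for r in rows]),
            se_G=np.array([r[1][1] for r in rows]),
            p_G=np.array([r[1][2] for r in rows]),
            beta_GT=np.array([r[2][0] for r in rows]),
            se_GT=np.array([r[2][1] for r in rows]),
            p_GT=np.array([r[2][2] for r in rows]),
            n=n_total, treated_fraction=r_meta,
            eaf=np.array([r[4] for r in rows]),
        )
    return DiseaseSummaryStats(
        variants=variants,
        beta=np.array([r[1][0] for r in rows]),
        se=np.array([r[1][1] for r in rows]),
        p=np.array([r[1][2] for r in rows]),
        n=n_total,
        eaf=np.array([r[4] for r in rows]),
    )


def combine_multiethnic_prs(prs_a: PRSPair, prs_b: PRSPair, cohort: PGxCohort,
                            pi_grid=None, k_folds: int = 5, seed: int = 0):
    """Grid-search the mixing weight π of PRS_0 = π·PRS_a + (1−π)·PRS_b.

    π* maximizes the k-fold cross-validated R² of the evaluation model in
    ``cohort``; ties are broken toward the smallest π.  Returns
    ``(pi_star, combined PRSPair at pi_star)``.
    """
    if pi_grid is None:
        pi_grid = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    pi_grid = [float(p) for p in pi_grid]
    if not pi_grid:
        raise ValidationError("pi_grid must be non-empty")
    if len(prs_a.prs_G) != cohort.n or len(prs_b.prs_G) != cohort.n:
        raise ValidationError("PRS length != cohort size")
    pi_grid = sorted(pi_grid)

    from .evaluate import _stratified_folds, _subcohort, evaluate_prediction
    folds = _stratified_folds(cohort.T, k_folds, seed)
    mean_oof = []
    for pi in pi_grid:
        g = pi * prs_a.prs_G + (1 - pi) * prs_b.prs_G
        gt = pi * prs_a.prs_GT + (1 - pi) * prs_b.prs_GT
        oof_r2 = []
        for f in range(k_folds):
            test = folds == f
            train = ~test
            try:
                res = evaluate_prediction(_subcohort(cohort, train),
                                          PRSPair(g[train], gt[train]))
            except ValidationError:
                oof_r2.append(0.0)
                continue
            Xt = np.column_stack([np.ones(test.sum()), cohort.T[test],
                                  g[test], cohort.T[test] * gt[test]])
            pred = Xt @ res.coefficients
            r2 = 0.0 if np.std(pred) == 0 else \
                float(np.corrcoef(pred, cohort.Y[test])[0, 1] ** 2)
            oof_r2.append(r2)
        mean_oof.append(float(np.mean(oof_r2)))
    best_i = int(np.argmax(mean_oof))  # argmax returns first max: smallest π wins ties
    pi_star = pi_grid[best_i]
    combined = PRSPair(
        pi_star * prs_a.prs_G + (1 - pi_star) * prs_b.prs_G,
        pi_star * prs_a.prs_GT + (1 - pi_star) * prs_b.prs_GT,
        population=cohort.population,
        provenance=f"multiethnic pi={pi_star}",
    )
    return pi_star, combined
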