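"""Score construction, the drug-response evaluation model, and tuning.

Two scores are carried per subject: PRS_G = Gβ_G (prognostic) and
PRS_GT = Gβ_GT (predictive).  Prediction quality is assessed with

    E[Y] = β0 + β1·T + β2·PRS_G + β3·T×PRS_GT

and reported as R² (squared correlation between fitted and observed response)
together with the two-sided Wald p-value for the PRS-by-treatment interaction
β3.  Methods that produce only a prognostic component reuse PRS_G in the
interaction term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PGxCohort, ValidationError

__all__ = ["PRSPair", "EvalResult", "compute_prs", "evaluate_prediction",
           "cv_tune", "external_tune", "stratify_patients", "posterior_to_weights"]


@dataclass
class PRSPair:
    """Per-subject prognostic and predictive polygenic scores."""

    prs_G: np.ndarray
    prs_GT: np.ndarray
    population: str = ""
    provenance: str = ""

    def __post_init__(self):
        self.prs_G = np.asarray(self.prs_G, dtype=float)
        self.prs_GT = np.asarray(self.prs_GT, dtype=float)
        if self.prs_G.shape != self.prs_GT.shape:
            raise ValidationError("prs_G and prs_GT lengths differ")
        if not (np.all(np.isfinite(self.prs_G)) and np.all(np.isfinite(self.prs_GT))):
            raise ValidationError("scores must be finite")


@dataclass
class EvalResult:
    r2: float
    beta3: float
    p_interaction: float
    coefficients: np.ndarray
    n: int
    meta: dict = field(default_factory=dict)


def posterior_to_weights(post, variants=None) -> pd.DataFrame:
    """Effect-weight table from an :class:`~pgxprs.bayes.EffectPosterior`."""
    if variants is not None:
        vmap = {v.id: v for v in variants}
        rows = [vmap[i] for i in post.variant_ids]
        chrom = [v.chrom for v in rows]
        pos = [v.pos for v in rows]
        a1 = [v.a1 for v in rows]
    else:
        chrom = ["0"] * len(post.variant_ids)
        pos = list(range(1, len(post.variant_ids) + 1))
        a1 = ["A"] * len(post.variant_ids)
    return pd.DataFrame({
        "SNP": post.variant_ids, "CHR": chrom, "POS": pos, "A1": a1,
        "BETA_G_POST": post.beta_post, "BETA_GT_POST": post.alpha_post,
        "POPULATION": post.population,
    })


def compute_prs(cohort: PGxCohort, weights: pd.DataFrame,
                standardize: bool = True) -> PRSPair:
    """Score a cohort with an effect-weight table.

    Weights are matched to cohort variants by SNP id; a weight whose ``A1``
    equals the cohort variant's other allele is applied with its sign negated
    (so allele-flipped weight files score identically).  SNPs without a
    reconcilable weight contribute 0.  With ``standardize`` (the default,
    matching the standardized scale of the Bayesian posterior means) dosage
    columns are z-scored before weighting.
    """
    w_by_id = {}
    for row in weights.itertuples():
        w_by_id[str(row.SNP)] = (str(row.A1), float(row.BETA_G_POST),
                                 float(row.BETA_GT_POST))
    w_G = np.zeros(cohort.m)
    w_GT = np.zeros(cohort.m)
    n_matched = 0
    for j, v in enumerate(cohort.variants):
        rec = w_by_id.get(v.id)
        if rec is None:
            continue
        a1, wg, wgt = rec
        if a1 == v.a1:
            sign = 1.0
        elif a1 == v.a2:
            sign = -1.0
        else:
            continue
        w_G[j] = sign * wg
        w_GT[j] = sign * wgt
        n_matched += 1
    if n_matched == 0:
        raise ValidationError("no overlap between weight table and cohort variants")
    G = cohort.G
    if standardize:
        mu = G.mean(axis=0)
        sd = G.std(axis=0)
        sd[sd == 0] = 1.0
        prs_G = (G - mu) @ (w_G / sd)
        prs_GT = (G - mu) @ (w_GT / sd)
    else:
        prs_G = G @ w_G
        prs_GT = G @ w_GT
    return PRSPair(prs_G=prs_G, prs_GT=prs_GT, population=cohort.population)


def _ols(X: np.ndarray, y: np.ndarray):
    """Closed-form OLS: coefficients, fitted values, SEs, residual dof."""
    XtX = X.T @ X
    try:
        coef = np.linalg.solve(XtX, X.T @ y)
    except np.linalg.LinAlgError as e:
        raise ValidationError("design matrix singular (constant PRS?)") from e
    fitted = X @ coef
    resid = y - fitted
    dof = len(y) - X.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(XtX)
    return coef, fitted, np.sqrt(np.clip(np.diag(cov), 0.0, None)), dof


def evaluate_prediction(cohort: PGxCohort, prs: PRSPair,
                        r2_mode: str = "fitted") -> EvalResult:
    """Fit the evaluation model and report R² and the interaction test.

    r2_mode "fitted": squared correlation between fitted and observed Y
    (the default); "incremental": R² of the full model minus that of the
    treatment-only null model (1, T).
    """
    if cohort.n < 10:
        raise ValidationError("need at least 10 subjects")
    if np.std(prs.prs_G) == 0 or np.std(prs.prs_GT) == 0:
        raise ValidationError("constant PRS: evaluation model degenerate")
    Y, T = cohort.Y, cohort.T
    X = np.column_stack([np.ones(cohort.n), T, prs.prs_G, T * prs.prs_GT])
    coef, fitted, se, dof = _ols(X, Y)
    tstat = coef[3] / se[3]
    p = float(2.0 * stats.t.sf(abs(tstat), dof))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    if r2_mode == "incremental":
        ss_full = float(((Y - fitted) ** 2).sum())
        X0 = X[:, :2]
        _, fitted0, _, _ = _ols(X0, Y)
        ss_null = float(((Y - fitted0) ** 2).sum())
        ss_tot = float(((Y - Y.mean()) ** 2).sum())
        r2 = max((ss_null - ss_full) / ss_tot, 0.0)
    elif r2_mode == "fitted":
        if np.std(fitted) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(fitted, Y)[0, 1] ** 2)
    else:
        raise ValidationError(f"unknown r2_mode {r2_mode!r}")
    return EvalResult(r2=r2, beta3=float(coef[3]), p_interaction=p,
                      coefficients=coef, n=cohort.n, meta={"r2_mode": r2_mode})


def _stratified_folds(T: np.ndarray, k_folds: int, seed: int) -> np.ndarray:
    """Fold labels keeping both arms represented in every fold."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(T), dtype=int)
    for arm in (0, 1):
        idx = np.flatnonzero(T == arm)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k_folds
    counts0 = np.bincount(folds[T == 0], minlength=k_folds)
    counts1 = np.bincount(folds[T == 1], minlength=k_folds)
    if counts0.min() == 0 or counts1.min() == 0:
        raise ValidationError("cohort too small to keep both arms in every fold")
    return folds


def _subcohort(cohort: PGxCohort, mask: np.ndarray) -> PGxCohort:
    return PGxCohort(cohort.population, cohort.Y[mask], cohort.T[mask],
                     cohort.G[mask], cohort.variants, single_arm=cohort.single_arm)


def cv_tune(cohort: PGxCohort, candidates: dict, k_folds: int = 5,
            seed: int = 0, r2_mode: str = "fitted"):
    """Cross-validated candidate selection in the target cohort.

    ``candidates`` maps a label (e.g. a hyperparameter setting or p-value
    threshold) to an effect-weight table.  Folds are seeded and stratified by
    treatment arm.  For each candidate, the evaluation model is fit on the
    training folds and scored on the held-out fold; the winner maximizes the
    mean out-of-fold R² (ties go to the earliest candidate in input order).
    The held-out scores of each fold's own training-fold winner are assembled
    into an unbiased out-of-fold PRS.

    Returns ``(best_label, fold_results, oof_prs)`` where ``fold_results`` is
    a dict label -> list of per-fold EvalResult.
    """
    if not candidates:
        raise ValidationError("no candidates supplied")
    if k_folds < 2:
        raise ValidationError("k_folds must be >= 2")
    folds = _stratified_folds(cohort.T, k_folds, seed)
    labels = list(candidates)
    scores = {lab: compute_prs(cohort, candidates[lab]) for lab in labels}

    fold_results: dict = {lab: [] for lab in labels}
    oof_G = np.zeros(cohort.n)
    oof_GT = np.zeros(cohort.n)
    for f in range(k_folds):
        test = folds == f
        train = ~test
        train_r2 = []
        for lab in labels:
            prs = scores[lab]
            train_prs = PRSPair(prs.prs_G[train], prs.prs_GT[train])
            try:
                res_train = evaluate_prediction(_subcohort(cohort, train), train_prs,
                                                r2_mode=r2_mode)
            except ValidationError:
                # degenerate candidate in this fold (e.g. all-zero weights at a
                # strict threshold): uninformative, scores 0
                train_r2.append(0.0)
                dummy = EvalResult(0.0, 0.0, 1.0, np.zeros(4), int(test.sum()),
                                   meta={"oof_r2": 0.0, "train_r2": 0.0,
                                         "degenerate": True})
                fold_results[lab].append(dummy)
                continue
            train_r2.append(res_train.r2)
            # out-of-fold: predict held-out subjects with the train-fold model
            coef = res_train.coefficients
            tst = PRSPair(prs.prs_G[test], prs.prs_GT[test])
            Xt = np.column_stack([np.ones(test.sum()), cohort.T[test],
                                  tst.prs_G, cohort.T[test] * tst.prs_GT])
            pred = Xt @ coef
            Yt = cohort.Y[test]
            r2_oof = 0.0 if np.std(pred) == 0 else float(np.corrcoef(pred, Yt)[0, 1] ** 2)
            try:
                res_test = evaluate_prediction(_subcohort(cohort, test), tst,
                                               r2_mode=r2_mode)
            except ValidationError:
                res_test = EvalResult(0.0, 0.0, 1.0, np.zeros(4), int(test.sum()))
            res_test.meta["oof_r2"] = r2_oof
            res_test.meta["train_r2"] = res_train.r2
            fold_results[lab].append(res_test)
        winner = labels[int(np.argmax(train_r2))]
        oof_G[test] = scores[winner].prs_G[test]
        oof_GT[test] = scores[winner].prs_GT[test]

    mean_oof = [float(np.mean([r.meta["oof_r2"] for r in fold_results[lab]]))
                for lab in labels]
    best = labels[int(np.argmax(mean_oof))]
    oof = PRSPair(oof_G, oof_GT, population=cohort.population,
                  provenance="out-of-fold")
    return best, fold_results, oof


def external_tune(valid_cohort: PGxCohort, candidates: dict,
                  r2_mode: str = "fitted"):
    """Pick the candidate with the best R² on a held-out validation cohort."""
    if not candidates:
        raise ValidationError("no candidates supplied")
    labels = list(candidates)
    r2s = []
    for lab in labels:
        try:
            prs = compute_prs(valid_cohort, candidates[lab])
            r2s.append(evaluate_prediction(valid_cohort, prs, r2_mode=r2_mode).r2)
        except ValidationError:
            r2s.append(0.0)
    return labels[int(np.argmax(r2s))]


def stratify_patients(prs: PRSPair, cohort: PGxCohort, n_strata: int = 4,
                      component: str = "GT") -> pd.DataFrame:
    """Quantile-stratify subjects by a score and tabulate arm means.

    component: "G", "GT" or "combined" (the sum of both scores).  Returns a
    frame with per-stratum counts, arm means, and the treated-minus-control
    difference (the stratum-level treatment effect).
    """
    if n_strata < 2:
        raise ValidationError("n_strata must be >= 2")
    score = {"G": prs.prs_G, "GT": prs.prs_GT,
             "combined": prs.prs_G + prs.prs_GT}.get(component)
    if score is None:
        raise ValidationError(f"unknown component {component!r}")
    try:
        strata = pd.qcut(score, n_strata, labels=False, duplicates="raise")
    except ValueError as e:
        raise ValidationError("tied scores collapse a stratum; use fewer strata") from e
    rows = []
    for s in range(n_strata):
        mask = strata == s
        t1 = mask & (cohort.T == 1)
        t0 = mask & (cohort.T == 0)
        if t1.sum() == 0 or t0.sum() == 0:
            raise ValidationError("a stratum lost an arm; use fewer strata")
        m1, m0 = cohort.Y[t1].mean(), cohort.Y[t0].mean()
        rows.append({"stratum": s, "n": int(mask.sum()),
                     "score_mean": float(score[mask].mean()),
                     "mean_treated": float(m1), "mean_control": float(m0),
                     "treatment_effect": float(m1 - m0)})
    return pd.DataFrame(rows)
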