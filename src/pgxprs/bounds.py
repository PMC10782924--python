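"""Recoverability limit of a disease PRS for drug response.

Among treated subjects the generative model Y = Gβ + Gα + ε gives, for the
oracle disease score S_dis = Gβ and standardized genotypes with LD matrix R,

    cor²(S_dis, Y) = h² · [β'R(β+α)]² / (β'Rβ · (β+α)'R(β+α)) ≤ h²,

by Cauchy-Schwarz in the R inner product, with equality iff the interaction
effects α are proportional to the main effects β.  A disease-GWAS-derived PRS
therefore cannot recover the full drug-response heritability unless every
causal variant's predictive effect is proportional to its prognostic one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LDBlockPanel, ValidationError

__all__ = ["ArchitectureSpec", "disease_prs_r2_limit", "proportionality_gap"]


@dataclass
class ArchitectureSpec:
    """True effect architecture: β, α, LD matrix R (dense or block panel), h²."""

    beta_true: np.ndarray
    alpha_true: np.ndarray
    R: np.ndarray | LDBlockPanel
    h2: float

    def __post_init__(self):
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.alpha_true = np.asarray(self.alpha_true, dtype=float)
        if self.beta_true.shape != self.alpha_true.shape:
            raise ValidationError("beta_true and alpha_true lengths differ")
        if not (0.0 <= self.h2 < 1.0):
            raise ValidationError("h2 must lie in [0, 1)")
        if not np.all(np.isfinite(self.beta_true)) or not np.all(np.isfinite(self.alpha_true)):
            raise ValidationError("effect vectors must be finite")


def _quad(R, x, y):
    """x' R y for dense R or a block panel."""
    if isinstance(R, LDBlockPanel):
        total = 0.0
        for sl, b in zip(R.block_slices(), R.blocks):
            total += float(x[sl] @ (b.R @ y[sl]))
        return total
    return float(x @ (np.asarray(R, dtype=float) @ y))


def proportionality_gap(beta: np.ndarray, alpha: np.ndarray, R) -> float:
    """1 − cos²-angle between β and β+α in the R metric; 0 iff α ∝ β."""
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    s = beta + alpha
    bb = _quad(R, beta, beta)
    ss = _quad(R, s, s)
    if bb <= 0 or ss <= 0:
        raise ValidationError("degenerate norms: beta'R beta and (beta+alpha)'R(beta+alpha) "
                              "must be positive")
    bs = _quad(R, beta, s)
    gap = 1.0 - bs ** 2 / (bb * ss)
    return float(min(max(gap, 0.0), 1.0))


def disease_prs_r2_limit(spec: ArchitectureSpec) -> dict:
    """Treated-arm cor²(S_dis, Y) for the oracle disease PRS, and the h² bound.

    Returns ``{"r2", "bound", "fraction_lost"}``; guarantees r2 ≤ h² up to
    1e-12.  Raises if β ≡ 0 (the disease score is degenerate).
    """
    if not np.any(spec.beta_true):
        raise ValidationError("beta_true is identically zero: S_dis degenerate, "
                              "correlation undefined")
    gap = proportionality_gap(spec.beta_true, spec.alpha_true, spec.R)
    r2 = spec.h2 * (1.0 - gap)
    r2 = min(r2, spec.h2)
    return {"r2": float(r2), "bound": float(spec.h2),
            "fraction_lost": float(gap)}
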