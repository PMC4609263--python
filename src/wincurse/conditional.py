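"""Conditional-likelihood "compromise" estimator for one selected SNP.

Conditions the normal approximation of the logHR estimator on its own
selection event |beta_hat / se| > c, where c is the two-sided Wald cutoff.
The compromise estimate is the average of the conditional maximum-likelihood
estimate (CMLE) and the mean of the normalised conditional likelihood (MCL);
it corrects threshold-selection bias for a single SNP but, unlike the
genome-wide bootstrap, knows nothing about ranking competition among SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ConditionalModel",
    "conditional_loglik",
    "cmle",
    "mcl_mean",
    "compromise_estimate",
]

GRID_POINTS = 4001
GRID_HALF_WIDTH = 8.0  # in units of se, either side of beta_hat


@dataclass(frozen=True)
class ConditionalModel:
    """Summary statistics of a selected SNP: estimate, SE and selection cutoff."""

    beta_hat: float
    se: float
    c: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if abs(self.beta_hat / self.se) <= self.c:
            raise ValueError(
                "conditional model requires a selected SNP: |beta_hat/se| > c"
            )

    @classmethod
    def from_alpha(cls, beta_hat: float, se: float, alpha: float) -> "ConditionalModel":
        return cls(beta_hat, se, float(stats.norm.ppf(1.0 - alpha / 2.0)))


def conditional_loglik(beta, model: ConditionalModel):
    """Log density of beta_hat at candidate beta, conditioned on selection.

    log phi((beta_hat - beta)/se)/se - log[1 - Phi(c - beta/se) + Phi(-c - beta/se)].
    Vectorised over ``beta``.
    """
    b = np.asarray(beta, dtype=float)
    z = (model.beta_hat - b) / model.se
    log_num = stats.norm.logpdf(z) - np.log(model.se)
    theta = b / model.se
    psel = stats.norm.sf(model.c - theta) + stats.norm.cdf(-model.c - theta)
    return log_num - np.log(psel)


def cmle(model: ConditionalModel) -> float:
    """Conditional maximum-likelihood estimate by bounded 1-D maximisation."""
    lo = model.beta_hat - GRID_HALF_WIDTH * model.se
    hi = model.beta_hat + GRID_HALF_WIDTH * model.se
    res = optimize.minimize_scalar(
        lambda b: -conditional_loglik(b, model),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def mcl_mean(model: ConditionalModel, n_grid: int = GRID_POINTS) -> float:
    """Mean of the normalised conditional likelihood on a trapezoidal grid."""
    grid = np.linspace(
        model.beta_hat - GRID_HALF_WIDTH * model.se,
        model.beta_hat + GRID_HALF_WIDTH * model.se,
        n_grid,
    )
    ll = conditional_loglik(grid, model)
    w = np.exp(ll - ll.max())
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite conditional-likelihood weights")
    denom = np.trapezoid(w, grid)
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("conditional likelihood integrates to zero")
    return float(np.trapezoid(grid * w, grid) / denom)


def compromise_estimate(model: ConditionalModel) -> float:
    """(CMLE + MCL mean) / 2 — the recommended single-SNP shrinkage estimate."""
    return 0.5 * (cmle(model) + mcl_mean(model))
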