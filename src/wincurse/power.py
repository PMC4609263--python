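"""Analytic power, required events, and expected selection bias for a Cox SNP test.

Under an additive Cox PH model, the Wald statistic for a SNP with logHR beta,
MAF p and D observed events is approximately normal with mean
beta * sqrt(D * 2p(1-p)) (Hardy-Weinberg genotypic variance 2p(1-p)), giving
the one-tail approximation

    power = Phi(|beta| * sqrt(D * 2p(1-p)) - z_{1-alpha/2})

for a two-sided level-alpha test. The same normal model yields a closed form
for the expected magnitude of a logHR estimate conditional on passing the
threshold (the winner's-curse selection bias): the bias grows with a stricter
threshold and lower MAF, and vanishes as power approaches one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerQuery",
    "analytic_power",
    "required_events",
    "expected_selection_bias",
]


@dataclass(frozen=True)
class PowerQuery:
    """Design point: logHR magnitude, MAF, number of events, two-sided alpha."""

    beta: float
    maf: float
    events: int
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5]: {self.maf}")
        if self.events < 1:
            raise ValueError("events must be a positive integer")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def genotypic_variance(self) -> float:
        return 2.0 * self.maf * (1.0 - self.maf)

    @property
    def se(self) -> float:
        """Approximate SE of the logHR estimate: 1/sqrt(D * 2p(1-p))."""
        return 1.0 / np.sqrt(self.events * self.genotypic_variance)


def analytic_power(q: PowerQuery) -> float:
    """Phi(|beta| sqrt(D 2p(1-p)) - z_{1-alpha/2})."""
    z = stats.norm.ppf(1.0 - q.alpha / 2.0)
    ncp = abs(q.beta) * np.sqrt(q.events * q.genotypic_variance)
    return float(stats.norm.cdf(ncp - z))


def required_events(
    beta: float, maf: float, target_power: float, alpha: float = 0.01
) -> int:
    """Smallest number of events D with analytic power >= target_power."""
    if beta == 0:
        raise ValueError("beta = 0: target power unattainable")
    if not (alpha < target_power < 1.0):
        raise ValueError("target_power must be in (alpha, 1)")
    v = 2.0 * maf * (1.0 - maf)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_p = stats.norm.ppf(target_power)
    d = int(np.ceil((z_a + z_p) ** 2 / (beta**2 * v)))
    d = max(d, 1)
    # guard the ceil against floating error: enforce minimality exactly
    while analytic_power(PowerQuery(beta, maf, d, alpha)) < target_power:
        d += 1
    while d > 1 and analytic_power(PowerQuery(beta, maf, d - 1, alpha)) >= target_power:
        d -= 1
    return d


def expected_selection_bias(q: PowerQuery) -> float:
    """Expected bias of the positively oriented logHR estimate given selection.

    With beta_hat ~ N(beta, se^2) and two-sided selection |beta_hat| > c*se,
    the selected estimate (oriented to the positive direction, as null SNPs
    are after recoding) has expectation

        E[|beta_hat| : |beta_hat| > c se] =
            [beta (1 - Phi(c-t) - Phi(-c-t)) + se (phi(c-t) + phi(c+t))] / P

    with t = beta/se and P = 1 - Phi(c-t) + Phi(-c-t); the bias is that
    expectation minus beta. Always non-negative; tends to 0 as power -> 1.
    """
    se = q.se
    c = stats.norm.ppf(1.0 - q.alpha / 2.0)
    t = abs(q.beta) / se
    p_sel = stats.norm.sf(c - t) + stats.norm.cdf(-c - t)
    num = abs(q.beta) * (1.0 - stats.norm.cdf(c - t) - stats.norm.cdf(-c - t)) + se * (
        stats.norm.pdf(c - t) + stats.norm.pdf(c + t)
    )
    bias = num / p_sel - abs(q.beta)
    return float(max(bias, 0.0))
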