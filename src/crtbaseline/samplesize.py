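"""Clusters per arm and achieved power from a variance multiplier.

With ``Var(theta_hat) = multiplier * sigma^2 / J``, a two-sided level-alpha
test of the treatment effect attains power ``1 - beta`` against a
standardised effect ``theta* / sigma`` when

    J >= multiplier * (sigma / theta*)^2 * (z_{1-alpha/2} + z_{1-beta})^2

using standard-normal centiles ``z_p``.  Normal-approximation power only; no
small-sample degrees-of-freedom correction is applied, though results carry a
reminder that designs with few clusters may warrant one or more extra
clusters per arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["PowerQuery", "ClusterRequirement", "required_clusters", "achieved_power"]

SMALL_CLUSTER_ADVICE = (
    "normal-approximation sample size; with small numbers of clusters it may "
    "be wise to add one or more clusters per arm"
)


@dataclass(frozen=True)
class PowerQuery:
    """Standardised effect size theta*/sigma, significance level and target power."""

    effect_std: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not self.effect_std > 0.0:
            raise ValueError(f"effect_std must be positive, got {self.effect_std}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must lie in (0, 1), got {self.power}")
        if self.power <= self.alpha / 2.0:
            raise ValueError(
                f"target power ({self.power}) must exceed alpha/2 ({self.alpha / 2})"
            )


@dataclass(frozen=True)
class ClusterRequirement:
    """Required clusters per arm (ceiling) with the unrounded value alongside."""

    clusters: int
    exact: float
    advice: str = SMALL_CLUSTER_ADVICE

    def __int__(self) -> int:
        return self.clusters


def required_clusters(multiplier: float, query: PowerQuery) -> ClusterRequirement:
    """Clusters per arm needed to hit the target power.

    ``J`` is the ceiling of ``multiplier / effect_std^2 * (z_{1-alpha/2} +
    z_{1-beta})^2``; the unrounded value is reported alongside.
    """
    if not multiplier > 0.0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    z = norm.ppf(1.0 - query.alpha / 2.0) + norm.ppf(query.power)
    exact = multiplier * z**2 / query.effect_std**2
    return ClusterRequirement(clusters=math.ceil(exact - 1e-9), exact=exact)


def achieved_power(
    j_clusters: int, multiplier: float, effect_std: float, alpha: float = 0.05
) -> float:
    """Power achieved by ``J`` clusters per arm (two-sided level-alpha test)."""
    if j_clusters != int(j_clusters) or j_clusters < 1:
        raise ValueError(f"j_clusters must be a positive integer, got {j_clusters!r}")
    if not multiplier > 0.0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    if not effect_std > 0.0:
        raise ValueError(f"effect_std must be positive, got {effect_std}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return float(
        norm.cdf(effect_std * math.sqrt(j_clusters / multiplier) - norm.ppf(1.0 - alpha / 2.0))
    )
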