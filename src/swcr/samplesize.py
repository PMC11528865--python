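"""Clusters required and power, from the variance multiplier theta.

With ``Var(delta_hat) = theta * sigma^2 / J``, the normal-approximation
sample-size identity gives the number of clusters needed to detect an
effect ``delta*`` with a two-sided level-``alpha`` Wald test:

    J >= (z_{1-alpha/2} + z_{power})^2 * (sigma / delta*)^2 * theta

J is then rounded up to the next multiple of the number of sequences
(default 3, matching equal allocation). No small-sample or
degrees-of-freedom correction is applied; quantiles are from the standard
normal at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.stats import norm

__all__ = ["SampleSizeSpec", "clusters_required", "power_given_clusters"]

#: slack before ceiling, so bounds within floating noise of an exact
#: multiple are not bumped a whole multiple upward
_CEIL_SLACK = 1e-9


@dataclass(frozen=True)
class SampleSizeSpec:
    """Target effect, outcome SD, power and test level for a sample size.

    ``round_multiple`` is the integer the cluster count is rounded up to
    (3 for three equally weighted sequences). For unequal middle-sequence
    weight ``w`` the real-valued bound is the meaningful quantity, since
    proportions ``(1-w)/2 : w : (1-w)/2`` need not divide any integer J.
    """

    delta_star: float
    sigma: float
    power: float = 0.80
    alpha: float = 0.05
    round_multiple: int = 3

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")
        if not (0.0 < self.power < 1.0):
            raise ValueError(f"power must be in (0, 1), got {self.power!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha!r}")
        if not (isinstance(self.round_multiple, int) and self.round_multiple >= 1):
            raise ValueError("round_multiple must be a positive integer")


def cluster_bound(theta: float, spec: SampleSizeSpec) -> float:
    """The real-valued lower bound on J, before rounding."""
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta!r}")
    if spec.delta_star == 0:
        raise ValueError("delta_star must be non-zero for a sample size")
    z = norm.ppf(1.0 - spec.alpha / 2.0) + norm.ppf(spec.power)
    return z**2 * (spec.sigma / spec.delta_star) ** 2 * theta


def clusters_required(theta: float, spec: SampleSizeSpec) -> int:
    """Smallest multiple of ``spec.round_multiple`` meeting the J bound."""
    bound = cluster_bound(theta, spec)
    k = spec.round_multiple
    return max(k * math.ceil(bound / k - _CEIL_SLACK), k)


def power_given_clusters(theta: float, J: int, spec: SampleSizeSpec) -> float:
    """Power of the two-sided level-``alpha`` Wald test with J clusters.

    ``power = Phi(|delta*| / (sigma * sqrt(theta / J)) - z_{1-alpha/2})``;
    the far-tail rejection probability is neglected, so at ``delta* -> 0``
    this tends to ``alpha / 2`` (one tail). Inverse-consistent with
    :func:`clusters_required`.
    """
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta!r}")
    if J < 1:
        raise ValueError(f"J must be at least 1, got {J!r}")
    se = spec.sigma * math.sqrt(theta / J)
    return float(norm.cdf(abs(spec.delta_star) / se - norm.ppf(1.0 - spec.alpha / 2.0)))
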