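"""A-priori power for two-sample MR with a binary outcome.

Follows the standard non-centrality argument for an instrumental-variable
test of a log odds ratio: with total outcome sample size ``N``, case
fraction ``p`` and instrument-explained exposure variance ``R^2``, the MR
z-statistic for a causal log OR ``b`` has approximate mean
``b * sqrt(N * R^2 * p * (1 - p))``. Inverting at significance ``alpha``
and target power gives the minimum detectable OR

    OR_min = exp[ (z_{1-alpha/2} + z_{power}) / sqrt(N R^2 p(1-p)) ].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class PowerSpec:
    """Design of one MR power calculation.

    ``r2`` is the proportion of exposure variance explained by the genetic
    instrument (liability scale for binary exposures); ``alpha`` is the
    two-sided significance level and ``power`` the target power.
    """

    r2: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.r2 < 1.0:
            raise ConfigurationError("r2 must lie in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigurationError("case and control counts must be positive")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise ConfigurationError("alpha and power must lie in (0, 1)")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n


def _design_sd(spec: PowerSpec) -> float:
    p = spec.case_fraction
    if p <= 0.0 or p >= 1.0:
        raise ConfigurationError("degenerate case fraction")
    return float(np.sqrt(spec.n * spec.r2 * p * (1.0 - p)))


def min_detectable_or(spec: PowerSpec) -> float:
    """Smallest odds ratio (> 1) detectable at the design's alpha and power."""
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_power = stats.norm.ppf(spec.power)
    return float(np.exp((z_alpha + z_power) / _design_sd(spec)))


def power_at_or(spec: PowerSpec, or_alt: float) -> float:
    """Power to detect a given alternative odds ratio at the design's alpha.

    By convention an alternative of exactly OR = 1 returns ``alpha / 2``,
    the limit of the formula as the effect vanishes.
    """
    if or_alt <= 0.0:
        raise ConfigurationError("or_alt must be positive")
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = abs(np.log(or_alt)) * _design_sd(spec)
    return float(stats.norm.cdf(ncp - z_alpha))
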