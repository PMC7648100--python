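"""Fixed-effect heterogeneity between Crohn's disease and ulcerative colitis estimates.

Crohn's disease (CD) and ulcerative colitis (UC) are the two main IBD
subtypes; an exposure may act on them in opposite directions (e.g. adiposity
raises CD risk while lowering UC risk). Given the per-subtype causal
estimates for one exposure, the fixed-effect Cochran Q on 1 degree of
freedom tests whether the two log odds ratios share a common value.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .estimators import MrEstimate
from .exceptions import ConfigurationError


@dataclass(frozen=True)
class SubtypeHetResult:
    """Q statistic (1 df), its p-value, and the pooled fixed-effect estimate."""

    q: float
    df: int
    pvalue: float
    pooled: float


def disease_heterogeneity(est_cd: MrEstimate, est_uc: MrEstimate) -> SubtypeHetResult:
    """Fixed-effect Q test comparing the CD and UC causal estimates.

    The pooled value is the inverse-variance-weighted mean of the two
    log-ORs; Q sums the squared standardized deviations from it and is
    referred to chi-square with 1 df.
    """
    if est_cd.se <= 0 or est_uc.se <= 0:
        raise ConfigurationError("both subtype estimates need positive SEs")
    w_cd = 1.0 / est_cd.se**2
    w_uc = 1.0 / est_uc.se**2
    pooled = (w_cd * est_cd.theta + w_uc * est_uc.theta) / (w_cd + w_uc)
    q = w_cd * (est_cd.theta - pooled) ** 2 + w_uc * (est_uc.theta - pooled) ** 2
    return SubtypeHetResult(q=float(q), df=1, pvalue=float(stats.chi2.sf(q, 1)), pooled=float(pooled))


def estimate_from_or_ci(
    or_value: float, ci_low: float, ci_high: float, method: str = "ml", n_snp: int = 0
) -> MrEstimate:
    """Reconstruct a log-scale estimate from a printed OR and 95% CI.

    The SE is recovered from the CI width on the log scale assuming the
    symmetric normal interval ``theta +/- 1.96 se``; useful for re-testing
    published forest-plot rows.
    """
    import math

    from .estimators import Z_95, _estimate

    theta = math.log(or_value)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    return _estimate(method, theta, se, n_snp)
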