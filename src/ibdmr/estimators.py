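"""Core two-sample MR estimators.

All estimators consume a :class:`~ibdmr.summary_io.HarmonizedInstrument`
(per-SNP exposure betas ``x`` with SEs ``sx`` and outcome log-odds ``y``
with SEs ``sy``) and return a causal log-odds ratio per SD of exposure.

The headline estimator is the bivariate-normal maximum-likelihood model:
observed ``x_j ~ N(xi_j, sx_j^2)`` and ``y_j ~ N(theta * xi_j, sy_j^2)``
independently, with the true instrument effects ``xi_j`` profiled out.
It accounts for uncertainty in both samples; the inverse-variance-weighted
(IVW) fit is its limit when exposure SEs vanish. MR-Egger, the weighted
median and the mode-based estimate serve as pleiotropy-robust sensitivity
analyses, and Cochran's Q quantifies per-SNP heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .exceptions import (
    ConvergenceError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .summary_io import HarmonizedInstrument

Z_95 = stats.norm.ppf(0.975)

#: Iteration cap for the profile-likelihood optimizer.
ML_MAX_ITER = 500

#: Default parametric-bootstrap replicates for median/mode SEs.
N_BOOT_DEFAULT = 1000


@dataclass(frozen=True)
class MrEstimate:
    """A causal effect estimate on the log-odds-per-SD scale.

    ``or_scale`` is the componentwise exponential of
    ``(theta, ci_low, ci_high)``, i.e. the odds ratio and its 95% CI.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (math.exp(self.theta), math.exp(self.ci_low), math.exp(self.ci_high))


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the intercept test for directional pleiotropy."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_p: float


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity statistic across per-SNP Wald ratios."""

    q: float
    df: int
    pvalue: float


def _estimate(method: str, theta: float, se: float, n_snp: int) -> MrEstimate:
    """Assemble an MrEstimate with a symmetric 95% CI and normal p-value."""
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(theta) / se)
        p = max(p, np.nextafter(0.0, 1.0))
    else:
        p = 1.0 if theta == 0 else np.nextafter(0.0, 1.0)
    return MrEstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z_95 * se),
        ci_high=float(theta + Z_95 * se),
        pvalue=float(min(p, 1.0)),
        n_snp=n_snp,
    )


def wald_ratios(
    inst: HarmonizedInstrument, second_order: bool = False
) -> list[tuple[float, float]]:
    """Per-SNP causal estimates ``theta_j = y_j / x_j`` with delta-method SEs.

    The first-order SE ``sy_j / |x_j|`` is the default, matching the
    weighting regime of the likelihood model; ``second_order=True`` adds the
    exposure-uncertainty term ``y_j^2 sx_j^2 / x_j^4`` under the square root.
    """
    zeros = [r for r, xj in zip(inst.rsids, inst.x) if xj == 0.0]
    if zeros:
        raise DegenerateInstrumentError(f"exposure beta is zero for SNP(s) {zeros}")
    theta = inst.y / inst.x
    if second_order:
        se = np.sqrt(inst.sy**2 / inst.x**2 + inst.y**2 * inst.sx**2 / inst.x**4)
    else:
        se = inst.sy / np.abs(inst.x)
    return list(zip(theta.tolist(), se.tolist()))


def _profile_objective(theta: float, inst: HarmonizedInstrument) -> float:
    # -2 log-likelihood profiled over the latent instrument effects xi_j:
    # min over xi of (x-xi)^2/sx^2 + (y-theta*xi)^2/sy^2 has this closed form.
    return float(np.sum((inst.y - theta * inst.x) ** 2 / (inst.sy**2 + theta**2 * inst.sx**2)))


def ml_estimate(inst: HarmonizedInstrument) -> MrEstimate:
    """Likelihood-based MR estimate (bivariate-normal measurement model).

    The observed per-SNP effects are modelled as ``x_j ~ N(xi_j, sx_j^2)``
    and ``y_j ~ N(theta xi_j, sy_j^2)``, independent between the two GWAS
    samples. Profiling out the nuisance ``xi_j`` leaves a one-dimensional
    objective ``sum_j (y_j - theta x_j)^2 / (sy_j^2 + theta^2 sx_j^2)``
    minimized numerically. The SE comes from the observed information
    (curvature) of the profile likelihood at the optimum.
    """
    if inst.n_snp < 1:
        raise InsufficientInstrumentsError("ml_estimate requires at least 1 SNP")

    # IVW start, then bracketed scalar minimization of the profile deviance.
    w = 1.0 / inst.sy**2
    denom = float(np.sum(w * inst.x**2))
    start = float(np.sum(w * inst.x * inst.y)) / denom if denom > 0 else 0.0
    span = 10.0 * (1.0 + abs(start))
    res = optimize.minimize_scalar(
        _profile_objective,
        args=(inst,),
        bounds=(start - span, start + span),
        method="bounded",
        options={"maxiter": ML_MAX_ITER, "xatol": 1e-12},
    )
    if not res.success:
        raise ConvergenceError(f"profile-likelihood optimization failed: {res.message}")
    theta = float(res.x)

    # Observed information of the profile: L = exp(-f/2), so I = f''/2.
    h = 1e-5 * (1.0 + abs(theta))
    f2 = (
        _profile_objective(theta + h, inst)
        - 2.0 * _profile_objective(theta, inst)
        + _profile_objective(theta - h, inst)
    ) / h**2
    if f2 <= 0:
        raise ConvergenceError("profile likelihood has non-positive curvature at optimum")
    se = math.sqrt(2.0 / f2)
    return _estimate("ml", theta, se, inst.n_snp)


def ivw_estimate(inst: HarmonizedInstrument) -> MrEstimate:
    """Inverse-variance-weighted estimate: zero-intercept weighted regression.

    Regresses ``y`` on ``x`` through the origin with weights ``1/sy_j^2``
    and reports the fixed-effect SE ``1/sqrt(sum w x^2)``. Ignores exposure
    uncertainty; used as the reference estimator inside MR-PRESSO and as the
    vanishing-``sx`` limit of :func:`ml_estimate`.
    """
    if inst.n_snp < 2:
        raise InsufficientInstrumentsError("ivw_estimate requires at least 2 SNPs")
    w = 1.0 / inst.sy**2
    sxx = float(np.sum(w * inst.x**2))
    theta = float(np.sum(w * inst.x * inst.y)) / sxx
    se = math.sqrt(1.0 / sxx)
    return _estimate("ivw", theta, se, inst.n_snp)


def egger_estimate(inst: HarmonizedInstrument) -> EggerResult:
    """MR-Egger regression: slope plus intercept test for directional pleiotropy.

    Each SNP is first re-signed so its exposure effect is non-negative (the
    estimator is defined up to allele orientation), then ``y = a + theta x``
    is fit by weighted least squares with weights ``1/sy^2``. A nonzero
    intercept indicates unbalanced horizontal pleiotropy; its two-sided
    p-value uses the t distribution with J-2 df.
    """
    if inst.n_snp < 3:
        raise InsufficientInstrumentsError("egger_estimate requires at least 3 SNPs")
    sign = np.where(inst.x < 0, -1.0, 1.0)
    x = inst.x * sign
    y = inst.y * sign
    fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / inst.sy**2).fit()
    alpha, theta = fit.params
    alpha_se, theta_se = fit.bse
    slope = _estimate("egger", float(theta), float(theta_se), inst.n_snp)
    return EggerResult(
        slope=slope,
        intercept=float(alpha),
        intercept_se=float(alpha_se),
        intercept_p=float(fit.pvalues[0]),
    )


def _ratio_weights(inst: HarmonizedInstrument) -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios and normalized first-order inverse-variance weights."""
    theta = inst.y / inst.x
    w = (inst.x / inst.sy) ** 2
    return theta, w / w.sum()


def weighted_median_point(inst: HarmonizedInstrument) -> float:
    """Weighted median of the per-SNP Wald ratios.

    Ratios are sorted ascending; with normalized weights ``w_(j)`` the
    cumulative mid-weights are ``p_j = sum_{k<=j} w_(k) - w_(j)/2`` and the
    estimate interpolates theta linearly at ``p = 0.5``. Consistent when at
    least half the weight comes from valid instruments.
    """
    theta, w = _ratio_weights(inst)
    order = np.argsort(theta, kind="stable")
    theta_s, w_s = theta[order], w[order]
    p = np.cumsum(w_s) - 0.5 * w_s
    return float(np.interp(0.5, p, theta_s))


def _bootstrap_se(
    inst: HarmonizedInstrument,
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap SE: resample betas from their sampling normals."""
    rng = np.random.default_rng(seed)
    J = inst.n_snp
    xs = rng.normal(inst.x, inst.sx, size=(n_boot, J))
    ys = rng.normal(inst.y, inst.sy, size=(n_boot, J))
    est = np.empty(n_boot)
    for b in range(n_boot):
        boot = HarmonizedInstrument(
            rsids=inst.rsids, x=xs[b], sx=inst.sx, y=ys[b], sy=inst.sy, flags=inst.flags
        )
        est[b] = point_fn(boot)
    return float(est.std(ddof=1))


def weighted_median_estimate(
    inst: HarmonizedInstrument, n_boot: int = N_BOOT_DEFAULT, seed: int = 0
) -> MrEstimate:
    """Weighted-median MR estimate with a parametric-bootstrap SE."""
    if inst.n_snp < 3:
        raise InsufficientInstrumentsError("weighted_median_estimate requires at least 3 SNPs")
    theta = weighted_median_point(inst)
    se = _bootstrap_se(inst, weighted_median_point, n_boot, seed)
    return _estimate("weighted_median", theta, se, inst.n_snp)


#: Grid resolution for locating the kernel-density argmax.
MODE_GRID_POINTS = 10_000


def mode_point(inst: HarmonizedInstrument, phi: float = 1.0) -> float:
    """Mode of the inverse-variance-weighted kernel density of Wald ratios.

    A normal kernel with the modified Silverman bandwidth
    ``h = phi * 0.9 * min(weighted SD, weighted MAD / 0.6745) * J^(-1/5)``
    is placed at each ratio with normalized weights ``1/se_j^2``; the
    estimate is the density argmax located on a fine grid spanning the
    ratios plus three bandwidths. Identical ratios (zero bandwidth) return
    the common value.
    """
    theta, w = _ratio_weights(inst)
    if np.ptp(theta) == 0.0:
        return float(theta[0])
    mean = float(np.sum(w * theta))
    sd = math.sqrt(float(np.sum(w * (theta - mean) ** 2)))
    med = _weighted_quantile(theta, w, 0.5)
    mad = _weighted_quantile(np.abs(theta - med), w, 0.5) / 0.6745
    h = phi * 0.9 * min(sd, mad) * inst.n_snp ** (-1 / 5)
    if h <= 0.0:
        # Degenerate spread (e.g. half the ratios identical): fall back to SD.
        h = phi * 0.9 * sd * inst.n_snp ** (-1 / 5)
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, MODE_GRID_POINTS)
    dens = np.sum(w[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2), axis=0)
    return float(grid[int(np.argmax(dens))])


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(q * w.sum(), p, v))


def mode_estimate(
    inst: HarmonizedInstrument,
    phi: float = 1.0,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
) -> MrEstimate:
    """Mode-based MR estimate with a parametric-bootstrap SE.

    ``phi`` scales the kernel bandwidth (default 1). Robust when the largest
    group of SNPs sharing a causal effect are valid instruments.
    """
    if inst.n_snp < 3:
        raise InsufficientInstrumentsError("mode_estimate requires at least 3 SNPs")
    if not phi > 0:
        raise ValueError("phi must be > 0")
    theta_all = inst.y / inst.x
    if np.ptp(theta_all) == 0.0:
        return _estimate("mode", float(theta_all[0]), 0.0, inst.n_snp)
    theta = mode_point(inst, phi)
    se = _bootstrap_se(inst, lambda b: mode_point(b, phi), n_boot, seed)
    return _estimate("mode", theta, se, inst.n_snp)


def cochran_q(inst: HarmonizedInstrument) -> QResult:
    """Cochran's Q across Wald ratios with weights ``(x_j/sy_j)^2``.

    Q is referred to a chi-square with J-1 df; large values signal
    heterogeneity between SNP-level causal estimates, i.e. likely
    horizontal pleiotropy.
    """
    if inst.n_snp < 2:
        raise InsufficientInstrumentsError("cochran_q requires at least 2 SNPs")
    theta = inst.y / inst.x
    w = (inst.x / inst.sy) ** 2
    theta_ivw = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_ivw) ** 2))
    df = inst.n_snp - 1
    return QResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))
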