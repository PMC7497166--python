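"""Causal-effect estimators and instrument diagnostics for two-sample MR.

Estimators operate on a :class:`~adipomr.harmonisation.HarmonisedSet` of
per-SNP (β_GX, se_GX, β_GY, se_GY) pairs:

* Wald ratio for single-SNP instruments, with a two-term first-order delta
  SE: ``sqrt(se_GY²/β_GX² + β_GY²·se_GX²/β_GX⁴)``. No covariance term is
  included — the two-sample design makes the two estimates independent.
* IVW: weighted regression of β_GY on β_GX through the origin with weights
  1/se_GY². The multiplicative random-effects variant scales the fixed-effect
  SE by φ = max(1, sqrt(RSS_w/(k−1))); the floor at 1 is the underdispersion
  rule "the residual standard error is never allowed below 1".
* Correlation-adjusted IVW for instruments of correlated variants, using the
  outcome-SE-scaled LD covariance Ω with the same φ-floor rule.
* MR-Egger regression (weighted, free intercept, SNPs oriented so β_GX ≥ 0);
  the intercept is the directional-pleiotropy test. The slope SE carries the
  φ floor; the intercept test uses the unfloored residual scale so it stays
  exactly t(k−2)-calibrated under the no-pleiotropy null.
* Weighted median with a seeded parametric bootstrap SE.
* Leave-one-out re-estimation, R²/F instrument-strength diagnostics, and
  odds-ratio conversion.

P-values use the normal reference except MR-Egger, which uses t with k−2 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import ConditioningError, DegenerateInstrumentError, DomainError, EmptyInputError
from .harmonisation import HarmonisedSet
from .sumstats_io import AssociationRecord

Z975 = stats.norm.ppf(0.975)
_P_FLOOR = 5e-324  # smallest positive subnormal; keeps p in (0, 1] when z is huge

METHODS = ("wald", "ivw_fe", "ivw_re", "ivw_corr", "egger_slope", "weighted_median")


def two_sided_p(z: float) -> float:
    p = 2.0 * stats.norm.sf(abs(z))
    return p if p > 0.0 else _P_FLOOR


@dataclass(frozen=True)
class MREstimate:
    """A method-tagged causal estimate with its Wald interval and diagnostics.

    ``dispersion`` is the residual scale φ actually applied to the SE (1 for
    fixed-effect and single-SNP estimates); ``cochran_q`` is the weighted
    residual sum of squares, i.e. Cochran's heterogeneity statistic, when the
    estimator defines one.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    dispersion: float = 1.0
    cochran_q: float | None = None
    exposure: str = ""
    outcome: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DomainError(f"unknown method tag {self.method!r}")
        if not (self.se > 0):
            raise DomainError("estimate must carry a positive standard error")
        if not (self.ci_low < self.beta < self.ci_high):
            raise DomainError("confidence interval must bracket the estimate")
        if not (0.0 < self.pvalue <= 1.0):
            raise DomainError("pvalue must lie in (0, 1]")

    def with_labels(self, exposure: str, outcome: str) -> "MREstimate":
        return replace(self, exposure=exposure, outcome=outcome)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope estimate plus the intercept directional-pleiotropy test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass(frozen=True)
class StrengthStats:
    """Instrument strength: variance explained R² and the F-statistic."""

    r2: float
    f_stat: float
    n: float
    k: int

    def __post_init__(self) -> None:
        expected = self.r2 * (self.n - self.k - 1) / (self.k * (1.0 - self.r2))
        if abs(self.f_stat - expected) > 1e-9 * max(1.0, abs(expected)):
            raise DomainError("f_stat inconsistent with r2, n, k")


def _estimate(method: str, beta: float, se: float, k: int, *, phi: float = 1.0, q: float | None = None) -> MREstimate:
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        pvalue=two_sided_p(beta / se),
        n_snp=k,
        dispersion=phi,
        cochran_q=q,
    )


def wald_ratio(hset: HarmonisedSet) -> MREstimate:
    """Single-SNP causal estimate β_GY/β_GX with the delta-method SE."""
    if len(hset) != 1:
        raise EmptyInputError(f"wald_ratio needs exactly 1 SNP, got {len(hset)}")
    bx, sx = float(hset.beta_exposure[0]), float(hset.se_exposure[0])
    by, sy = float(hset.beta_outcome[0]), float(hset.se_outcome[0])
    if bx == 0.0:
        raise DegenerateInstrumentError("SNP-exposure effect is zero")
    beta = by / bx
    se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return _estimate("wald", beta, se, 1)


def ivw(hset: HarmonisedSet, effects: str = "multiplicative_random") -> MREstimate:
    """IVW estimate: origin-through weighted regression with weights 1/se_GY².

    ``effects`` is ``"fixed"`` or ``"multiplicative_random"``. A single-SNP set
    delegates to :func:`wald_ratio`. The random-effects SE is the fixed-effect
    SE times φ = max(1, sqrt(RSS_w/(k−1))); Cochran's Q (the weighted RSS) is
    reported either way.
    """
    if effects not in ("fixed", "multiplicative_random"):
        raise DomainError(f"unknown effects model {effects!r}")
    k = len(hset)
    if k < 1:
        raise EmptyInputError("ivw needs at least one SNP")
    if k == 1:
        return wald_ratio(hset)
    bx, by, sy = hset.beta_exposure, hset.beta_outcome, hset.se_outcome
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx * bx))
    if denom <= 0.0:
        raise DegenerateInstrumentError("all SNP-exposure effects are zero")
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = math.sqrt(1.0 / denom)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    phi_hat = math.sqrt(q / (k - 1))
    if effects == "fixed":
        return _estimate("ivw_fe", beta, se_fixed, k, phi=1.0, q=q)
    phi = max(1.0, phi_hat)
    return _estimate("ivw_re", beta, se_fixed * phi, k, phi=phi, q=q)


def ivw_correlated(
    hset: HarmonisedSet,
    effects: str = "multiplicative_random",
    ridge: float = 1e-8,
) -> MREstimate:
    """Correlation-adjusted IVW using Ω_ij = se_GY,i·se_GY,j·r_ij.

    The generalized weighted estimate is (xᵀΩ⁻¹x)⁻¹ xᵀΩ⁻¹y. A near-singular Ω
    gets ``ridge`` times the mean diagonal added once; if the condition number
    still exceeds 1e12 a :class:`~adipomr.errors.ConditioningError` is raised.
    """
    if effects not in ("fixed", "multiplicative_random"):
        raise DomainError(f"unknown effects model {effects!r}")
    k = len(hset)
    if k < 2:
        raise EmptyInputError("ivw_correlated needs at least 2 SNPs")
    if hset.ld is None:
        raise EmptyInputError("ivw_correlated needs an LD matrix on the harmonised set")
    sy = hset.se_outcome
    omega = np.outer(sy, sy) * hset.ld.r
    if np.linalg.cond(omega) > 1e12:
        omega = omega + ridge * float(np.mean(np.diag(omega))) * np.eye(k)
        if np.linalg.cond(omega) > 1e12:
            raise ConditioningError("outcome covariance is singular even after ridge adjustment")
    x, y = hset.beta_exposure, hset.beta_outcome
    oi_x = np.linalg.solve(omega, x)
    oi_y = np.linalg.solve(omega, y)
    bread = float(x @ oi_x)
    if bread <= 0.0:
        raise DegenerateInstrumentError("degenerate design under the LD-adjusted weighting")
    beta = float(x @ oi_y) / bread
    se_fixed = math.sqrt(1.0 / bread)
    resid = y - beta * x
    q = float(resid @ np.linalg.solve(omega, resid))
    if effects == "fixed":
        return _estimate("ivw_corr", beta, se_fixed, k, phi=1.0, q=q)
    phi = max(1.0, math.sqrt(q / (k - 1)))
    return _estimate("ivw_corr", beta, se_fixed * phi, k, phi=phi, q=q)


def mr_egger(hset: HarmonisedSet) -> EggerResult:
    """Weighted MR-Egger regression of β_GY on β_GX with a free intercept.

    SNPs are first oriented so every β_GX ≥ 0 (the estimator is invariant to
    per-SNP sign flips of the (β_GX, β_GY) pair). P-values use t with k−2 df.
    """
    k = len(hset)
    if k < 3:
        raise EmptyInputError("mr_egger needs at least 3 SNPs")
    sign = np.where(hset.beta_exposure < 0, -1.0, 1.0)
    bx = hset.beta_exposure * sign
    by = hset.beta_outcome * sign
    w = 1.0 / hset.se_outcome**2
    design = sm.add_constant(bx)
    fit = sm.WLS(by, design, weights=w).fit()
    intercept, slope = (float(v) for v in fit.params)
    # SEs on the unit-residual-variance scale: sqrt(diag((XᵀWX)⁻¹))
    xtwx_inv = np.linalg.inv(design.T @ (w[:, None] * design))
    se_unit = np.sqrt(np.diag(xtwx_inv))
    resid = by - fit.fittedvalues
    rss = float(np.sum(w * resid**2))
    sigma_hat = math.sqrt(rss / (k - 2))
    phi = max(1.0, sigma_hat)
    df = k - 2
    tq = stats.t.ppf(0.975, df)
    slope_se = float(se_unit[1]) * phi
    slope_p = float(2.0 * stats.t.sf(abs(slope / slope_se), df))
    slope_est = MREstimate(
        method="egger_slope",
        beta=slope,
        se=slope_se,
        ci_low=slope - tq * slope_se,
        ci_high=slope + tq * slope_se,
        pvalue=slope_p if slope_p > 0 else _P_FLOOR,
        n_snp=k,
        dispersion=phi,
        cochran_q=rss,
    )
    # intercept test on the unfloored residual scale: exactly t(k-2) under the null
    icpt_se = float(se_unit[0]) * max(sigma_hat, 1e-300)
    icpt_p = float(2.0 * stats.t.sf(abs(intercept / icpt_se), df)) if icpt_se > 0 else _P_FLOOR
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=icpt_se,
        intercept_pvalue=icpt_p if icpt_p > 0 else _P_FLOOR,
    )


def _ratio_weights(bx, sx, by, sy) -> tuple[np.ndarray, np.ndarray]:
    ratios = by / bx
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    return ratios, 1.0 / var


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / float(np.sum(weights))
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(hset: HarmonisedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median causal estimate (consistent when ≥50% of the weight is
    from valid instruments).

    Per-SNP ratio estimates are ordered; inverse-delta-variance weights are
    normalised and the estimate is linearly interpolated where the cumulative
    midpoint weight crosses 0.5. The SE is the SD of the estimator over
    ``n_boot`` parametric bootstrap draws (normal perturbations of β_GX and
    β_GY) under the given seed.
    """
    k = len(hset)
    if k < 3:
        raise EmptyInputError("weighted_median needs at least 3 SNPs")
    if n_boot < 2:
        raise DomainError("n_boot must be at least 2")
    bx, sx = hset.beta_exposure, hset.se_exposure
    by, sy = hset.beta_outcome, hset.se_outcome
    ratios, weights = _ratio_weights(bx, sx, by, sy)
    beta = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    bx_b = bx + rng.standard_normal((n_boot, k)) * sx
    by_b = by + rng.standard_normal((n_boot, k)) * sy
    boots = np.empty(n_boot)
    for b in range(n_boot):
        r_b, w_b = _ratio_weights(bx_b[b], sx, by_b[b], sy)
        boots[b] = _weighted_median_point(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    if se <= 0.0:
        raise DegenerateInstrumentError("bootstrap produced a zero-variance estimator")
    return _estimate("weighted_median", beta, se, k)


def leave_one_out(hset: HarmonisedSet) -> list[tuple[str, MREstimate]]:
    """Re-estimate with IVW (random effects) leaving each SNP out in turn."""
    k = len(hset)
    if k < 3:
        raise EmptyInputError("leave_one_out needs at least 3 SNPs")
    out = []
    for i in range(k):
        sub = hset.subset([j for j in range(k) if j != i])
        out.append((hset.snp_ids[i], ivw(sub)))
    return out


def instrument_strength(r2: float, n: float, k: int) -> StrengthStats:
    """F-statistic for an instrument: F = R²(n−k−1) / (k(1−R²))."""
    if not (0.0 <= r2 < 1.0):
        raise DomainError("r2 must lie in [0, 1)")
    if k < 1:
        raise DomainError("k must be at least 1")
    if n <= k + 1:
        raise DomainError("n must exceed k + 1")
    f = r2 * (n - k - 1) / (k * (1.0 - r2))
    return StrengthStats(r2=r2, f_stat=f, n=n, k=k)


def r2_from_sumstats(records: Sequence[AssociationRecord]) -> float:
    """Variance explained by independent SNPs: Σ 2·eaf·(1−eaf)·β².

    Valid when the exposure is in SD units; requires eaf on every record.
    """
    total = 0.0
    for r in records:
        if r.eaf is None:
            raise DomainError(f"cannot compute R²: SNP {r.snp_id} has no effect-allele frequency")
        total += 2.0 * r.eaf * (1.0 - r.eaf) * r.beta**2
    return total


def to_odds_ratio(estimate: MREstimate) -> tuple[float, float, float]:
    """Convert a log-odds estimate to (OR, 95% CI low, 95% CI high)."""
    return (
        math.exp(estimate.beta),
        math.exp(estimate.beta - Z975 * estimate.se),
        math.exp(estimate.beta + Z975 * estimate.se),
    )
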