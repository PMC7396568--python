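"""Mendelian-randomization estimators on summary statistics.

Implements the single-instrument Wald ratio (ratio of the outcome log
hazard ratio to the exposure log odds ratio), fixed-effect and
DerSimonian–Laird random-effects inverse-variance-weighted pooling,
Cochran's Q heterogeneity test, MR-Egger weighted regression with a free
intercept, the summed-T² instrument-strength statistic, and a variance
inflation for exposure/outcome sample overlap in one-sample designs.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .summaries import (
    EggerResult,
    OutcomeSummary,
    PooledEstimate,
    RatioEstimate,
    SnpSummary,
    StrengthReport,
    Z95,
    se_from_ci,
    se_from_p,
)

__all__ = [
    "wald_ratio",
    "ivw_pool",
    "cochran_q",
    "egger_regression",
    "instrument_strength",
    "overlap_adjust",
]


def wald_ratio(
    outcome: OutcomeSummary,
    exposure: SnpSummary,
    ci_method: Literal["ratio", "delta"] = "ratio",
    level: float = 0.95,
) -> RatioEstimate:
    """Single-instrument MR estimate: β_outcome / β_exposure.

    With the default ``ci_method="ratio"`` the confidence bounds are the
    outcome CI bounds raised to the power 1/β_exposure (equivalently the
    log bounds divided by β_exposure), sorted ascending — dividing by a
    negative exposure effect flips the interval.  Exposure-side
    uncertainty is ignored (first order); ``"delta"`` adds it via the
    delta method using a symmetric normal interval instead.
    """
    beta = exposure.beta_exp
    if beta == 0:
        raise ZeroDivisionError(
            f"{exposure.snp_id}: exposure effect is zero; Wald ratio undefined"
        )
    log_ratio = outcome.log_hr / beta
    if ci_method == "ratio":
        se = se_from_ci(outcome.ci_low, outcome.ci_high, level) / abs(beta)
        bounds = sorted(
            (math.log(outcome.ci_low) / beta, math.log(outcome.ci_high) / beta)
        )
        ci_low, ci_high = math.exp(bounds[0]), math.exp(bounds[1])
    elif ci_method == "delta":
        se_out = se_from_ci(outcome.ci_low, outcome.ci_high, level)
        se_exp = exposure.se_or_recover()
        se = math.sqrt(
            se_out**2 / beta**2 + outcome.log_hr**2 * se_exp**2 / beta**4
        )
        z = Z95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2.0)
        ci_low, ci_high = math.exp(log_ratio - z * se), math.exp(log_ratio + z * se)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RatioEstimate(
        snp_id=exposure.snp_id,
        log_ratio=log_ratio,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        phenotype=exposure.phenotype,
        subgroup=exposure.subgroup,
    )


def cochran_q(
    estimates: Sequence[RatioEstimate],
    pooled: PooledEstimate | float | None = None,
) -> tuple[float, int, float | None]:
    """Cochran's Q heterogeneity statistic for a set of ratio estimates.

    Returns ``(Q, df, p)``; with a single estimate Q is identically zero
    and the p-value is undefined (``None``), matching the "N/A" cells of
    study tables.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates")
    w = np.array([e.weight for e in estimates])
    r = np.array([e.log_ratio for e in estimates])
    if pooled is None:
        mu = float(np.sum(w * r) / np.sum(w))
    elif isinstance(pooled, PooledEstimate):
        mu = pooled.log_pooled
    else:
        mu = float(pooled)
    q = float(np.sum(w * (r - mu) ** 2))
    df = len(estimates) - 1
    p = float(stats.chi2.sf(q, df)) if df >= 1 else None
    return q, df, p


def ivw_pool(
    estimates: Sequence[RatioEstimate],
    rho: float = 0.0,
    method: Literal["fixed", "random"] = "fixed",
    level: float = 0.95,
) -> PooledEstimate:
    """Inverse-variance-weighted pool of single-instrument estimates.

    Fixed-effect by default: μ̂ = Σwᵢrᵢ/Σwᵢ with wᵢ = seᵢ⁻².  The
    ``"random"`` option applies the DerSimonian–Laird between-instrument
    variance.  ``rho`` applies the one-sample overlap variance inflation
    (see :func:`overlap_adjust`); the point estimate is rho-invariant.
    """
    if len(estimates) == 0:
        raise ValueError("cannot pool an empty list of estimates")
    for e in estimates:
        if e.se <= 0:
            raise ValueError(f"{e.snp_id}: se = 0 gives an infinite weight")
    w = np.array([e.weight for e in estimates])
    r = np.array([e.log_ratio for e in estimates])
    mu = float(np.sum(w * r) / np.sum(w))
    q, df, p_het = cochran_q(estimates, mu)
    label = "fixed-effect IVW"
    if method == "random":
        # DerSimonian–Laird moment estimator of the between-SNP variance
        tau2 = max(0.0, (q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w))) if df > 0 else 0.0
        w = 1.0 / (1.0 / w + tau2)
        mu = float(np.sum(w * r) / np.sum(w))
        label = "random-effects IVW (DerSimonian-Laird)"
    elif method != "fixed":
        raise ValueError(f"unknown pooling method {method!r}")
    se = float(np.sum(w)) ** -0.5
    z = Z95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2.0)
    if len(estimates) == 1:
        # n = 1 reduction: reproduce the component exactly, including its
        # (possibly asymmetric) ratio-method CI
        ci_low, ci_high = estimates[0].ci_low, estimates[0].ci_high
    else:
        ci_low, ci_high = math.exp(mu - z * se), math.exp(mu + z * se)
    pooled = PooledEstimate(
        log_pooled=mu,
        se_pooled=se,
        ci_low=ci_low,
        ci_high=ci_high,
        q_stat=q,
        q_df=df,
        p_het=p_het,
        n_snps=len(estimates),
        rho=0.0,
        method=label,
    )
    if rho != 0.0:
        pooled = overlap_adjust(pooled, rho, level=level)
    return pooled


def overlap_adjust(
    pooled: PooledEstimate, rho: float, level: float = 0.95
) -> PooledEstimate:
    """Inflate the pooled variance for exposure/outcome sample overlap.

    In a one-sample design the exposure and outcome scans share
    participants; ``rho`` is the (Spearman) correlation between the
    exposure phenotype and the outcome.  The variance is multiplied by
    f(ρ) = 1/(1−ρ²) — equal to 1 at ρ = 0 and increasing in |ρ| — a
    pragmatic reconstruction, applied to the SE and CI only; the point
    estimate is unchanged.
    """
    if abs(rho) > 1.0:
        raise ValueError(f"rho {rho!r} outside [-1, 1]")
    inflation = math.inf if abs(rho) == 1.0 else math.sqrt(1.0 / (1.0 - rho**2))
    se = pooled.se_pooled * inflation
    z = Z95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2.0)
    return replace(
        pooled,
        se_pooled=se,
        ci_low=math.exp(pooled.log_pooled - z * se),
        ci_high=math.exp(pooled.log_pooled + z * se),
        rho=rho,
    )


def egger_regression(
    pairs: Sequence[tuple[float, float, float]],
    snp_ids: Sequence[str] | None = None,
    intercept_reference: Literal["normal", "t"] = "normal",
    scale: Literal["fixed", "mult"] = "fixed",
) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure effects.

    ``pairs`` are harmonized ``(beta_exp, log_hr, se_log_hr)`` triples;
    weights are se⁻².  A free intercept absorbs directional pleiotropy:
    its two-sided p-value (normal reference by default, Student-t with
    n−2 df optionally) tests whether pleiotropic effects are skewed in
    one direction.  ``scale="fixed"`` uses the unscaled (X'WX)⁻¹
    standard errors consistent with fixed-effect IVW; ``"mult"`` applies
    the multiplicative overdispersion max(1, σ̂²).
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"MR-Egger needs at least 3 instruments, got {n}")
    bx = np.array([p[0] for p in pairs], dtype=float)
    by = np.array([p[1] for p in pairs], dtype=float)
    se = np.array([p[2] for p in pairs], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all outcome SEs must be positive")
    if np.ptp(bx) == 0:
        raise np.linalg.LinAlgError("all exposure effects equal: singular design")
    w = se**-2.0
    X = np.column_stack([np.ones(n), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    cov = np.linalg.inv(xtwx)
    if scale == "mult":
        resid = by - X @ coef
        sigma2 = float(np.sum(w * resid**2) / (n - 2))
        cov = cov * max(1.0, sigma2)
    elif scale != "fixed":
        raise ValueError(f"unknown scale {scale!r}")
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    z = coef[0] / se_int
    if intercept_reference == "t":
        p_int = float(2.0 * stats.t.sf(abs(z), df=n - 2))
    elif intercept_reference == "normal":
        p_int = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown intercept_reference {intercept_reference!r}")
    return EggerResult(
        intercept=float(coef[0]),
        se_intercept=se_int,
        p_intercept=p_int,
        slope=float(coef[1]),
        se_slope=se_slope,
        n_snps=n,
    )


def instrument_strength(
    snps: Sequence[SnpSummary], threshold: float = 10.0
) -> StrengthReport:
    """Summed-T² instrument strength against a conventional threshold.

    Per SNP, T² = (β_exp/se_exp)²; when the SE is unavailable it equals
    z², with z the two-sided normal quantile of the exposure p-value.
    Instruments are considered adequately strong when the sum exceeds
    the threshold (default 10 units).
    """
    per_snp: list[tuple[str, float]] = []
    for s in snps:
        if s.se_exp is not None and s.se_exp > 0:
            t2 = (s.beta_exp / s.se_exp) ** 2
        elif s.p_exp is not None:
            z = stats.norm.isf(s.p_exp / 2.0)
            t2 = float(z**2)
        else:  # pragma: no cover - SnpSummary validation forbids this
            raise ValueError(f"{s.snp_id}: neither se_exp nor p_exp available")
        per_snp.append((s.snp_id, t2))
    total = float(sum(t for _, t in per_snp))
    return StrengthReport(
        per_snp_t2=tuple(per_snp),
        total=total,
        threshold=threshold,
        passed=total > threshold,
    )
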