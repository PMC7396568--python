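"""Individual-level association scans.

Exposure side: per-SNP maximum-likelihood logistic regression of the
binary insulin-resistance phenotype on allele dosage plus covariates.
Outcome side: per-SNP Cox proportional-hazards regression (Efron tie
handling) of the right-censored colorectal-cancer outcome on dosage
plus covariates, with a scaled-Schoenfeld-residual check of the
proportional-hazards assumption.  Subgroup stratification follows the
study cut-offs: BMI 30 kg/m², 10 MET, 7% of calories from saturated
fat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .cohort import CohortTable
from .summaries import OutcomeSummary, SnpSummary, Z95

__all__ = [
    "FitResult",
    "logistic_scan",
    "cox_scan",
    "ph_check",
    "spearman_rho",
    "stratify",
    "STRATA_RULES",
]

#: Stratification cut-offs, as used for the study subgroups.
STRATA_RULES = {
    "bmi": ("bmi", 30.0, "obese", "non-obese"),
    "met": ("met", 10.0, "active", "inactive"),
    "sfa": ("sfa_pct", 7.0, "high-fat", "low-fat"),
}


@dataclass(frozen=True)
class FitResult:
    """One regression fit: log-OR or log-HR with Wald inference."""

    term: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    converged: bool


def _drop_degenerate(df: pd.DataFrame, cols: Sequence[str]) -> list[str]:
    keep = []
    for c in cols:
        if df[c].nunique() <= 1:
            warnings.warn(f"covariate {c!r} has zero variance; excluded", stacklevel=3)
        else:
            keep.append(c)
    return keep


def logistic_scan(
    cohort: CohortTable,
    snp_ids: Sequence[str] | None = None,
    covariates: Sequence[str] | None = None,
    phenotype: str = "FG",
    subgroup: str = "overall",
) -> list[SnpSummary]:
    """Per-SNP logistic regression of IR status on dosage + covariates.

    Non-converged or separated fits are reported with a warning and
    ``se_exp = None`` so that downstream stages can exclude them.
    """
    snp_ids = list(snp_ids) if snp_ids is not None else list(cohort.snp_cols)
    if phenotype not in cohort.ir_cols:
        raise KeyError(f"cohort has no IR status column for phenotype {phenotype!r}")
    y = cohort.data[cohort.ir_cols[phenotype]].to_numpy(dtype=float)
    covs = _drop_degenerate(cohort.data, list(covariates or []))
    out: list[SnpSummary] = []
    for snp in snp_ids:
        g = cohort.data[snp].to_numpy(dtype=float)
        X = sm.add_constant(
            np.column_stack([g] + [cohort.data[c].to_numpy(dtype=float) for c in covs]),
            has_constant="add",
        )
        beta, se, p, ok = math.nan, None, 1.0, False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            beta = float(fit.params[1])
            se = float(fit.bse[1])
            p = float(fit.pvalues[1])
            ok = bool(fit.mle_retvals.get("converged", True)) and np.isfinite(se) and se < 50
        except Exception as exc:
            warnings.warn(f"{snp}: logistic fit failed ({exc})", stacklevel=2)
        if not ok:
            warnings.warn(f"{snp}: logistic fit unreliable; flagged", stacklevel=2)
            se = None
            p = min(max(p, np.nextafter(0, 1)), 1.0)
        out.append(
            SnpSummary(
                snp_id=snp,
                chrom="NA",
                pos=0,
                ref_allele="N",
                alt_allele="N",
                alt_freq=float(np.mean(g) / 2.0),
                phenotype=phenotype,
                subgroup=subgroup,
                beta_exp=beta,
                se_exp=se,
                p_exp=min(max(p, 5e-324), 1.0),
            )
        )
    return out


def cox_scan(
    cohort: CohortTable,
    snp_ids: Sequence[str] | None = None,
    covariates: Sequence[str] | None = None,
) -> list[OutcomeSummary]:
    """Per-SNP Cox proportional-hazards fit of the CRC outcome.

    Efron's approximation handles ties.  Requires at least one event.
    """
    if cohort.n_events < 1:
        raise ValueError("no events in cohort; Cox model undefined")
    snp_ids = list(snp_ids) if snp_ids is not None else list(cohort.snp_cols)
    covs = _drop_degenerate(cohort.data, list(covariates or []))
    out: list[OutcomeSummary] = []
    for snp in snp_ids:
        df = cohort.data[[snp, *covs, cohort.time_col, cohort.event_col]]
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col=cohort.time_col, event_col=cohort.event_col)
            beta = float(cph.params_[snp])
            se = float(cph.standard_errors_[snp])
            p = float(cph.summary.loc[snp, "p"])
        except Exception as exc:
            warnings.warn(f"{snp}: Cox fit failed ({exc}); flagged", stacklevel=2)
            continue
        out.append(
            OutcomeSummary(
                snp_id=snp,
                log_hr=beta,
                ci_low=math.exp(beta - Z95 * se),
                ci_high=math.exp(beta + Z95 * se),
                p_out=min(max(p, 5e-324), 1.0),
            )
        )
    return out


def ph_check(
    cohort: CohortTable,
    covariates: Sequence[str],
    time_transform: str = "km",
) -> dict[str, tuple[float, float]]:
    """Proportional-hazards check via scaled Schoenfeld residuals.

    Fits a Cox model on the given columns and, per covariate, returns
    (rho, p): the correlation of the scaled Schoenfeld residuals with
    the (Kaplan–Meier-transformed by default) event times, and the
    chi-square test p-value.
    """
    if cohort.n_events < 2:
        raise ValueError("PH check needs at least 2 events")
    covs = _drop_degenerate(cohort.data, list(covariates))
    df = cohort.data[[*covs, cohort.time_col, cohort.event_col]]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=cohort.time_col, event_col=cohort.event_col)
        test = proportional_hazard_test(cph, df, time_transform=time_transform)
        resid = cph.compute_residuals(df, "scaled_schoenfeld")
    event_times = df.loc[resid.index, cohort.time_col].to_numpy()
    if time_transform == "km":
        # same transform lifelines applies: 1 - KM survival at the event time
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(
            df[cohort.time_col], df[cohort.event_col]
        ).survival_function_at_times(event_times).to_numpy()
        tt = 1.0 - km
    elif time_transform == "rank":
        tt = stats.rankdata(event_times)
    else:
        tt = event_times
    out: dict[str, tuple[float, float]] = {}
    for c in covs:
        rho = float(np.corrcoef(tt, resid[c].to_numpy())[0, 1])
        p = float(np.atleast_1d(test.summary.loc[c, "p"])[0])
        out[c] = (rho, p)
    return out


def spearman_rho(x, y) -> float | None:
    """Spearman rank correlation (mid-ranks for ties).

    Returns ``None`` with a warning when either vector is constant,
    where the rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return None
    return float(stats.spearmanr(x, y).statistic)


def stratify(cohort: CohortTable, rule: str) -> dict[str, CohortTable]:
    """Partition the cohort by a named cut-off rule.

    Rules: ``"bmi"`` (obese: BMI ≥ 30), ``"met"`` (active: MET ≥ 10),
    ``"sfa"`` (high-fat: ≥ 7.0% calories from saturated fat).  The
    boundary value goes to the ≥ side, as the cut-offs are printed.
    """
    if rule not in STRATA_RULES:
        raise KeyError(f"unknown stratification rule {rule!r}")
    col, cut, label_ge, label_lt = STRATA_RULES[rule]
    if col not in cohort.data.columns:
        raise ValueError(f"cohort lacks covariate {col!r} for rule {rule!r}")
    ge = cohort.data[col] >= cut
    return {label_ge: cohort.subset(ge), label_lt: cohort.subset(~ge)}
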