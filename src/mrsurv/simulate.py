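"""Synthetic cohorts with known ground truth.

Emulates the statistical structure of a postmenopausal one-sample MR
study: independent SNPs drawn under Hardy–Weinberg equilibrium with
rare-to-common alternative-allele frequencies, binary insulin-resistance
(IR) phenotypes (fasting glucose, fasting insulin, HOMA-IR) generated
from per-SNP logistic models, lifestyle covariates with the study's
stratification cut-offs, and right-censored colorectal-cancer event
times from an exponential proportional-hazards model.

The causal parameter θ is the log hazard ratio per unit increase in the
IR liability (log-odds) — the scale on which one-sample MR ratio
estimates are interpreted — so the pooled IVW estimate across the
instruments is a consistent estimator of θ when pleiotropy is absent.
Per-SNP direct outcome effects (pleiotropy) and a shared confounder can
be switched on to violate the MR assumptions on purpose.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .cohort import CohortTable

__all__ = [
    "SimConfig",
    "TrueParams",
    "simulate_genotypes",
    "assign_ir_status",
    "simulate_survival",
    "simulate_cohort",
]

#: Alternative-allele frequencies spanning the rare-to-common range of
#: the 13 study instruments (0.001–0.95).
DEFAULT_MAFS = (0.30, 0.29, 0.05, 0.01, 0.95, 0.75, 0.11, 0.001, 0.18, 0.04, 0.02, 0.35, 0.22)
DEFAULT_PHENOTYPES = ("FG", "FG", "FG", "FG", "FI", "FI", "FI",
                      "HOMA-IR", "HOMA-IR", "HOMA-IR", "HOMA-IR", "HOMA-IR", "HOMA-IR")
#: Moderate per-allele effects on the IR log-odds (log odds ratios).
DEFAULT_BETAS = (0.25, 0.25, 0.45, 0.6, 0.35, 0.25, 0.5, 1.2, 0.4, 0.45, 0.5, 0.3, 0.35)

#: CRC case fraction of the study cohort: 736 events among 11,078 women.
DEFAULT_EVENT_FRACTION = 736 / 11078


@dataclass
class SimConfig:
    """Generating parameters for one synthetic cohort."""

    n_individuals: int = 5000
    snp_ids: tuple[str, ...] = tuple(f"snp{i+1}" for i in range(13))
    mafs: tuple[float, ...] = DEFAULT_MAFS
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    beta_exp: tuple[float, ...] = DEFAULT_BETAS
    ir_prevalence: float = 0.30
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"bmi": 0.06, "met": -0.03, "sfa_pct": 0.03}
    )
    theta: float = math.log(0.85)
    confounder_ir: float = 0.0  # effect of shared confounder on each IR liability
    confounder_hr: float = 0.0  # direct log-HR of the confounder on CRC
    pleiotropy: tuple[float, ...] | None = None  # per-SNP direct log-HR
    baseline_hazard: float = 0.005
    event_fraction: float = DEFAULT_EVENT_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if not (len(self.mafs) == len(self.phenotypes) == len(self.beta_exp) == m):
            raise ValueError("snp_ids, mafs, phenotypes and beta_exp lengths differ")
        if any(not 0.0 < f < 1.0 for f in self.mafs):
            raise ValueError("mafs must lie strictly in (0, 1)")
        if not 0.0 < self.ir_prevalence < 1.0:
            raise ValueError("ir_prevalence must lie in (0, 1)")
        if not 0.0 < self.event_fraction < 1.0:
            raise ValueError("event_fraction must lie in (0, 1)")
        if not math.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.pleiotropy is not None and len(self.pleiotropy) != m:
            raise ValueError("pleiotropy vector length differs from snp count")


@dataclass
class TrueParams:
    """Ground-truth generating coefficients, emitted with every cohort."""

    theta: float
    snp_ids: tuple[str, ...]
    phenotypes: tuple[str, ...]
    mafs: tuple[float, ...]
    beta_exp: tuple[float, ...]
    pleiotropy: tuple[float, ...]
    intercepts: dict[str, float]
    covariate_effects: dict[str, float]
    confounder_ir: float
    confounder_hr: float
    baseline_hazard: float
    event_fraction_target: float
    censor_max: float
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "TrueParams":
        raw = json.loads(Path(path).read_text())
        for key in ("snp_ids", "phenotypes", "mafs", "beta_exp", "pleiotropy"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


def simulate_genotypes(n: int, mafs: Sequence[float], rng) -> np.ndarray:
    """Independent HWE genotypes: dosage ~ Binomial(2, maf) per SNP."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs >= 1)):
        raise ValueError("mafs must lie strictly in (0, 1)")
    rng = np.random.default_rng(rng)
    return rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)


def _covariates(n: int, rng) -> pd.DataFrame:
    """Lifestyle covariates with plausible postmenopausal distributions."""
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(63.0, 7.0, n), 50.0, 81.0),
            "bmi": np.clip(rng.normal(28.5, 5.5, n), 15.0, 60.0),
            "met": rng.lognormal(math.log(9.0), 0.9, n),
            "sfa_pct": np.clip(rng.normal(11.0, 4.5, n), 0.5, 30.0),
            "u": rng.normal(0.0, 1.0, n),  # latent shared confounder
        }
    )
    for k in range(1, 11):  # synthetic PCs: adjustment plumbing only
        df[f"pc{k}"] = rng.normal(0.0, 1.0, n)
    return df


def assign_ir_status(
    genotypes: np.ndarray,
    covariates: pd.DataFrame,
    beta: Sequence[float],
    rng,
    intercept: float | None = None,
    prevalence: float = 0.30,
    covariate_effects: Mapping[str, float] | None = None,
    confounder_ir: float = 0.0,
    return_liability: bool = False,
):
    """Draw a binary IR phenotype from a logistic model.

    The liability (logit of the case probability) is intercept +
    Σ dosage·β + centred covariate terms (+ confounder).  When no
    intercept is given it is tuned so the realized prevalence matches
    ``prevalence``.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if genotypes.shape[1] != beta.size:
        raise ValueError("beta length does not match genotype columns")
    if genotypes.shape[0] != len(covariates):
        raise ValueError("genotype and covariate row counts differ")
    rng = np.random.default_rng(rng)
    lin = genotypes @ beta
    for col, eff in (covariate_effects or {}).items():
        x = covariates[col].to_numpy(dtype=float)
        lin = lin + eff * (x - x.mean())
    if confounder_ir:
        lin = lin + confounder_ir * covariates["u"].to_numpy(dtype=float)
    if intercept is None:
        intercept = float(special.logit(prevalence) - lin.mean())
    liability = intercept + lin
    status = rng.binomial(1, special.expit(liability)).astype(int)
    if return_liability:
        return status, liability, intercept
    return status


def _censor_max_for_fraction(hazard: np.ndarray, target: float) -> float:
    """Uniform-censoring window hitting the target event fraction.

    With T ~ Exp(h) and C ~ U(0, c), P(event) = 1 − (1 − e^{−hc})/(hc);
    the window c is found by root-finding on the cohort mean.
    """

    def frac(c: float) -> float:
        hc = hazard * c
        return float(np.mean(1.0 - (1.0 - np.exp(-hc)) / hc))

    lo, hi = 1e-9, 1.0
    while frac(hi) < target:
        hi *= 10.0
        if hi > 1e15:
            raise RuntimeError("cannot reach target event fraction")
    return float(optimize.brentq(lambda c: frac(c) - target, lo, hi, xtol=1e-10))


def simulate_survival(
    exposure: np.ndarray,
    covariates: pd.DataFrame | None,
    theta: float,
    baseline_hazard: float,
    event_fraction: float,
    rng,
    confounder_hr: float = 0.0,
    extra_log_hazard: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exponential event times under a proportional-hazards model.

    hazard_i = baseline · exp(θ·exposure_i + confounder + extra terms);
    ``exposure`` may be the binary IR status or the IR liability.
    Independent uniform censoring is tuned so the expected event
    fraction matches ``event_fraction``.  Returns (time, event,
    censor_max).
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    rng = np.random.default_rng(rng)
    exposure = np.asarray(exposure, dtype=float)
    log_h = math.log(baseline_hazard) + theta * (exposure - exposure.mean())
    if confounder_hr and covariates is not None:
        log_h = log_h + confounder_hr * covariates["u"].to_numpy(dtype=float)
    if extra_log_hazard is not None:
        log_h = log_h + np.asarray(extra_log_hazard, dtype=float)
    hazard = np.exp(log_h)
    cmax = _censor_max_for_fraction(hazard, event_fraction)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, cmax, size=hazard.size)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    # guard against zero follow-up from floating underflow
    time = np.maximum(time, 1e-12)
    return time, event, cmax


def simulate_cohort(config: SimConfig) -> tuple[CohortTable, TrueParams]:
    """Generate a full cohort plus its ground-truth parameters.

    IR status is drawn per phenotype from the SNPs tagged with that
    phenotype; the outcome hazard depends on θ times the total
    (centred) IR liability, plus optional per-SNP pleiotropic effects
    and a shared confounder, so the MR experiment's true causal hazard
    ratio per unit IR log-odds is exp(θ).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    G = simulate_genotypes(n, config.mafs, rng)
    cov = _covariates(n, rng)
    betas = np.asarray(config.beta_exp, dtype=float)

    data = cov.copy()
    for j, snp in enumerate(config.snp_ids):
        data[snp] = G[:, j]

    intercepts: dict[str, float] = {}
    total_liability = np.zeros(n)
    ir_cols: dict[str, str] = {}
    for pheno in dict.fromkeys(config.phenotypes):  # stable unique order
        mask = np.array([p == pheno for p in config.phenotypes])
        status, liability, intercept = assign_ir_status(
            G[:, mask],
            cov,
            betas[mask],
            rng,
            prevalence=config.ir_prevalence,
            covariate_effects=config.covariate_effects,
            confounder_ir=config.confounder_ir,
            return_liability=True,
        )
        col = f"ir_{pheno.lower().replace('-', '_')}"
        data[col] = status
        ir_cols[pheno] = col
        intercepts[pheno] = intercept
        total_liability += liability - liability.mean()

    pleio = np.zeros(len(config.snp_ids)) if config.pleiotropy is None else np.asarray(
        config.pleiotropy, dtype=float
    )
    time, event, cmax = simulate_survival(
        total_liability,
        cov,
        config.theta,
        config.baseline_hazard,
        config.event_fraction,
        rng,
        confounder_hr=config.confounder_hr,
        extra_log_hazard=G @ pleio,
    )
    data["time"] = time
    data["event"] = event
    # subgroup labels derivable from the covariates via the fixed cut-offs
    data["subgroup_bmi"] = np.where(data["bmi"] >= 30.0, "obese", "non-obese")
    data["subgroup_met"] = np.where(data["met"] >= 10.0, "active", "inactive")
    data["subgroup_sfa"] = np.where(data["sfa_pct"] >= 7.0, "high-fat", "low-fat")

    cohort = CohortTable(
        data=data,
        snp_cols=list(config.snp_ids),
        covariate_cols=["age", "bmi", "met", "sfa_pct", "u"]
        + [f"pc{k}" for k in range(1, 11)],
        ir_cols=ir_cols,
        time_col="time",
        event_col="event",
        snp_phenotypes=dict(zip(config.snp_ids, config.phenotypes)),
    )
    params = TrueParams(
        theta=config.theta,
        snp_ids=tuple(config.snp_ids),
        phenotypes=tuple(config.phenotypes),
        mafs=tuple(config.mafs),
        beta_exp=tuple(config.beta_exp),
        pleiotropy=tuple(float(x) for x in pleio),
        intercepts=intercepts,
        covariate_effects=dict(config.covariate_effects),
        confounder_ir=config.confounder_ir,
        confounder_hr=config.confounder_hr,
        baseline_hazard=config.baseline_hazard,
        event_fraction_target=config.event_fraction,
        censor_max=cmax,
        seed=config.seed,
    )
    return cohort, params
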