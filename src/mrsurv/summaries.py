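"""Summary-statistic containers and allele harmonization.

The package works on GWAS-style per-SNP summary statistics: an exposure
record (log odds ratio of a binary insulin-resistance phenotype per copy
of the alternative allele) and an outcome record (log hazard ratio of
colorectal cancer per allele copy, with its 95% confidence interval).
Both sides are kept on the log scale internally; confidence bounds are
stored exponentiated, as printed in study tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpSummary",
    "OutcomeSummary",
    "RatioEstimate",
    "PooledEstimate",
    "EggerResult",
    "StrengthReport",
    "HarmonizationError",
    "se_from_ci",
    "se_from_p",
    "harmonize",
    "read_summary_tsv",
    "write_summary_tsv",
    "summary_frame",
]

#: Standard-normal 97.5% point rounded as used in printed 95% intervals.
Z95 = 1.96

PHENOTYPES = ("FG", "FI", "HOMA-IR")
SUBGROUPS = ("overall", "obese", "non-obese", "active", "inactive", "low-fat", "high-fat")

#: Strand-ambiguous allele pairs (identical to their reverse complement).
_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class HarmonizationError(ValueError):
    """Raised when exposure and outcome records cannot be allele-aligned."""


@dataclass(frozen=True)
class SnpSummary:
    """Exposure-side summary statistics for one instrument.

    ``beta_exp`` is the log odds ratio of the tagged insulin-resistance
    phenotype per alternative-allele copy.  ``se_exp`` may be ``None``
    when only a p-value is available (as in printed association tables);
    it can then be recovered via :func:`se_from_p`.
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    alt_freq: float
    phenotype: str
    subgroup: str
    beta_exp: float
    se_exp: float | None
    p_exp: float
    gene: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(f"alt_freq {self.alt_freq!r} outside [0, 1]")
        if not 0.0 < self.p_exp <= 1.0:
            raise ValueError(f"p_exp {self.p_exp!r} outside (0, 1]")
        if self.se_exp is not None and self.se_exp < 0:
            raise ValueError("se_exp must be >= 0")

    @property
    def key(self) -> tuple[str, str, str]:
        """(phenotype, subgroup, snp_id) — unique row key."""
        return (self.phenotype, self.subgroup, self.snp_id)

    def se_or_recover(self) -> float:
        """Return ``se_exp``, recovering it from ``p_exp`` when absent."""
        if self.se_exp is not None and self.se_exp > 0:
            return self.se_exp
        return se_from_p(self.beta_exp, self.p_exp)


@dataclass(frozen=True)
class OutcomeSummary:
    """Outcome-side summary for one SNP: log HR of CRC with 95% CI."""

    snp_id: str
    log_hr: float
    ci_low: float
    ci_high: float
    p_out: float

    def __post_init__(self) -> None:
        if self.ci_low <= 0 or self.ci_high <= 0:
            raise ValueError("CI bounds must be positive (hazard-ratio scale)")
        if self.ci_low > self.ci_high:
            raise ValueError("inverted CI bounds")
        hr = math.exp(self.log_hr)
        # printed 2-dp tables can put the point on a bound; allow slack
        if not (self.ci_low - 5e-3 <= hr <= self.ci_high + 5e-3):
            raise ValueError(f"HR {hr:.4g} outside its CI ({self.ci_low}, {self.ci_high})")

    @property
    def se(self) -> float:
        """First-order SE of log HR recovered from the printed CI."""
        return se_from_ci(self.ci_low, self.ci_high)


@dataclass(frozen=True)
class RatioEstimate:
    """Single-instrument Wald-ratio MR estimate on the log scale."""

    snp_id: str
    log_ratio: float
    se: float
    ci_low: float
    ci_high: float
    phenotype: str | None = None
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")
        point = math.exp(self.log_ratio)
        if not (self.ci_low - 1e-9 <= point <= self.ci_high + 1e-9):
            raise ValueError("ratio CI does not bracket the point estimate")

    @property
    def weight(self) -> float:
        """Inverse-variance weight 1/se² (inf when se == 0)."""
        return math.inf if self.se == 0 else self.se**-2


@dataclass(frozen=True)
class PooledEstimate:
    """Inverse-variance-weighted pool of ratio estimates."""

    log_pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    q_stat: float
    q_df: int
    p_het: float | None
    n_snps: int
    rho: float = 0.0
    method: str = "fixed-effect IVW"

    @property
    def hr(self) -> float:
        return math.exp(self.log_pooled)

    @property
    def p_value(self) -> float:
        if self.se_pooled == 0:
            return 0.0 if self.log_pooled != 0 else 1.0
        z = self.log_pooled / self.se_pooled
        return 2.0 * stats.norm.sf(abs(z))


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger weighted regression: intercept tests directional pleiotropy."""

    intercept: float
    se_intercept: float
    p_intercept: float
    slope: float
    se_slope: float
    n_snps: int


@dataclass(frozen=True)
class StrengthReport:
    """Instrument-strength summary: per-SNP T² and their sum vs a threshold."""

    per_snp_t2: tuple[tuple[str, float], ...]
    total: float
    threshold: float
    passed: bool


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Recover the SE of a log effect from its printed ratio-scale CI.

    Uses z = 1.96 at the conventional 95% level to match rounded printed
    intervals; other levels use the exact normal quantile.
    """
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("CI bounds must be positive")
    if ci_low > ci_high:
        raise ValueError("inverted CI bounds")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    z = Z95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2.0)
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)


def se_from_p(beta: float, p: float) -> float:
    """Recover the SE of ``beta`` from its two-sided normal p-value."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    z = stats.norm.isf(p / 2.0)
    if z <= 0:
        warnings.warn("p = 1 gives z = 0: SE is infinite; exclude this SNP", stacklevel=2)
        return math.inf
    return abs(beta) / z


def _is_palindromic(ref: str, alt: str) -> bool:
    return (ref.upper(), alt.upper()) in _PALINDROMES


def harmonize(
    exposure: SnpSummary,
    outcome: OutcomeSummary,
    outcome_alleles: tuple[str, str] | None = None,
) -> tuple[SnpSummary, OutcomeSummary]:
    """Align an exposure/outcome record pair to the IR-increasing allele.

    Both records are re-expressed so that the exposure effect is positive
    (the allele that raises the insulin-resistance phenotype).  Flipping
    negates both log effects, reciprocates and re-sorts the outcome CI,
    replaces ``alt_freq`` by its complement and swaps the allele labels.
    The Wald ratio is invariant under this reorientation.

    ``outcome_alleles`` optionally gives the (ref, alt) orientation the
    outcome effect was estimated on; if it is the swap of the exposure's
    alleles the outcome sign is corrected first.  Any other pair raises
    :class:`HarmonizationError`.  Palindromic (strand-ambiguous) alleles
    trigger a warning, never an error.
    """
    if exposure.snp_id != outcome.snp_id:
        raise HarmonizationError(
            f"snp_id mismatch: {exposure.snp_id!r} vs {outcome.snp_id!r}"
        )
    if _is_palindromic(exposure.ref_allele, exposure.alt_allele):
        warnings.warn(
            f"{exposure.snp_id}: palindromic alleles "
            f"{exposure.ref_allele}/{exposure.alt_allele}; strand ambiguity unresolved",
            stacklevel=2,
        )
    if outcome_alleles is not None:
        pair = (outcome_alleles[0].upper(), outcome_alleles[1].upper())
        mine = (exposure.ref_allele.upper(), exposure.alt_allele.upper())
        if pair == mine:
            pass
        elif pair == mine[::-1]:
            outcome = _flip_outcome(outcome)
        else:
            raise HarmonizationError(
                f"{exposure.snp_id}: alleles {pair} match neither orientation of {mine}"
            )
    if exposure.beta_exp > 0:
        return exposure, outcome
    flipped = replace(
        exposure,
        ref_allele=exposure.alt_allele,
        alt_allele=exposure.ref_allele,
        alt_freq=1.0 - exposure.alt_freq,
        beta_exp=-exposure.beta_exp,
    )
    return flipped, _flip_outcome(outcome)


def _flip_outcome(outcome: OutcomeSummary) -> OutcomeSummary:
    return replace(
        outcome,
        log_hr=-outcome.log_hr,
        ci_low=1.0 / outcome.ci_high,
        ci_high=1.0 / outcome.ci_low,
    )


# ---------------------------------------------------------------------------
# TSV dialect: one row per (phenotype, subgroup, SNP)

_COLUMNS = [
    "snp_id", "gene", "chrom", "pos", "ref", "alt", "alt_freq",
    "phenotype", "subgroup", "or_exp", "p_exp",
    "hr_out", "hr_ci_low", "hr_ci_high", "p_out",
]


def _records_from_frame(df: pd.DataFrame) -> tuple[list[SnpSummary], list[OutcomeSummary]]:
    exposures, outcomes = [], []
    for row in df.itertuples(index=False):
        exposures.append(
            SnpSummary(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                alt_freq=float(row.alt_freq),
                phenotype=str(row.phenotype),
                subgroup=str(row.subgroup),
                beta_exp=math.log(float(row.or_exp)),
                se_exp=None,
                p_exp=float(row.p_exp),
                gene=str(row.gene) if "gene" in df.columns else None,
            )
        )
        outcomes.append(
            OutcomeSummary(
                snp_id=str(row.snp_id),
                log_hr=math.log(float(row.hr_out)),
                ci_low=float(row.hr_ci_low),
                ci_high=float(row.hr_ci_high),
                p_out=float(row.p_out),
            )
        )
    return exposures, outcomes


def read_summary_tsv(path) -> tuple[list[SnpSummary], list[OutcomeSummary]]:
    """Read the per-SNP summary-statistics TSV dialect."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c != "gene" and c not in df.columns]
    if missing:
        raise ValueError(f"summary TSV missing columns: {missing}")
    return _records_from_frame(df)


def summary_frame(
    exposures: Sequence[SnpSummary], outcomes: Sequence[OutcomeSummary]
) -> pd.DataFrame:
    """Tabulate paired records in the summary TSV dialect."""
    if len(exposures) != len(outcomes):
        raise ValueError("exposure/outcome lists differ in length")
    rows = []
    for e, o in zip(exposures, outcomes):
        if e.snp_id != o.snp_id:
            raise ValueError(f"row mismatch: {e.snp_id} vs {o.snp_id}")
        rows.append(
            {
                "snp_id": e.snp_id,
                "gene": e.gene,
                "chrom": e.chrom,
                "pos": e.pos,
                "ref": e.ref_allele,
                "alt": e.alt_allele,
                "alt_freq": e.alt_freq,
                "phenotype": e.phenotype,
                "subgroup": e.subgroup,
                "or_exp": math.exp(e.beta_exp),
                "p_exp": e.p_exp,
                "hr_out": math.exp(o.log_hr),
                "hr_ci_low": o.ci_low,
                "hr_ci_high": o.ci_high,
                "p_out": o.p_out,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_summary_tsv(
    path, exposures: Sequence[SnpSummary], outcomes: Sequence[OutcomeSummary]
) -> None:
    summary_frame(exposures, outcomes).to_csv(path, sep="\t", index=False)
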