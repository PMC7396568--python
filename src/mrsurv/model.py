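"""Model/results interface for summary-statistics MR.

``MRModel`` is built from paired exposure/outcome summary records (or a
DataFrame in the package's summary-TSV dialect); ``fit()`` returns an
``MRResults`` carrying the pooled estimate, per-instrument Wald ratios,
heterogeneity diagnostics, instrument strength, the MR-Egger pleiotropy
test, and a ``summary()`` table.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import core
from .summaries import (
    EggerResult,
    OutcomeSummary,
    PooledEstimate,
    RatioEstimate,
    SnpSummary,
    StrengthReport,
    harmonize,
    _records_from_frame,
)

__all__ = ["MRModel", "MRResults"]


class MRModel:
    """One-sample MR model for a set of instruments on one outcome.

    Parameters
    ----------
    exposures, outcomes
        Paired per-SNP records; pairs are allele-harmonized on
        construction so every exposure effect is positive.
    ci_method
        How single-instrument CIs are formed: ``"ratio"`` (outcome CI
        bounds divided by the exposure effect on the log scale; the
        default, first-order) or ``"delta"``.
    """

    def __init__(
        self,
        exposures: Sequence[SnpSummary],
        outcomes: Sequence[OutcomeSummary],
        ci_method: Literal["ratio", "delta"] = "ratio",
    ) -> None:
        if len(exposures) != len(outcomes):
            raise ValueError("exposure/outcome lists differ in length")
        if len(exposures) == 0:
            raise ValueError("no instruments")
        pairs = [harmonize(e, o) for e, o in zip(exposures, outcomes)]
        self.exposures: list[SnpSummary] = [p[0] for p in pairs]
        self.outcomes: list[OutcomeSummary] = [p[1] for p in pairs]
        self.ci_method = ci_method

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MRModel":
        """Build from a DataFrame in the summary-TSV dialect."""
        exposures, outcomes = _records_from_frame(df)
        return cls(exposures, outcomes, **kwargs)

    @property
    def n_instruments(self) -> int:
        return len(self.exposures)

    def ratio_estimates(self) -> list[RatioEstimate]:
        return [
            core.wald_ratio(o, e, ci_method=self.ci_method)
            for e, o in zip(self.exposures, self.outcomes)
        ]

    def fit(
        self,
        rho: float = 0.0,
        method: Literal["fixed", "random"] = "fixed",
    ) -> "MRResults":
        estimates = self.ratio_estimates()
        pooled = core.ivw_pool(estimates, rho=rho, method=method)
        return MRResults(self, estimates, pooled)


class MRResults:
    """Fitted MR results: pooled effect, diagnostics and summaries."""

    def __init__(
        self,
        model: MRModel,
        ratio_estimates: list[RatioEstimate],
        pooled: PooledEstimate,
    ) -> None:
        self.model = model
        self.ratio_estimates = ratio_estimates
        self.pooled = pooled

    # -- statsmodels-flavoured accessors --------------------------------

    @property
    def params(self) -> float:
        """Pooled causal log hazard ratio per unit IR log-odds."""
        return self.pooled.log_pooled

    @property
    def bse(self) -> float:
        return self.pooled.se_pooled

    @property
    def pvalues(self) -> float:
        return self.pooled.p_value

    def conf_int(self) -> tuple[float, float]:
        """Exponentiated 95% bounds of the pooled hazard ratio."""
        return (self.pooled.ci_low, self.pooled.ci_high)

    @property
    def q_stat(self) -> float:
        return self.pooled.q_stat

    @property
    def p_het(self) -> float | None:
        return self.pooled.p_het

    @property
    def n_instruments(self) -> int:
        return self.pooled.n_snps

    def egger(self, **kwargs) -> EggerResult:
        """MR-Egger directional-pleiotropy test over the instruments."""
        pairs = [
            (e.beta_exp, o.log_hr, o.se)
            for e, o in zip(self.model.exposures, self.model.outcomes)
        ]
        return core.egger_regression(pairs, **kwargs)

    def strength(self, threshold: float = 10.0) -> StrengthReport:
        return core.instrument_strength(self.model.exposures, threshold)

    def ratio_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "phenotype": r.phenotype,
                "subgroup": r.subgroup,
                "hr": math.exp(r.log_ratio),
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "se_log": r.se,
                "weight": r.weight,
            }
            for r in self.ratio_estimates
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.pooled
        lines = [
            "One-sample Mendelian randomization (summary statistics)",
            "=" * 60,
            f"Instruments:        {p.n_snps}",
            f"Pooling:            {p.method} (rho = {p.rho:g})",
            f"HR per unit IR log-odds: {p.hr:.3f}  "
            f"(95% CI {p.ci_low:.3f}-{p.ci_high:.3f})",
            f"log HR: {p.log_pooled:+.4f}  SE {p.se_pooled:.4f}  p = {p.p_value:.3g}",
            f"Cochran's Q: {p.q_stat:.3f} on {p.q_df} df"
            + (f"  (p_het = {p.p_het:.3f})" if p.p_het is not None else "  (p_het N/A)"),
            "-" * 60,
            f"{'snp_id':<14}{'HR':>8}{'ci_low':>9}{'ci_high':>9}{'weight%':>9}",
        ]
        total_w = sum(r.weight for r in self.ratio_estimates)
        for r in self.ratio_estimates:
            lines.append(
                f"{r.snp_id:<14}{math.exp(r.log_ratio):>8.3f}"
                f"{r.ci_low:>9.3f}{r.ci_high:>9.3f}{100 * r.weight / total_w:>9.1f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MRResults n={self.pooled.n_snps} HR={self.pooled.hr:.3f} "
            f"p={self.pooled.p_value:.3g}>"
        )
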