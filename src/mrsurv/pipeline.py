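"""End-to-end orchestration and tabular reporting.

Runs the full analysis from either summary statistics (the bundled
13-instrument study table, or any TSV in the same dialect) or an
individual-level cohort, and writes the result bundle: per-SNP Wald
ratios, pooled estimates laid out like the study's MR table (one row
per phenotype × subgroup cell plus per-phenotype and all-SNP pools,
with "N/A" heterogeneity for single-SNP cells), instrument strength,
MR-Egger tests, forest-plot data, QC log and run log.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core
from .associations import cox_scan, logistic_scan, spearman_rho
from .cohort import CohortTable
from .instruments import QcConfig, QcLog, filter_significant
from .model import MRModel, MRResults
from .simulate import SimConfig, simulate_cohort
from .summaries import (
    OutcomeSummary,
    PooledEstimate,
    RatioEstimate,
    SnpSummary,
    read_summary_tsv,
    summary_frame,
)

__all__ = [
    "RunConfig",
    "ForestRow",
    "load_fixture_table1",
    "run_pipeline",
    "forest_data",
]

log = logging.getLogger("mrsurv")

#: Adjustment presets for cohort mode; the sensitivity preset drops the
#: lifestyle covariates and keeps age plus the 10 genetic PCs.
ADJUSTMENT_PRESETS = {
    "full": ["age", "bmi", "met", "sfa_pct"] + [f"pc{k}" for k in range(1, 11)],
    "age-pcs-only": ["age"] + [f"pc{k}" for k in range(1, 11)],
}


@dataclass
class RunConfig:
    mode: Literal["summary-mr", "cohort-mr", "simulate"]
    input_path: str | None = None
    output_dir: str = "mrsurv-output"
    qc: QcConfig = field(default_factory=QcConfig)
    adjustment: str = "full"
    rho: float | str = 0.0  # number, or "estimate" (cohort mode only)
    seed: int = 0
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("summary-mr", "cohort-mr", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.adjustment not in ADJUSTMENT_PRESETS:
            raise ValueError(f"unknown adjustment preset {self.adjustment!r}")


@dataclass(frozen=True)
class ForestRow:
    """One forest-plot line: a pool member with its weight share."""

    label: str
    hr: float
    ci_low: float
    ci_high: float
    weight_share: float


def load_fixture_table1() -> tuple[list[SnpSummary], list[OutcomeSummary]]:
    """The bundled 13-instrument study table (per-SNP ORs, HRs, CIs)."""
    with resources.as_file(
        resources.files("mrsurv.fixtures").joinpath("table1.tsv")
    ) as path:
        return read_summary_tsv(path)


def forest_data(
    pooled: PooledEstimate, components: Sequence[RatioEstimate], label: str = "pool"
) -> list[ForestRow]:
    """Forest rows for a pool: per-SNP lines then the pooled line.

    Weight shares are wᵢ/Σw, invariant to uniform SE rescaling.
    """
    if len(components) == 0:
        raise ValueError("empty pool")
    total = sum(r.weight for r in components)
    rows = [
        ForestRow(
            label=r.snp_id,
            hr=math.exp(r.log_ratio),
            ci_low=r.ci_low,
            ci_high=r.ci_high,
            weight_share=r.weight / total,
        )
        for r in components
    ]
    rows.append(
        ForestRow(
            label=label,
            hr=pooled.hr,
            ci_low=pooled.ci_low,
            ci_high=pooled.ci_high,
            weight_share=1.0,
        )
    )
    return rows


# ---------------------------------------------------------------------------


def _grouped_fits(
    exposures: Sequence[SnpSummary],
    outcomes: Sequence[OutcomeSummary],
    rho: float,
) -> list[tuple[str, str, MRResults]]:
    """Fit every phenotype × subgroup cell, per-phenotype and all-SNP pools."""
    pairs = list(zip(exposures, outcomes))
    fits: list[tuple[str, str, MRResults]] = []

    def fit(subset, phenotype, subgroup):
        model = MRModel([e for e, _ in subset], [o for _, o in subset])
        fits.append((phenotype, subgroup, model.fit(rho=rho)))

    phenos = list(dict.fromkeys(e.phenotype for e, _ in pairs))
    for pheno in phenos:
        rows = [(e, o) for e, o in pairs if e.phenotype == pheno]
        for sub in dict.fromkeys(e.subgroup for e, _ in rows):
            fit([(e, o) for e, o in rows if e.subgroup == sub], pheno, sub)
        fit(rows, pheno, "pooled")
    fit(pairs, "all", "pooled")
    return fits


def _pooled_frames(
    fits: list[tuple[str, str, MRResults]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(pretty, full-precision) pooled tables in the study-table layout."""
    full_rows, pretty_rows = [], []
    for pheno, sub, res in fits:
        p = res.pooled
        full_rows.append(
            {
                "phenotype": pheno,
                "subgroup": sub,
                "n_snps": p.n_snps,
                "hr": p.hr,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "p": p.p_value,
                "q_stat": p.q_stat,
                "p_het": p.p_het if p.p_het is not None else np.nan,
            }
        )
        pretty_rows.append(
            {
                "phenotype": pheno,
                "subgroup": sub,
                "n_snps": p.n_snps,
                "hr": f"{p.hr:.2f}",
                "ci_low": f"{p.ci_low:.2f}",
                "ci_high": f"{p.ci_high:.2f}",
                "p": f"{p.p_value:.3f}",
                "p_het": "N/A" if p.p_het is None else f"{p.p_het:.3f}",
            }
        )
    return pd.DataFrame(pretty_rows), pd.DataFrame(full_rows)


def _write_bundle(
    outdir: Path,
    exposures: Sequence[SnpSummary],
    outcomes: Sequence[OutcomeSummary],
    rho: float,
    qc_log: QcLog | None = None,
) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    fits = _grouped_fits(exposures, outcomes, rho)
    files: dict[str, Path] = {}

    all_res = next(res for ph, sub, res in fits if ph == "all")
    ratios = all_res.ratio_frame()
    files["ratios"] = outdir / "ratios.tsv"
    ratios.to_csv(files["ratios"], sep="\t", index=False)

    pretty, full = _pooled_frames(fits)
    files["pooled"] = outdir / "pooled.tsv"
    files["pooled_full"] = outdir / "pooled_full.tsv"
    pretty.to_csv(files["pooled"], sep="\t", index=False)
    full.to_csv(files["pooled_full"], sep="\t", index=False)

    strength_rows = []
    for pheno, sub, res in fits:
        if sub != "pooled":
            continue
        rep = res.strength()
        strength_rows.append(
            {
                "phenotype": pheno,
                "n_snps": res.n_instruments,
                "total_t2": rep.total,
                "threshold": rep.threshold,
                "passed": rep.passed,
            }
        )
    files["strength"] = outdir / "strength.tsv"
    pd.DataFrame(strength_rows).to_csv(files["strength"], sep="\t", index=False)

    egger_rows = []
    for pheno, sub, res in fits:
        if sub != "pooled" or res.n_instruments < 3:
            continue
        eg = res.egger()
        egger_rows.append(
            {
                "phenotype": pheno,
                "n_snps": eg.n_snps,
                "intercept": eg.intercept,
                "se_intercept": eg.se_intercept,
                "p_intercept": eg.p_intercept,
                "slope": eg.slope,
                "se_slope": eg.se_slope,
            }
        )
    files["egger"] = outdir / "egger.tsv"
    pd.DataFrame(egger_rows).to_csv(files["egger"], sep="\t", index=False)

    forest_rows = []
    for pheno, sub, res in fits:
        label = f"{pheno}/{sub}"
        for row in forest_data(res.pooled, res.ratio_estimates, label=label):
            forest_rows.append({"group": label, **dataclasses.asdict(row)})
    files["forest"] = outdir / "forest.tsv"
    pd.DataFrame(forest_rows).to_csv(files["forest"], sep="\t", index=False)

    if qc_log is not None:
        files["qc_log"] = outdir / "qc_log.tsv"
        qc_log.to_tsv(files["qc_log"])
    return files


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run one mode end to end; returns the paths of the written bundle."""
    outdir = Path(config.output_dir)
    try:
        if config.mode == "simulate":
            sim = config.sim or SimConfig(seed=config.seed)
            log.info("simulate: n=%d, %d SNPs, seed=%d", sim.n_individuals,
                     len(sim.snp_ids), sim.seed)
            cohort, params = simulate_cohort(sim)
            outdir.mkdir(parents=True, exist_ok=True)
            cohort.to_tsv(outdir / "cohort.tsv")
            params.to_json(outdir / "true_params.json")
            return {"cohort": outdir / "cohort.tsv",
                    "true_params": outdir / "true_params.json"}

        if config.mode == "summary-mr":
            if config.input_path is None:
                log.info("summary-mr: using the bundled study table")
                exposures, outcomes = load_fixture_table1()
            else:
                exposures, outcomes = read_summary_tsv(config.input_path)
            if config.rho == "estimate":
                raise ValueError("rho='estimate' needs individual-level data")
            qc_log = QcLog()
            kept = filter_significant(exposures, config.qc.gw_p_threshold, qc_log)
            kept_ids = {id(e) for e in kept}
            pairs = [(e, o) for e, o in zip(exposures, outcomes) if id(e) in kept_ids]
            return _write_bundle(
                outdir, [e for e, _ in pairs], [o for _, o in pairs],
                float(config.rho), qc_log,
            )

        # cohort-mr
        if config.input_path is None:
            raise ValueError("cohort-mr mode needs an input cohort TSV")
        cohort = CohortTable.from_tsv(config.input_path)
        covs = [c for c in ADJUSTMENT_PRESETS[config.adjustment]
                if c in cohort.data.columns]
        log.info("cohort-mr: n=%d, %d SNPs, adjusting for %s",
                 len(cohort), len(cohort.snp_cols), covs)
        outcome_by_id = {o.snp_id: o for o in cox_scan(cohort, covariates=covs)}
        snp_pheno = cohort.snp_phenotypes
        exposures: list[SnpSummary] = []
        outcomes: list[OutcomeSummary] = []
        rho_by_pheno: dict[str, float] = {}
        for pheno in cohort.ir_cols:
            # without an instrument map every SNP is scanned per phenotype
            snp_ids = [s for s in cohort.snp_cols
                       if snp_pheno is None or snp_pheno.get(s) == pheno]
            if not snp_ids:
                continue
            scan = logistic_scan(cohort, snp_ids=snp_ids, covariates=covs,
                                 phenotype=pheno)
            for s in scan:
                if s.se_exp is None or s.snp_id not in outcome_by_id:
                    continue
                exposures.append(s)
                outcomes.append(outcome_by_id[s.snp_id])
            r = spearman_rho(cohort.data[cohort.ir_cols[pheno]],
                             cohort.data[cohort.event_col])
            rho_by_pheno[pheno] = 0.0 if r is None else r
        if config.rho == "estimate":
            rho = float(np.mean(list(rho_by_pheno.values())))
            log.info("estimated overlap rho by phenotype: %s -> %g", rho_by_pheno, rho)
        else:
            rho = float(config.rho)
        return _write_bundle(outdir, exposures, outcomes, rho)
    except Exception:
        log.exception("pipeline failed in mode %s", config.mode)
        raise
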