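"""Instrument discovery and quality control.

Candidate instruments pass, in order: missing-call-rate filtering
(<3%), a Hardy–Weinberg exact test (p ≥ 1e-4), imputation quality
(R² ≥ 0.6), genome-wide significance (p < 5e-8), greedy LD pruning
(pairwise r² < 0.1, most significant SNP wins), and an optional screen
that excludes SNPs with evidence of association with obesity, the main
pleiotropy concern when the exposure is insulin resistance.  Every
decision is recorded in a :class:`QcLog`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .summaries import SnpSummary

__all__ = [
    "QcConfig",
    "QcLog",
    "QcLogEntry",
    "filter_significant",
    "ld_prune",
    "hwe_exact_test",
    "apply_qc",
    "pleiotropy_screen",
    "read_dosage_tsv",
    "read_vcf_genotypes",
    "qc_metrics_from_dosages",
]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for instrument QC; defaults follow the study design."""

    gw_p_threshold: float = 5e-8
    ld_r2_max: float = 0.1
    hwe_p_min: float = 1e-4
    max_missing_rate: float = 0.03
    min_impute_r2: float = 0.6
    pleiotropy_p_min: float = 0.05

    def __post_init__(self) -> None:
        for name in ("gw_p_threshold", "hwe_p_min", "pleiotropy_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v!r} outside [0, 1]")
        if not 0.0 <= self.ld_r2_max <= 1.0:
            raise ValueError("ld_r2_max outside [0, 1]")
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate outside [0, 1]")
        if not 0.0 <= self.min_impute_r2 <= 1.0:
            raise ValueError("min_impute_r2 outside [0, 1]")


@dataclass(frozen=True)
class QcLogEntry:
    snp_id: str
    stage: str
    kept: bool
    reason: str


@dataclass
class QcLog:
    """Ordered record of every QC decision, one entry per SNP per stage."""

    entries: list[QcLogEntry] = field(default_factory=list)

    def record(self, snp_id: str, stage: str, kept: bool, reason: str) -> None:
        self.entries.append(QcLogEntry(snp_id, stage, kept, reason))

    def dropped(self) -> dict[str, QcLogEntry]:
        """Terminal drop entry per SNP (a SNP is dropped at most once)."""
        out: dict[str, QcLogEntry] = {}
        for e in self.entries:
            if not e.kept:
                if e.snp_id in out:
                    raise AssertionError(f"{e.snp_id} dropped twice")
                out[e.snp_id] = e
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.snp_id, e.stage, e.kept, e.reason) for e in self.entries],
            columns=["snp_id", "stage", "kept", "reason"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_significant(
    snps: Sequence[SnpSummary],
    threshold: float = 5e-8,
    log: QcLog | None = None,
) -> list[SnpSummary]:
    """Keep SNPs at genome-wide significance (strictly p < threshold)."""
    log = log if log is not None else QcLog()
    kept = []
    for s in snps:
        ok = s.p_exp < threshold
        log.record(
            s.snp_id, "significance", ok,
            f"p_exp={s.p_exp:.3g} {'<' if ok else '>='} {threshold:.3g}",
        )
        if ok:
            kept.append(s)
    return kept


def ld_prune(
    snps: Sequence[SnpSummary],
    r2: np.ndarray,
    r2_max: float = 0.1,
    log: QcLog | None = None,
) -> list[SnpSummary]:
    """Greedy LD pruning: in ascending exposure-p order, keep a SNP iff
    its r² with every already-kept SNP is strictly below ``r2_max``.

    Output preserves the input order of the kept SNPs.
    """
    r2 = np.asarray(r2, dtype=float)
    n = len(snps)
    if r2.shape != (n, n):
        raise ValueError(f"r2 matrix shape {r2.shape} does not match {n} SNPs")
    if not np.allclose(r2, r2.T, atol=1e-8):
        raise ValueError("r2 matrix is not symmetric")
    if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
        raise ValueError("r2 matrix diagonal must be 1")
    if np.any((r2 < -1e-12) | (r2 > 1 + 1e-12)):
        raise ValueError("r2 entries must lie in [0, 1]")
    log = log if log is not None else QcLog()
    order = sorted(range(n), key=lambda i: (snps[i].p_exp, i))  # stable tie-break
    kept_idx: list[int] = []
    for i in order:
        clash = [j for j in kept_idx if r2[i, j] >= r2_max]
        if clash:
            worst = max(r2[i, j] for j in clash)
            log.record(
                snps[i].snp_id, "ld-prune", False,
                f"r2={worst:.3g} >= {r2_max:.3g} with {snps[clash[0]].snp_id}",
            )
        else:
            kept_idx.append(i)
            log.record(snps[i].snp_id, "ld-prune", True, f"max r2 with kept < {r2_max:.3g}")
    kept_idx.sort()
    kept = [snps[i] for i in kept_idx]
    # invariant: no kept pair may violate the threshold
    for a in range(len(kept_idx)):
        for b in range(a + 1, len(kept_idx)):
            assert r2[kept_idx[a], kept_idx[b]] < r2_max
    return kept


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg test on genotype counts.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed that of
    the observed count (two-sided exact test).  Monomorphic sites return
    p = 1.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    if rare == 0:
        return 1.0
    # heterozygote count shares the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het = h | allele counts) up to a constant, via gammaln
    from scipy.special import gammaln

    def logp(h):
        hom_rare = (rare - h) / 2.0
        hom_common = (max(n_alt, n_ref) - h) / 2.0
        return (
            h * math.log(2.0)
            - gammaln(h + 1)
            - gammaln(hom_rare + 1)
            - gammaln(hom_common + 1)
        )

    lp = np.array([logp(h) for h in hets])
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    # tolerance guards against ties broken by floating error
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    return min(1.0, p)


def apply_qc(
    snps: Sequence[SnpSummary],
    missing_rates: Mapping[str, float] | None = None,
    impute_r2: Mapping[str, float] | None = None,
    genotype_counts: Mapping[str, tuple[int, int, int]] | None = None,
    r2_matrix: np.ndarray | None = None,
    config: QcConfig | None = None,
) -> tuple[list[SnpSummary], QcLog]:
    """Run the sequential QC pipeline and log every decision.

    Stage order: missingness → HWE → imputation R² → genome-wide
    significance → LD pruning.  A stage is skipped (and logged as
    skipped) for SNPs whose metric is absent; malformed metrics drop the
    SNP conservatively.
    """
    config = config or QcConfig()
    log = QcLog()
    current = list(snps)

    def metric_stage(name, metrics, keep_fn, describe):
        nonlocal current
        if metrics is None:
            return
        nxt = []
        for s in current:
            if s.snp_id not in metrics:
                log.record(s.snp_id, name, True, "metric absent; stage skipped")
                nxt.append(s)
                continue
            value = metrics[s.snp_id]
            try:
                ok = keep_fn(value)
            except Exception as exc:  # malformed metric: conservative drop
                log.record(s.snp_id, name, False, f"malformed metric ({exc})")
                continue
            log.record(s.snp_id, name, ok, describe(value))
            if ok:
                nxt.append(s)
        current = nxt

    metric_stage(
        "missingness", missing_rates,
        lambda v: float(v) < config.max_missing_rate,
        lambda v: f"missing rate {float(v):.3g} vs < {config.max_missing_rate}",
    )
    metric_stage(
        "hwe", genotype_counts,
        lambda v: hwe_exact_test(*v) >= config.hwe_p_min,
        lambda v: f"HWE exact p={hwe_exact_test(*v):.3g} vs >= {config.hwe_p_min}",
    )
    metric_stage(
        "imputation", impute_r2,
        lambda v: float(v) >= config.min_impute_r2,
        lambda v: f"imputation R2 {float(v):.3g} vs >= {config.min_impute_r2}",
    )
    current = filter_significant(current, config.gw_p_threshold, log)
    if r2_matrix is not None and len(current) > 0:
        cur_ids = {id(s) for s in current}
        idx = [i for i, s in enumerate(snps) if id(s) in cur_ids]
        sub = np.asarray(r2_matrix)[np.ix_(idx, idx)]
        current = ld_prune(current, sub, config.ld_r2_max, log)
    return current, log


def read_dosage_tsv(path) -> pd.DataFrame:
    """Read a 012 genotype matrix TSV (rows individuals, columns SNPs).

    Missing calls may be encoded as empty cells, ``NA`` or ``.``.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", "."])
    bad = [c for c in df.columns if not df[c].dropna().isin([0, 1, 2]).all()]
    if bad:
        raise ValueError(f"non-012 dosage values in columns: {bad}")
    return df


def read_vcf_genotypes(path) -> pd.DataFrame:
    """Hard-call dosages from a VCF, using the GT field only.

    Returns a 012 DataFrame (individuals × SNPs, NaN for missing calls),
    counting alternative-allele copies.  Multi-allelic records are
    rejected; anything beyond GT is ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(f"{variant.ID or variant.POS}: multi-allelic record")
        gt = variant.gt_types.astype(float)  # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        cols[variant.ID or f"{variant.CHROM}:{variant.POS}"] = gt
    return pd.DataFrame(cols, index=samples)


def qc_metrics_from_dosages(
    dosages: pd.DataFrame,
) -> tuple[dict[str, float], dict[str, tuple[int, int, int]]]:
    """Per-SNP missing rates and genotype counts from a 012 matrix."""
    missing = {c: float(dosages[c].isna().mean()) for c in dosages.columns}
    counts = {}
    for c in dosages.columns:
        obs = dosages[c].dropna().astype(int)
        counts[c] = (int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum()))
    return missing, counts


def pleiotropy_screen(
    snps: Sequence[SnpSummary],
    obesity_assoc: Mapping[str, float],
    threshold: float = 0.05,
    missing: str = "keep",
    log: QcLog | None = None,
) -> tuple[list[SnpSummary], QcLog]:
    """Exclude SNPs associated with obesity (potential pleiotropy).

    Obesity is itself a CRC risk factor, so an instrument associated
    with obesity may act on the outcome through a pathway other than
    insulin resistance.  SNPs with an obesity-association p-value below
    ``threshold`` are dropped with reason ``pleiotropy-obesity``.  SNPs
    without a p-value are kept with a warning by default
    (``missing="keep"``) or dropped (``missing="drop"``).
    """
    log = log if log is not None else QcLog()
    kept = []
    for s in snps:
        if s.snp_id not in obesity_assoc:
            if missing == "keep":
                warnings.warn(
                    f"{s.snp_id}: no obesity association p-value; kept unscreened",
                    stacklevel=2,
                )
                log.record(s.snp_id, "pleiotropy-obesity", True, "no p-value; kept")
                kept.append(s)
            elif missing == "drop":
                log.record(s.snp_id, "pleiotropy-obesity", False, "no p-value; dropped")
            else:
                raise ValueError(f"unknown missing policy {missing!r}")
            continue
        p = obesity_assoc[s.snp_id]
        ok = p >= threshold
        log.record(
            s.snp_id, "pleiotropy-obesity", ok,
            f"obesity p={p:.3g} {'>=' if ok else '<'} {threshold:.3g}",
        )
        if ok:
            kept.append(s)
    return kept, log
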