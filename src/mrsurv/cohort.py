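"""Individual-level cohort container.

A :class:`CohortTable` wraps a pandas DataFrame of per-woman rows —
SNP dosages (0/1/2), covariates (age, BMI, MET physical-activity score,
percent calories from saturated fat, genetic principal components),
binary insulin-resistance status per phenotype, and a right-censored
colorectal-cancer outcome — together with the column roles, so the
association scans and the simulator speak the same dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["CohortTable"]


@dataclass
class CohortTable:
    data: pd.DataFrame
    snp_cols: list[str]
    covariate_cols: list[str]
    ir_cols: dict[str, str]  # phenotype tag -> binary status column
    time_col: str = "time"
    event_col: str = "event"
    snp_phenotypes: dict[str, str] | None = None  # snp -> phenotype it instruments

    def __post_init__(self) -> None:
        cols = set(self.data.columns)
        for c in (*self.snp_cols, *self.covariate_cols, *self.ir_cols.values(),
                  self.time_col, self.event_col):
            if c not in cols:
                raise ValueError(f"cohort is missing column {c!r}")
        if (self.data[self.time_col] <= 0).any():
            raise ValueError("follow-up times must be positive")
        ev = self.data[self.event_col]
        if not ev.isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        dos = self.data[self.snp_cols].to_numpy()
        if np.any((dos < 0) | (dos > 2)):
            raise ValueError("dosages must lie in [0, 2]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data[self.event_col].sum())

    def subset(self, mask) -> "CohortTable":
        return CohortTable(
            data=self.data.loc[mask].reset_index(drop=True),
            snp_cols=list(self.snp_cols),
            covariate_cols=list(self.covariate_cols),
            ir_cols=dict(self.ir_cols),
            time_col=self.time_col,
            event_col=self.event_col,
            snp_phenotypes=dict(self.snp_phenotypes) if self.snp_phenotypes else None,
        )

    # -- I/O: TSV body plus a YAML sidecar naming the column roles -------

    def to_tsv(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False)
        sidecar = {
            "snp_cols": list(self.snp_cols),
            "covariate_cols": list(self.covariate_cols),
            "ir_cols": dict(self.ir_cols),
            "time_col": self.time_col,
            "event_col": self.event_col,
            "snp_phenotypes": self.snp_phenotypes,
        }
        path.with_suffix(path.suffix + ".yaml").write_text(
            yaml.safe_dump(sidecar, sort_keys=False)
        )

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        path = Path(path)
        sidecar = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
        return cls(data=pd.read_csv(path, sep="\t"), **sidecar)
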