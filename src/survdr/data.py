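"""Cohort container: genotype matrix plus right-censored survival outcome.

Genotypes are coded as minor-allele counts in {0, 1, 2}; the outcome is an
observed time (study time units, >= 0) and an event indicator (1 = event
observed, 0 = right-censored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalData"]


@dataclass
class SurvivalData:
    """One row per subject: SNP genotypes, observed time, event indicator.

    Parameters
    ----------
    genotypes : (n_subjects, n_snps) integer array with values in {0, 1, 2}.
    time : (n_subjects,) float array of observed times, finite and >= 0.
    event : (n_subjects,) integer array; 1 = event, 0 = right-censored.
    snp_names : one identifier per genotype column.
    meta : free-form provenance (simulation parameters, causative SNPs, ...).
    """

    genotypes: np.ndarray
    time: np.ndarray
    event: np.ndarray
    snp_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(np.asarray(self.genotypes, dtype=np.int8))
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        self.snp_names = list(self.snp_names)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix (subjects x SNPs)")
        n = self.genotypes.shape[0]
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match number of subjects")
        if len(self.snp_names) != self.genotypes.shape[1]:
            raise ValueError("snp_names length must match number of genotype columns")
        if n == 0:
            raise ValueError("empty cohort")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("invalid time: times must be finite and >= 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if self.genotypes.size and not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must take values in {0, 1, 2}")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def censorship(self) -> float:
        """Fraction of right-censored subjects."""
        return float(1.0 - self.event.mean())

    def subset(self, idx) -> "SurvivalData":
        """Row subset (subjects), preserving column order and metadata."""
        idx = np.asarray(idx)
        return SurvivalData(
            genotypes=self.genotypes[idx],
            time=self.time[idx],
            event=self.event[idx],
            snp_names=self.snp_names,
            meta=dict(self.meta),
        )

    def column_index(self, name: str) -> int:
        try:
            return self.snp_names.index(name)
        except ValueError:
            raise KeyError(f"unknown SNP column: {name!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=self.snp_names)
        df["time"] = self.time
        df["event"] = self.event.astype(int)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: dict | None = None) -> "SurvivalData":
        if "time" not in df.columns or "event" not in df.columns:
            raise ValueError("dataframe must contain 'time' and 'event' columns")
        snp_cols = [c for c in df.columns if c not in ("time", "event")]
        return cls(
            genotypes=df[snp_cols].to_numpy(),
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(),
            snp_names=snp_cols,
            meta=meta or {},
        )
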