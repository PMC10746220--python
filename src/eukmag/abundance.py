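"""RPKM and CPM abundance matrices from read-recruitment counts.

RPKM(i, s) = X(i, s) / (l(i) * N(s)) with X = reads recruited to MAG i in
sample s, l = MAG length in kilobases and N = total trimmed reads in the
sample in millions.  CPM renormalizes each sample's RPKM column to sum to
one million, which makes samples directly comparable regardless of
sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CPM_SCALE = 1_000_000.0


@dataclass
class ReadCountTable:
    """Reads per (MAG, sample), MAG lengths in kb, per-sample totals in millions."""

    X: pd.DataFrame          # MAG x sample, non-negative counts
    lengths_kb: pd.Series    # per MAG, > 0
    totals_millions: pd.Series  # per sample, > 0

    def __post_init__(self) -> None:
        self.X = self.X.astype(float)
        self.lengths_kb = self.lengths_kb.astype(float).reindex(self.X.index)
        self.totals_millions = self.totals_millions.astype(float).reindex(self.X.columns)
        if self.lengths_kb.isna().any():
            missing = list(self.lengths_kb[self.lengths_kb.isna()].index)
            raise ValueError(f"MAGs without a length: {missing[:5]}")
        if self.totals_millions.isna().any():
            missing = list(self.totals_millions[self.totals_millions.isna()].index)
            raise ValueError(f"samples without a read total: {missing[:5]}")
        if (self.lengths_kb <= 0).any():
            raise ValueError("MAG lengths must be positive")
        if (self.totals_millions <= 0).any():
            raise ValueError("per-sample read totals must be positive")
        if not np.isfinite(self.X.values).all() or (self.X.values < 0).any():
            raise ValueError("read counts must be finite and non-negative")

    @classmethod
    def from_long_tables(
        cls,
        counts: pd.DataFrame,
        lengths: pd.DataFrame,
        totals: pd.DataFrame,
    ) -> "ReadCountTable":
        """Build from long tables: (mag_id, sample_id, reads),
        (mag_id, length_bp), (sample_id, total_reads).  Lengths are
        converted bp -> kb and totals reads -> millions here."""
        X = counts.pivot_table(
            index="mag_id", columns="sample_id", values="reads", fill_value=0.0,
            aggfunc="sum",
        )
        lengths_kb = lengths.set_index("mag_id")["length_bp"].astype(float) / 1_000.0
        totals_millions = (
            totals.set_index("sample_id")["total_reads"].astype(float) / 1_000_000.0
        )
        return cls(X, lengths_kb, totals_millions)


@dataclass
class AbundanceMatrix:
    """MAG x sample abundance values under one metric (RPKM or CPM)."""

    values: pd.DataFrame
    metric: str  # "RPKM" | "CPM"

    def __post_init__(self) -> None:
        if self.metric not in ("RPKM", "CPM"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if (self.values.values < 0).any():
            raise ValueError("abundance values must be non-negative")


def rpkm(counts: ReadCountTable) -> AbundanceMatrix:
    """Reads per kilobase per million mapped reads."""
    values = counts.X.div(counts.lengths_kb, axis=0).div(counts.totals_millions, axis=1)
    return AbundanceMatrix(values, "RPKM")


def cpm(rpkm_matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Counts per million: each sample's RPKM column rescaled to sum to 1e6.

    Samples recruiting no reads at all yield an all-zero column (with a
    logged warning) rather than an error, since very sparse samples are
    routine in environmental surveys.
    """
    if rpkm_matrix.metric != "RPKM":
        raise ValueError("cpm() expects an RPKM matrix")
    vals = rpkm_matrix.values
    col_sums = vals.sum(axis=0)
    empty = col_sums[col_sums == 0].index
    if len(empty):
        logger.warning(
            "samples with zero total RPKM left as all-zero columns: %s",
            list(empty),
        )
    safe = col_sums.replace(0, np.nan)
    out = vals.div(safe, axis=1).fillna(0.0) * CPM_SCALE
    return AbundanceMatrix(out, "CPM")


def cpm_from_counts(counts: ReadCountTable) -> AbundanceMatrix:
    return cpm(rpkm(counts))
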