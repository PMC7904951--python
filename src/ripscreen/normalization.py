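"""RPM and RPKM abundance measures.

RPM(g, s) = count(g, s) / total(s) * 1e6, with total(s) the sum of per-gene
counts of sample s — the only library total recoverable from a count table.
RPKM(g, s) = RPM(g, s) * 1e3 / length_nt(g), lengths being longest-isoform
transcript lengths. Each matrix is normalized on its own totals; matrices
from different datasets are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountMatrix, GeneAnnotation, ValidationError

UNITS = ("RPM", "RPKM")


@dataclass
class AbundanceMatrix:
    """Non-negative real gene x sample abundances with a unit tag."""

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown abundance unit {self.unit!r}")
        if np.any(self.values.to_numpy() < 0):
            raise ValidationError("abundance values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def column(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    def mean_over(self, sample_ids) -> pd.Series:
        """Mean abundance across the named samples (replicate averaging)."""
        ids = list(sample_ids)
        if not ids:
            raise ValidationError("empty sample subset")
        return self.values[ids].mean(axis=1)


def compute_rpm(counts: CountMatrix) -> AbundanceMatrix:
    """Reads-per-million normalization of a count matrix.

    Raises if any sample has a zero total: silently zero-filling would hide
    an empty library.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValidationError(f"sample(s) with zero total counts: {zero}")
    values = counts.counts.astype(float).div(totals, axis=1) * 1e6
    return AbundanceMatrix(values, "RPM")


def compute_rpkm(rpm: AbundanceMatrix, annotation: GeneAnnotation) -> AbundanceMatrix:
    """RPKM = RPM * 1e3 / longest-isoform transcript length (nt)."""
    if rpm.unit != "RPM":
        raise ValidationError(f"compute_rpkm expects RPM input, got {rpm.unit}")
    lengths = annotation.lengths.reindex(rpm.values.index)
    missing = lengths[lengths.isna()].index.tolist()
    if missing:
        raise ValidationError(f"gene(s) with no annotated length: {missing}")
    values = rpm.values.mul(1e3 / lengths.astype(float), axis=0)
    return AbundanceMatrix(values, "RPKM")
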