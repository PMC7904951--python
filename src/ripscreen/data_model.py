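"""Core domain types for the RIP-seq / gonad RNA-seq analysis pipeline.

The pipeline's contract starts at gene-level count tables: a
:class:`CountMatrix` holds non-negative integer counts (genes x samples)
together with per-sample metadata, a :class:`GeneAnnotation` holds
longest-isoform transcript lengths, and :class:`AnalysisConfig` collects
every numeric threshold the analysis applies, with defaults equal to the
published constants (enrichment FC >= 4, RPKM >= 1 bound call; RPKM > 1
expressed call; FC > 2, q < 0.05 differential call; pseudocounts 1 and 2).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

TISSUES = frozenset({"gonad", "whole_animal", "ip", "mock_ip"})
_BASE_GENOTYPES = frozenset({"wild_type", "mutant", "rescue"})
_VARIANT_RE = re.compile(r"^variant-[A-Za-z0-9_.]+$")


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _check_genotype(genotype: str) -> None:
    if genotype not in _BASE_GENOTYPES and not _VARIANT_RE.match(genotype):
        raise ValidationError(
            f"unknown genotype label {genotype!r}; expected one of "
            f"{sorted(_BASE_GENOTYPES)} or 'variant-<label>'"
        )


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing sample.

    ``tissue`` and ``genotype`` are drawn from closed vocabularies; unknown
    labels fail at construction rather than being coerced.
    """

    sample_id: str
    tissue: str
    genotype: str
    temperature_c: float
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"unknown tissue label {self.tissue!r} for sample "
                f"{self.sample_id!r}; expected one of {sorted(TISSUES)}"
            )
        _check_genotype(self.genotype)
        if not (isinstance(self.replicate, (int, np.integer)) and self.replicate >= 1):
            raise ValidationError(
                f"replicate must be a positive integer, got {self.replicate!r} "
                f"for sample {self.sample_id!r}"
            )


@dataclass
class CountMatrix:
    """Integer gene x sample read counts plus aligned sample metadata.

    ``counts`` is a pandas DataFrame indexed by gene id with one column per
    sample id, in file order. ``samples`` is aligned to the columns.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches every keyword condition."""
        out = []
        for s in self.samples:
            if all(getattr(s, k) == v for k, v in conditions.items()):
                out.append(s.sample_id)
        return out

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        metas = [self.meta(s) for s in ids]
        return CountMatrix(self.counts[ids].copy(), metas)

    def validate(self) -> None:
        idx = self.counts.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene id(s): {dup}")
        cols = self.counts.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dup}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # allow float input only if every value is integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count at gene {idx[g]!r}, sample {cols[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        meta_ids = [s.sample_id for s in self.samples]
        if sorted(meta_ids) != sorted(cols.tolist()):
            raise ValidationError(
                "metadata sample set does not match count-matrix columns: "
                f"metadata={sorted(meta_ids)} columns={sorted(cols.tolist())}"
            )
        # keep metadata aligned to column order; canonical axis naming
        order = {sid: i for i, sid in enumerate(cols)}
        self.samples = sorted(self.samples, key=lambda s: order[s.sample_id])
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None


@dataclass
class GeneAnnotation:
    """Per-gene longest-isoform transcript lengths (nucleotides)."""

    lengths: pd.Series  # index: gene_id, values: int nt
    biotypes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.lengths.index.has_duplicates:
            dup = self.lengths.index[self.lengths.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene id(s) in annotation: {dup}")
        if np.any(self.lengths.to_numpy() < 1):
            bad = self.lengths[self.lengths < 1].index.tolist()
            raise ValidationError(f"non-positive transcript length for: {bad}")
        self.lengths = self.lengths.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.lengths.index)

    def length_of(self, gene_id: str) -> int:
        return int(self.lengths.loc[gene_id])


@dataclass
class AnalysisConfig:
    """All thresholds of the analysis, defaulting to the published values.

    rip_fc_min / rip_rpkm_min
        bound-transcript call: enrichment FC >= 4 and IP RPKM >= 1.
    expressed_rpkm_min
        expressed-gene call: mean RPKM strictly > 1.
    de_fc_min / de_q_max
        differential call: fold change strictly > 2 and BH q < 0.05
        (``use_raw_p`` switches the significance column to the raw p value).
    sef_pseudocount / rip_pseudocount
        +2 in the soma-enrichment factor, +1 in the enrichment FC.
    rescue_fc_max
        a class-I gene counts as rescued when its pseudocounted
        rescue/wild-type expression ratio is below this fold.
    oro_stain_threshold
        minimum red-minus-blue excess for a pixel to count as stained.
    """

    rip_fc_min: float = 4.0
    rip_rpkm_min: float = 1.0
    expressed_rpkm_min: float = 1.0
    de_fc_min: float = 2.0
    de_q_max: float = 0.05
    sef_pseudocount: float = 2.0
    rip_pseudocount: float = 1.0
    rescue_fc_max: float = 2.0
    oro_stain_threshold: float = 0.05
    use_raw_p: bool = False
    seed: int = 0
    paths: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    _THRESHOLDS = (
        "rip_fc_min", "rip_rpkm_min", "expressed_rpkm_min", "de_fc_min",
        "de_q_max", "sef_pseudocount", "rip_pseudocount", "rescue_fc_max",
        "oro_stain_threshold",
    )

    def __post_init__(self) -> None:
        for name in self._THRESHOLDS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"threshold {name} must be > 0, got {v!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
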