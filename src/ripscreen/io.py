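"""Validated readers and writers for count matrices, annotations and results.

All on-disk formats are UTF-8, tab-separated, with a header row; gene ids
occupy the first column. Abundance tables carry a ``# unit=RPM|RPKM``
comment line so the unit survives a round trip.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CountMatrix, GeneAnnotation, SampleMeta, ValidationError
from .normalization import AbundanceMatrix

logger = logging.getLogger(__name__)

_METADATA_COLUMNS = ["sample_id", "tissue", "genotype", "temperature_c", "replicate"]


def read_sample_metadata(path) -> list[SampleMeta]:
    """Read a sample-metadata TSV (sample_id, tissue, genotype, temperature_c, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(_METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"metadata file {path} lacks column(s): {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
            genotype=str(r.genotype),
            temperature_c=float(r.temperature_c),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_sample_metadata(samples: list[SampleMeta], path) -> None:
    df = pd.DataFrame(
        [[s.sample_id, s.tissue, s.genotype, s.temperature_c, s.replicate] for s in samples],
        columns=_METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_count_matrix(path, metadata) -> CountMatrix:
    """Read a gene x sample count TSV and attach sample metadata.

    ``metadata`` is a path to a metadata TSV or an already-built list of
    :class:`SampleMeta`. Gene order is preserved from the file; duplicate
    gene ids, non-integer or negative cells and metadata/header mismatches
    are load errors.
    """
    if not isinstance(metadata, list):
        metadata = read_sample_metadata(metadata)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene id(s) in {path}: {dup}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValidationError(
                f"non-integer or negative count in {path} at gene {gene!r}, sample {col!r}"
            )
        df[col] = vals.astype(np.int64)
    return CountMatrix(df, metadata)


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_gene_lengths(path, format: str = "tsv") -> GeneAnnotation:
    """Load longest-isoform transcript lengths from a TSV or a GTF.

    TSV input needs ``gene_id`` and ``length_nt`` columns (``biotype``
    optional). For GTF input, each transcript's length is the sum of its
    exon lengths on 1-based inclusive coordinates (end - start + 1), exons
    taken as given without overlap merging, and each gene's length is the
    maximum over its transcripts — i.e. the longest isoform.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        missing = {"gene_id", "length_nt"} - set(df.columns)
        if missing:
            raise ValidationError(f"annotation TSV lacks column(s): {sorted(missing)}")
        lengths = pd.Series(
            df["length_nt"].to_numpy(), index=df["gene_id"].to_numpy(), name="length_nt"
        )
        biotypes = None
        if "biotype" in df.columns:
            biotypes = pd.Series(df["biotype"].to_numpy(), index=lengths.index)
        return GeneAnnotation(lengths, biotypes)
    if format == "gtf":
        return _read_gene_lengths_gtf(path)
    raise ValidationError(f"unknown annotation format {format!r}; expected 'tsv' or 'gtf'")


def _read_gene_lengths_gtf(path) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_len: dict[tuple[str, str], int] = {}
    declared_genes: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype == "gene":
            declared_genes.add(feat.attributes["gene_id"][0])
        elif feat.featuretype == "exon":
            gene = feat.attributes["gene_id"][0]
            tx = feat.attributes["transcript_id"][0]
            exon_len = feat.end - feat.start + 1
            if exon_len <= 0:
                raise ValidationError(
                    f"exon with non-positive length in {path}: {gene}/{tx} "
                    f"{feat.start}-{feat.end}"
                )
            tx_len[(gene, tx)] = tx_len.get((gene, tx), 0) + exon_len
    gene_len: dict[str, int] = {}
    for (gene, _tx), L in tx_len.items():
        gene_len[gene] = max(gene_len.get(gene, 0), L)
    exonless = declared_genes - set(gene_len)
    if exonless:
        raise ValidationError(f"gene(s) with no exon features: {sorted(exonless)}")
    if not gene_len:
        raise ValidationError(f"no exon features found in {path}")
    lengths = pd.Series(gene_len, name="length_nt").sort_index()
    return GeneAnnotation(lengths)


def write_gene_lengths(ann: GeneAnnotation, path) -> None:
    df = ann.lengths.rename_axis("gene_id").reset_index()
    if ann.biotypes is not None:
        df["biotype"] = ann.biotypes.reindex(ann.lengths.index).to_numpy()
    df.to_csv(path, sep="\t", index=False)


def write_results_table(table: pd.DataFrame, path) -> None:
    """Write a result table as deterministic TSV.

    Rows are sorted by ``gene_id`` unless a ``rank`` column exists (then by
    rank); floats are rendered with 6 significant digits. An empty table
    yields a header-only file.
    """
    df = table.copy()
    if "rank" in df.columns:
        df = df.sort_values("rank", kind="mergesort")
    elif "gene_id" in df.columns:
        df = df.sort_values("gene_id", kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_abundance(am: AbundanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# unit={am.unit}\n")
        am.values.rename_axis("gene_id").to_csv(fh, sep="\t", float_format="%.6g")


def read_abundance(path) -> AbundanceMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# unit="):
            raise ValidationError(f"{path} lacks the '# unit=' header line")
        unit = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return AbundanceMatrix(df.astype(float), unit)


def read_gene_list(path) -> list[str]:
    """Read a one-id-per-line gene list, ignoring blanks."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))
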