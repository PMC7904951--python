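"""Pseudo-counted IP/mock enrichment and bound-transcript calling.

A transcript's immunoprecipitation enrichment is the ratio of its RPM in
the IP library to its RPM in the mock-IP library, each incremented by 1 so
the ratio stays finite when the mock recovers nothing:

    FC = (IP RPM + 1) / (mock RPM + 1)

Bound transcripts are those with FC >= 4 and IP-sample RPKM >= 1 (both
comparisons inclusive). The mock RPKM plays no role.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import ValidationError
from .normalization import AbundanceMatrix

logger = logging.getLogger(__name__)

RIP_COLUMNS = ["gene_id", "ip_rpm", "mock_rpm", "enrichment_fc", "ip_rpkm", "bound"]


def _as_single_column(am: AbundanceMatrix, which: str) -> pd.Series:
    """Collapse an abundance matrix to one column, averaging replicates."""
    if len(am.sample_ids) == 1:
        return am.values.iloc[:, 0]
    logger.info("averaging %d replicate columns for %s", len(am.sample_ids), which)
    return am.values.mean(axis=1)


def ip_enrichment(
    ip: AbundanceMatrix,
    mock: AbundanceMatrix,
    ip_rpkm: AbundanceMatrix,
    pseudocount: float = 1.0,
    fc_min: float = 4.0,
    rpkm_min: float = 1.0,
) -> pd.DataFrame:
    """Build the per-transcript enrichment table (one row per gene).

    The three inputs must share one gene universe. Replicate columns, if
    present, are averaged before the FC formula. The returned frame has
    columns ``gene_id, ip_rpm, mock_rpm, enrichment_fc, ip_rpkm, bound``.
    """
    if ip.unit != "RPM" or mock.unit != "RPM":
        raise ValidationError("ip and mock must be RPM matrices")
    if ip_rpkm.unit != "RPKM":
        raise ValidationError("ip_rpkm must be an RPKM matrix")
    universes = [set(ip.gene_ids), set(mock.gene_ids), set(ip_rpkm.gene_ids)]
    union = set().union(*universes)
    inter = universes[0] & universes[1] & universes[2]
    if union != inter:
        diff = sorted(union - inter)
        raise ValidationError(
            f"gene universes differ between IP/mock/RPKM inputs; "
            f"symmetric difference ({len(diff)} ids): {diff[:10]}"
        )
    ip_col = _as_single_column(ip, "IP")
    mock_col = _as_single_column(mock, "mock IP").reindex(ip_col.index)
    rpkm_col = _as_single_column(ip_rpkm, "IP RPKM").reindex(ip_col.index)
    fc = (ip_col + pseudocount) / (mock_col + pseudocount)
    table = pd.DataFrame(
        {
            "gene_id": ip_col.index,
            "ip_rpm": ip_col.to_numpy(),
            "mock_rpm": mock_col.to_numpy(),
            "enrichment_fc": fc.to_numpy(),
            "ip_rpkm": rpkm_col.to_numpy(),
        }
    )
    table["bound"] = (table["enrichment_fc"] >= fc_min) & (table["ip_rpkm"] >= rpkm_min)
    return table


def call_bound(table: pd.DataFrame, fc_min: float = 4.0, rpkm_min: float = 1.0) -> list[str]:
    """Genes with enrichment_fc >= fc_min and ip_rpkm >= rpkm_min (inclusive)."""
    keep = (table["enrichment_fc"] >= fc_min) & (table["ip_rpkm"] >= rpkm_min)
    return sorted(table.loc[keep, "gene_id"].tolist())


def binding_condition_summary(
    tables: Mapping[str, pd.DataFrame],
    fc_min: float = 4.0,
    rpkm_min: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Compare RNA-binding strength (IP RPM) across conditions.

    For every ordered condition pair the fraction of transcripts with
    strictly higher IP RPM in the first condition is reported, alongside
    per-condition bound-set sizes — the comparison behind variant- and
    temperature-wise binding rankings.
    """
    labels = list(tables)
    if len(labels) < 2:
        raise ValidationError("need at least 2 conditions to summarize binding")
    universe = None
    for lab, tab in tables.items():
        genes = set(tab["gene_id"])
        if universe is None:
            universe = genes
        elif genes != universe:
            raise ValidationError(f"condition {lab!r} has a different gene universe")
    per_condition = pd.DataFrame(
        {
            "condition": labels,
            "n_bound": [len(call_bound(tables[c], fc_min, rpkm_min)) for c in labels],
            "median_ip_rpm": [float(tables[c]["ip_rpm"].median()) for c in labels],
        }
    )
    rows = []
    for a, b in itertools.permutations(labels, 2):
        sa = tables[a].set_index("gene_id")["ip_rpm"]
        sb = tables[b].set_index("gene_id")["ip_rpm"].reindex(sa.index)
        higher = int((sa > sb).sum())
        tied = int((sa == sb).sum())
        n = len(sa)
        rows.append((a, b, higher, higher / n, tied / n))
    pairs = pd.DataFrame(
        rows, columns=["condition_a", "condition_b", "n_higher", "frac_higher", "frac_tied"]
    )
    return {"per_condition": per_condition, "pairs": pairs}
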