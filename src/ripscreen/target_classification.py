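"""Germline target classification and soma-enrichment scoring.

Bound transcripts that are differentially expressed in the mutant gonad
split into two classes: class I (upregulated in the mutant, hence normally
repressed by the endoribonuclease) and class II (downregulated, hence
normally sustained). Binding enrichment of a gene group is tested on a 2x2
contingency table with Pearson's chi-square. Soma-vs-germline expression
bias per gene is the soma enrichment factor

    SEF = (RPKM_whole_animal + 2) / (RPKM_gonad + 2)

with the +2 pseudocount damping ratios driven by tiny RPKMs. Group SEF
distributions are compared on the log scale by one-way ANOVA with Dunnett
comparisons against a reference group. Rescue of class-I misexpression is
scored per gene by whether the rescue-strain expression sits within a
configurable fold of wild type (same +2 pseudocount).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ValidationError
from .normalization import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class TargetClasses:
    class_i: tuple[str, ...]
    class_ii: tuple[str, ...]
    up_unbound: tuple[str, ...]
    down_unbound: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for label, genes in [
            ("class_i", self.class_i),
            ("class_ii", self.class_ii),
            ("up_unbound", self.up_unbound),
            ("down_unbound", self.down_unbound),
        ]:
            rows.extend((g, label) for g in genes)
        return pd.DataFrame(rows, columns=["gene_id", "class"])


@dataclass
class EnrichmentTestResult:
    group_bound: int
    group_unbound: int
    rest_bound: int
    rest_unbound: int
    chi_square: float
    p_value: float
    low_count: bool = False

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.group_bound, self.group_unbound],
             [self.rest_bound, self.rest_unbound]]
        )


@dataclass
class SefComparison:
    summary: pd.DataFrame
    anova_f: float | None
    anova_p: float | None
    dunnett: pd.DataFrame | None


@dataclass
class RescueAssessment:
    per_gene: pd.DataFrame  # wt_mean, mutant_mean, rescue_mean, ratio, rescued
    fraction_rescued: float
    heatmap: pd.DataFrame = field(repr=False, default=None)


def call_expressed(
    rpkm: AbundanceMatrix,
    samples: list[str] | None = None,
    threshold: float = 1.0,
    rule: str = "mean",
) -> list[str]:
    """Genes scored as expressed: RPKM strictly > threshold.

    Replicates are combined by the mean by default; ``rule`` may also be
    ``"all"`` (every replicate above threshold) or ``"any"``.
    """
    ids = samples if samples is not None else rpkm.sample_ids
    if not ids:
        raise ValidationError("empty sample subset for expressed-gene call")
    vals = rpkm.values[list(ids)]
    if rule == "mean":
        keep = vals.mean(axis=1) > threshold
    elif rule == "all":
        keep = (vals > threshold).all(axis=1)
    elif rule == "any":
        keep = (vals > threshold).any(axis=1)
    else:
        raise ValidationError(f"unknown expressed-call rule {rule!r}")
    return sorted(vals.index[keep].tolist())


def classify_targets(up, down, bound) -> TargetClasses:
    """Intersect differential gene sets with the bound set.

    class I = up ∩ bound, class II = down ∩ bound; the unbound complements
    are kept so the partition invariants are checkable.
    """
    up, down, bound = set(up), set(down), set(bound)
    overlap = up & down
    if overlap:
        raise ValidationError(
            f"up and down sets overlap ({len(overlap)} ids): {sorted(overlap)[:10]}"
        )
    return TargetClasses(
        class_i=tuple(sorted(up & bound)),
        class_ii=tuple(sorted(down & bound)),
        up_unbound=tuple(sorted(up - bound)),
        down_unbound=tuple(sorted(down - bound)),
    )


def binding_enrichment_test(group, universe, bound) -> EnrichmentTestResult:
    """Pearson chi-square (df=1, no continuity correction) for binding
    enrichment of ``group`` within ``universe``."""
    group, universe, bound = set(group), set(universe), set(bound)
    if not group <= universe:
        raise ValidationError("group must be a subset of the universe")
    rest = universe - group
    a = len(group & bound)
    b = len(group - bound)
    c = len(rest & bound)
    d = len(rest - bound)
    obs = np.array([[a, b], [c, d]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if total == 0 or np.any(row == 0) or np.any(col == 0):
        # degenerate margin: no departure from independence is expressible
        return EnrichmentTestResult(a, b, c, d, 0.0, 1.0, low_count=True)
    expected = np.outer(row, col) / total
    low = bool(np.any(expected < 1))
    if low:
        logger.warning("chi-square expected cell < 1; result flagged low_count")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return EnrichmentTestResult(a, b, c, d, float(chi2), float(p), low_count=low)


def compute_sef(
    rpkm_whole: AbundanceMatrix,
    rpkm_gonad: AbundanceMatrix,
    pseudocount: float = 2.0,
) -> pd.DataFrame:
    """Per-gene soma enrichment factor table.

    Replicate columns are averaged before the formula; the gene universe is
    the intersection of the two inputs (mismatches logged).
    """
    if rpkm_whole.unit != "RPKM" or rpkm_gonad.unit != "RPKM":
        raise ValidationError("compute_sef expects RPKM matrices")
    w = rpkm_whole.values.mean(axis=1)
    g = rpkm_gonad.values.mean(axis=1)
    shared = w.index.intersection(g.index)
    dropped = len(w.index.symmetric_difference(g.index))
    if dropped:
        logger.warning("%d gene(s) absent from one SEF input; using intersection", dropped)
    w, g = w.loc[shared], g.loc[shared]
    if (w < 0).any() or (g < 0).any():
        raise ValidationError("negative RPKM in SEF input (corrupt data)")
    sef = (w + pseudocount) / (g + pseudocount)
    return pd.DataFrame(
        {
            "gene_id": shared,
            "rpkm_whole": w.to_numpy(),
            "rpkm_gonad": g.to_numpy(),
            "sef": sef.to_numpy(),
        }
    )


def compare_sef_groups(
    sef: pd.DataFrame,
    groups: dict[str, set],
    reference: str = "total",
) -> SefComparison:
    """Quartile summaries plus one-way ANOVA and Dunnett comparisons of
    log-SEF for each named group against the reference group."""
    if reference not in groups:
        raise ValidationError(f"reference group {reference!r} not among {sorted(groups)}")
    by_gene = sef.set_index("gene_id")["sef"]
    logs: dict[str, np.ndarray] = {}
    rows = []
    for name, genes in groups.items():
        genes = set(genes)
        if not genes:
            raise ValidationError(f"group {name!r} is empty")
        missing = genes - set(by_gene.index)
        if missing:
            raise ValidationError(
                f"group {name!r} has {len(missing)} id(s) outside the SEF universe"
            )
        vals = by_gene.loc[sorted(genes)].to_numpy()
        logs[name] = np.log(vals)
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        rows.append((name, len(vals), q25, q50, q75))
    summary = pd.DataFrame(rows, columns=["group", "n", "q25", "median", "q75"])

    if len(logs) < 2 or any(len(v) < 2 for v in logs.values()):
        if any(len(v) < 2 for v in logs.values()):
            logger.warning("a group has < 2 members; SEF tests skipped")
        return SefComparison(summary, None, None, None)

    f_stat, anova_p = stats.f_oneway(*logs.values())
    others = [name for name in groups if name != reference]
    drows = []
    if others:
        res = stats.dunnett(*(logs[name] for name in others), control=logs[reference])
        for i, name in enumerate(others):
            drows.append(
                (name, float(np.mean(logs[name]) - np.mean(logs[reference])),
                 float(res.pvalue[i]))
            )
    dunnett = pd.DataFrame(drows, columns=["group", "mean_log_sef_diff", "p_value"])
    return SefComparison(summary, float(f_stat), float(anova_p), dunnett)


def derive_somatic_targets(soma_up, bound, gonad_up) -> tuple[list[str], list[str]]:
    """Direct somatic targets: soma-upregulated, bound, and not gonad-up.

    candidates = soma_up ∩ bound; somatic_targets = candidates \\ gonad_up.
    """
    soma_up, bound, gonad_up = set(soma_up), set(bound), set(gonad_up)
    candidates = sorted(soma_up & bound)
    somatic = sorted(set(candidates) - gonad_up)
    return candidates, somatic


def assess_rescue(
    expr: AbundanceMatrix,
    genotype_samples: dict[str, list[str]],
    class_i,
    criterion_fc: float = 2.0,
    pseudocount: float = 2.0,
) -> RescueAssessment:
    """Score per-gene rescue of class-I misexpression.

    ``genotype_samples`` maps ``wild_type`` / ``mutant`` / ``rescue`` to
    sample columns of ``expr``. A gene is rescued when
    (rescue_mean + 2) / (wild_type_mean + 2) < criterion_fc. The heat-map
    matrix carries the three pseudocounted genotype means relative to wild
    type, rows ordered by mutant/wild-type ratio descending.
    """
    for geno in ("wild_type", "mutant", "rescue"):
        if not genotype_samples.get(geno):
            raise ValidationError(f"missing samples for genotype {geno!r}")
    class_i = sorted(set(class_i))
    if not class_i:
        raise ValidationError("empty class-I set")
    missing = set(class_i) - set(expr.gene_ids)
    if missing:
        raise ValidationError(f"class-I gene(s) absent from expression matrix: {sorted(missing)[:10]}")
    means = {
        geno: expr.mean_over(ids).loc[class_i]
        for geno, ids in genotype_samples.items()
    }
    rescue_ratio = (means["rescue"] + pseudocount) / (means["wild_type"] + pseudocount)
    mutant_ratio = (means["mutant"] + pseudocount) / (means["wild_type"] + pseudocount)
    per_gene = pd.DataFrame(
        {
            "gene_id": class_i,
            "wt_mean": means["wild_type"].to_numpy(),
            "mutant_mean": means["mutant"].to_numpy(),
            "rescue_mean": means["rescue"].to_numpy(),
            "mutant_ratio": mutant_ratio.to_numpy(),
            "rescue_ratio": rescue_ratio.to_numpy(),
        }
    )
    per_gene["rescued"] = per_gene["rescue_ratio"] < criterion_fc
    fraction = float(per_gene["rescued"].mean())
    order = per_gene.sort_values("mutant_ratio", ascending=False, kind="mergesort")
    heat = order.set_index("gene_id")[["mutant_ratio", "rescue_ratio"]].copy()
    heat.insert(0, "wild_type", 1.0)
    heat.columns = ["wild_type", "mutant", "rescue"]
    per_gene = order.reset_index(drop=True)
    per_gene.insert(0, "rank", np.arange(1, len(per_gene) + 1))
    return RescueAssessment(per_gene, fraction, heat)
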