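"""End-to-end orchestration: normalize -> rip-call -> DE -> classify -> SEF
-> rescue (-> recovery metrics on synthetic bundles)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import diffexpr, normalization, rip_enrichment, target_classification as tc
from .data_model import AnalysisConfig, ValidationError
from .normalization import AbundanceMatrix
from .synthetic_data import SyntheticBundle, evaluate_recovery

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    rip_table: pd.DataFrame
    bound: list[str]
    de_result: pd.DataFrame
    up: list[str]
    down: list[str]
    classes: tc.TargetClasses
    expressed_gonad: list[str]
    up_enrichment: tc.EnrichmentTestResult
    down_enrichment: tc.EnrichmentTestResult
    sef: pd.DataFrame
    sef_comparison: tc.SefComparison
    rescue: tc.RescueAssessment | None
    recovery: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def report(self) -> dict:
        """The paper-style summary counts of a run."""
        rep = {
            "n_genes": int(len(self.rip_table)),
            "n_bound": len(self.bound),
            "n_expressed_gonad": len(self.expressed_gonad),
            "n_up": len(self.up),
            "n_down": len(self.down),
            "n_class_i": len(self.classes.class_i),
            "n_class_ii": len(self.classes.class_ii),
            "up_bound_overlap": f"{len(self.classes.class_i)} of {len(self.up)}",
            "down_bound_overlap": f"{len(self.classes.class_ii)} of {len(self.down)}",
            "up_enrichment_chi2": self.up_enrichment.chi_square,
            "up_enrichment_p": self.up_enrichment.p_value,
            "down_enrichment_chi2": self.down_enrichment.chi_square,
            "down_enrichment_p": self.down_enrichment.p_value,
        }
        if self.sef_comparison.anova_p is not None:
            rep["sef_anova_p"] = self.sef_comparison.anova_p
        for _, row in self.sef_comparison.summary.iterrows():
            rep[f"sef_median_{row['group']}"] = float(row["median"])
        if self.rescue is not None:
            rep["fraction_rescued"] = self.rescue.fraction_rescued
        return rep


def run_bundle(
    bundle: SyntheticBundle,
    config: AnalysisConfig | None = None,
    de_table: pd.DataFrame | None = None,
    evaluate: bool = True,
) -> PipelineResult:
    """Run every analysis stage on a (synthetic or real) bundle.

    ``de_table`` bypasses the built-in NB test with a precomputed
    differential table. With ``evaluate`` the planted truth is scored.
    """
    cfg = config or AnalysisConfig()

    # --- abundances -------------------------------------------------------
    rip_rpm = normalization.compute_rpm(bundle.rip)
    gonad_rpm = normalization.compute_rpm(bundle.gonad)
    gonad_rpkm = normalization.compute_rpkm(gonad_rpm, bundle.annotation)
    whole_rpm = normalization.compute_rpm(bundle.whole_animal)
    whole_rpkm = normalization.compute_rpkm(whole_rpm, bundle.annotation)

    ip_ids = bundle.rip.samples_where(tissue="ip")
    mock_ids = bundle.rip.samples_where(tissue="mock_ip")
    if not ip_ids or not mock_ids:
        raise ValidationError("rip matrix needs both an ip and a mock_ip sample")
    ip_rpm = AbundanceMatrix(rip_rpm.values[ip_ids], "RPM")
    mock_rpm = AbundanceMatrix(rip_rpm.values[mock_ids], "RPM")
    ip_rpkm = AbundanceMatrix(
        normalization.compute_rpkm(ip_rpm, bundle.annotation).values, "RPKM"
    )

    # --- bound-transcript calling ----------------------------------------
    rip_table = rip_enrichment.ip_enrichment(
        ip_rpm, mock_rpm, ip_rpkm,
        pseudocount=cfg.rip_pseudocount,
        fc_min=cfg.rip_fc_min, rpkm_min=cfg.rip_rpkm_min,
    )
    bound = rip_enrichment.call_bound(rip_table, cfg.rip_fc_min, cfg.rip_rpkm_min)
    logger.info("bound-transcript call: %d of %d genes", len(bound), len(rip_table))

    # --- differential expression (mutant vs wild-type gonad) --------------
    wt_ids = bundle.gonad.samples_where(genotype="wild_type")
    mut_ids = bundle.gonad.samples_where(genotype="mutant")
    if de_table is not None:
        de_result = diffexpr.load_external_de(de_table)
    else:
        two_group = bundle.gonad.subset_samples(wt_ids + mut_ids)
        groups = {s: ("wild_type" if s in wt_ids else "mutant") for s in wt_ids + mut_ids}
        de_result = diffexpr.nb_wald_test(
            two_group, groups, reference="wild_type",
            fc_min=cfg.de_fc_min, q_max=cfg.de_q_max,
        )
    up, down = diffexpr.filter_de(
        de_result, cfg.de_fc_min, cfg.de_q_max, use_raw_p=cfg.use_raw_p
    )
    logger.info("differential call: %d up, %d down", len(up), len(down))

    # --- classification + binding enrichment ------------------------------
    classes = tc.classify_targets(up, down, bound)
    expressed = tc.call_expressed(gonad_rpkm, wt_ids + mut_ids, cfg.expressed_rpkm_min)
    universe = sorted(set(expressed) | set(up) | set(down))
    up_enr = tc.binding_enrichment_test(up, universe, bound)
    down_enr = tc.binding_enrichment_test(down, universe, bound)

    # --- soma enrichment factor -------------------------------------------
    gonad_wt_rpkm = AbundanceMatrix(gonad_rpkm.values[wt_ids], "RPKM")
    sef = tc.compute_sef(whole_rpkm, gonad_wt_rpkm, cfg.sef_pseudocount)
    sef_universe = set(sef["gene_id"])
    groups = {"total": sef_universe}
    if classes.class_i:
        groups["class_i"] = set(classes.class_i) & sef_universe
    if len(set(classes.class_ii) & sef_universe) >= 2:
        groups["class_ii"] = set(classes.class_ii) & sef_universe
    sef_cmp = tc.compare_sef_groups(sef, groups, reference="total")

    # --- rescue ------------------------------------------------------------
    rescue = None
    res_ids = bundle.gonad.samples_where(genotype="rescue")
    if res_ids and classes.class_i:
        rescue = tc.assess_rescue(
            gonad_rpkm,
            {"wild_type": wt_ids, "mutant": mut_ids, "rescue": res_ids},
            classes.class_i,
            criterion_fc=cfg.rescue_fc_max,
            pseudocount=cfg.sef_pseudocount,
        )

    recovery = None
    if evaluate and bundle.truth is not None:
        recovery = evaluate_recovery(
            bundle.truth, bound, classes.class_i, classes.class_ii,
            sef_table=sef,
            fraction_rescued=None if rescue is None else rescue.fraction_rescued,
            rescue_efficiency=None if bundle.config is None else bundle.config.rescue_efficiency,
        )

    return PipelineResult(
        rip_table=rip_table, bound=bound, de_result=de_result, up=up, down=down,
        classes=classes, expressed_gonad=expressed,
        up_enrichment=up_enr, down_enrichment=down_enr,
        sef=sef, sef_comparison=sef_cmp, rescue=rescue, recovery=recovery,
        extras={"gonad_rpkm": gonad_rpkm, "whole_rpkm": whole_rpkm, "rip_rpm": rip_rpm},
    )
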