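"""Expressed calling, class I/II assignment, chi-square, SEF and rescue."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ripscreen import (
    ValidationError,
    assess_rescue,
    binding_enrichment_test,
    call_expressed,
    classify_targets,
    compare_sef_groups,
    compute_sef,
    derive_somatic_targets,
)
from ripscreen.normalization import AbundanceMatrix


def rpkm_of(values, genes=None, columns=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and genes and len(genes) > 1:
        values = values.T
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    columns = columns or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=genes, columns=columns), "RPKM")


class TestCallExpressed:
    def test_exactly_one_not_expressed(self):
        am = rpkm_of([[1.0], [1.0001]])
        assert call_expressed(am) == ["g1"]

    def test_mean_rule_over_replicates(self):
        am = rpkm_of([[0.6, 1.8]])  # mean 1.2 > 1
        assert call_expressed(am) == ["g0"]
        assert call_expressed(am, rule="all") == []
        assert call_expressed(am, rule="any") == ["g0"]

    def test_zero_threshold_includes_all_positive(self, rng):
        am = rpkm_of(rng.uniform(0.01, 5, (20, 2)))
        assert call_expressed(am, threshold=1e-9) == sorted(am.gene_ids)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValidationError):
            call_expressed(rpkm_of([[1.0]]), samples=[])


class TestClassifyTargets:
    def test_partition_invariants_on_random_sets(self, rng):
        ids = np.array([f"g{i}" for i in range(100)])
        for _ in range(20):
            up = set(rng.choice(ids, 30, replace=False))
            down = set(rng.choice(sorted(set(ids) - up), 10, replace=False))
            bound = set(rng.choice(ids, 40, replace=False))
            tc = classify_targets(up, down, bound)
            assert set(tc.class_i) == up & bound
            assert set(tc.class_ii) == down & bound
            assert set(tc.class_i) | set(tc.up_unbound) == up
            assert set(tc.class_ii) | set(tc.down_unbound) == down
            assert not set(tc.class_i) & set(tc.class_ii)

    def test_disjoint_bound_gives_empty_classes(self):
        tc = classify_targets({"a"}, {"b"}, {"z"})
        assert tc.class_i == () and tc.class_ii == ()

    def test_overlapping_up_down_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            classify_targets({"a", "b"}, {"b"}, set())

    def test_outputs_sorted(self):
        tc = classify_targets({"z", "a", "m"}, set(), {"z", "a", "m"})
        assert tc.class_i == ("a", "m", "z")


class TestBindingEnrichment:
    def test_independence_gives_zero_statistic(self):
        # group and rest have identical binding fraction (1/2)
        group = {f"a{i}" for i in range(10)}
        rest = {f"b{i}" for i in range(10)}
        bound = {f"a{i}" for i in range(5)} | {f"b{i}" for i in range(5)}
        res = binding_enrichment_test(group, group | rest, bound)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_statistic_twenty(self):
        """Table (10,0,0,10) evaluates to chi-square 20 by hand."""
        group = {f"a{i}" for i in range(10)}
        rest = {f"b{i}" for i in range(10)}
        res = binding_enrichment_test(group, group | rest, group)
        assert (res.group_bound, res.group_unbound,
                res.rest_bound, res.rest_unbound) == (10, 0, 0, 10)
        assert res.chi_square == pytest.approx(20.0)

    def test_matches_cellwise_oracle_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 50, 4)
            group = {f"g{i}" for i in range(a + b)}
            rest = {f"r{i}" for i in range(c + d)}
            bound = {f"g{i}" for i in range(a)} | {f"r{i}" for i in range(c)}
            res = binding_enrichment_test(group, group | rest, bound)
            obs = np.array([[a, b], [c, d]], dtype=float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            chi2 = ((obs - exp) ** 2 / exp).sum()
            assert res.chi_square == pytest.approx(chi2)
            assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_margins_equal_input_sizes(self):
        group = {"a", "b"}
        universe = {"a", "b", "c", "d", "e"}
        res = binding_enrichment_test(group, universe, {"a", "c"})
        assert res.table.sum() == len(universe)
        assert res.table[0].sum() == len(group)

    def test_low_expected_cell_flagged(self, caplog):
        res = binding_enrichment_test({"a"}, {"a", "b", "c"}, {"a"})
        assert res.low_count

    def test_group_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            binding_enrichment_test({"x"}, {"a"}, set())


class TestComputeSef:
    def test_equal_inputs_give_one(self, rng):
        vals = rng.uniform(0, 100, 20)
        sef = compute_sef(rpkm_of(vals, genes=[f"g{i}" for i in range(20)]),
                          rpkm_of(vals, genes=[f"g{i}" for i in range(20)]))
        np.testing.assert_allclose(sef["sef"], 1.0)

    def test_direct_arithmetic(self):
        sef = compute_sef(rpkm_of([[8.0]]), rpkm_of([[0.0]]))
        assert sef["sef"].iloc[0] == pytest.approx(5.0)

    def test_zero_zero_is_one(self):
        sef = compute_sef(rpkm_of([[0.0]]), rpkm_of([[0.0]]))
        assert sef["sef"].iloc[0] == pytest.approx(1.0)

    def test_monotone_and_bounded(self, rng):
        w = rng.uniform(0, 50, 100)
        g = rng.uniform(0, 50, 100)
        genes = [f"g{i}" for i in range(100)]
        base = compute_sef(rpkm_of(w, genes=genes), rpkm_of(g, genes=genes))["sef"]
        more_soma = compute_sef(rpkm_of(w + 1, genes=genes), rpkm_of(g, genes=genes))["sef"]
        more_gonad = compute_sef(rpkm_of(w, genes=genes), rpkm_of(g + 1, genes=genes))["sef"]
        assert (more_soma > base).all()
        assert (more_gonad < base).all()
        assert (base <= (w + 2) / 2 + 1e-12).all()

    def test_replicates_averaged(self):
        whole = rpkm_of([[2.0, 6.0]])  # mean 4
        gonad = rpkm_of([[1.0, 1.0]])
        sef = compute_sef(whole, gonad)
        assert sef["sef"].iloc[0] == pytest.approx((4 + 2) / (1 + 2))

    def test_universe_intersection_used(self, caplog):
        whole = rpkm_of([1.0, 2.0], genes=["a", "b"])
        gonad = rpkm_of([1.0, 2.0], genes=["a", "c"])
        with caplog.at_level("WARNING"):
            sef = compute_sef(whole, gonad)
        assert sef["gene_id"].tolist() == ["a"]


class TestCompareSefGroups:
    @staticmethod
    def sef_frame(values):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(values))],
                             "sef": values})

    def test_identical_group_has_p_near_one(self, rng):
        vals = rng.lognormal(0, 1, 200)
        sef = self.sef_frame(vals)
        total = set(sef["gene_id"])
        cmp = compare_sef_groups(sef, {"total": total, "same": set(total)})
        assert cmp.dunnett["p_value"].iloc[0] > 0.99

    def test_shifted_group_detected(self, rng):
        """A group shifted +1 on the log scale (n=200) is significant at
        p < 0.001 in >= 99 of 100 seeded repeats."""
        hits = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            base = r.lognormal(0, 1, 800)
            shifted = r.lognormal(1, 1, 200)
            sef = self.sef_frame(np.concatenate([base, shifted]))
            total = set(sef["gene_id"])
            group = set(sef["gene_id"].iloc[800:])
            cmp = compare_sef_groups(sef, {"total": total, "class_i": group})
            hits += cmp.dunnett["p_value"].iloc[0] < 0.001
        assert hits >= 99

    def test_null_anova_calibrated(self):
        """Disjoint groups drawn from one distribution: fraction of ANOVA
        p < 0.05 within 0.05 +/- 0.02 over 500 seeded repeats."""
        hits = 0
        for rep in range(500):
            r = np.random.default_rng(10_000 + rep)
            sef = self.sef_frame(r.lognormal(0, 1, 300))
            ids = sef["gene_id"].to_numpy()
            groups = {"total": set(ids[:100]), "a": set(ids[100:200]),
                      "b": set(ids[200:300])}
            cmp = compare_sef_groups(sef, groups)
            hits += cmp.anova_p < 0.05
        assert 0.03 <= hits / 500 <= 0.07

    def test_quartile_summary_matches_percentiles(self, rng):
        vals = rng.lognormal(0, 1, 101)
        sef = self.sef_frame(vals)
        cmp = compare_sef_groups(sef, {"total": set(sef["gene_id"])})
        row = cmp.summary.iloc[0]
        assert row["median"] == pytest.approx(np.median(vals))
        assert row["q25"] == pytest.approx(np.percentile(vals, 25))

    def test_tiny_group_skips_tests(self, rng, caplog):
        sef = self.sef_frame(rng.lognormal(0, 1, 50))
        with caplog.at_level("WARNING"):
            cmp = compare_sef_groups(
                sef, {"total": set(sef["gene_id"]), "one": {"g0"}}
            )
        assert cmp.anova_f is None and cmp.dunnett is None
        assert len(cmp.summary) == 2

    def test_group_outside_universe_rejected(self, rng):
        sef = self.sef_frame(rng.lognormal(0, 1, 10))
        with pytest.raises(ValidationError):
            compare_sef_groups(sef, {"total": set(sef["gene_id"]), "bad": {"nope"}})


class TestDeriveSomaticTargets:
    def test_intersections_and_subtraction(self):
        soma_up = {"a", "b", "c", "d"}
        bound = {"b", "c", "d", "e"}
        gonad_up = {"c"}
        candidates, somatic = derive_somatic_targets(soma_up, bound, gonad_up)
        assert candidates == ["b", "c", "d"]
        assert somatic == ["b", "d"]

    def test_full_subtraction_empties_result(self):
        candidates, somatic = derive_somatic_targets({"a"}, {"a"}, {"a", "z"})
        assert candidates == ["a"] and somatic == []

    def test_equals_brute_force_scan(self, rng):
        ids = np.array([f"g{i}" for i in range(200)])
        for _ in range(20):
            soma_up = set(rng.choice(ids, 50, replace=False))
            bound = set(rng.choice(ids, 80, replace=False))
            gonad_up = set(rng.choice(ids, 30, replace=False))
            cand, som = derive_somatic_targets(soma_up, bound, gonad_up)
            assert cand == sorted(g for g in ids if g in soma_up and g in bound)
            assert som == sorted(g for g in cand if g not in gonad_up)


class TestAssessRescue:
    @staticmethod
    def expr_matrix(wt, mut, res, genes=None):
        genes = genes or [f"g{i}" for i in range(len(wt))]
        df = pd.DataFrame({"wt1": wt, "mut1": mut, "res1": res},
                          index=genes, dtype=float)
        return AbundanceMatrix(df, "RPKM")

    GENO = {"wild_type": ["wt1"], "mutant": ["mut1"], "rescue": ["res1"]}

    def test_identical_to_wild_type_fully_rescued(self, rng):
        wt = rng.uniform(1, 50, 20)
        expr = self.expr_matrix(wt, wt * 10, wt)
        res = assess_rescue(expr, self.GENO, expr.gene_ids)
        assert res.fraction_rescued == 1.0

    def test_stuck_at_mutant_level_not_rescued(self, rng):
        wt = rng.uniform(10, 50, 20)
        expr = self.expr_matrix(wt, wt * 10, wt * 10)
        res = assess_rescue(expr, self.GENO, expr.gene_ids)
        assert res.fraction_rescued == 0.0

    def test_heatmap_rows_ordered_by_mutant_ratio(self, rng):
        wt = rng.uniform(5, 50, 30)
        mut = wt * rng.uniform(2, 20, 30)
        expr = self.expr_matrix(wt, mut, wt)
        res = assess_rescue(expr, self.GENO, expr.gene_ids)
        ratios = res.heatmap["mutant"].to_numpy()
        assert (np.diff(ratios) <= 1e-12).all()

    def test_missing_genotype_rejected(self, rng):
        expr = self.expr_matrix([1.0], [2.0], [1.0])
        with pytest.raises(ValidationError, match="rescue"):
            assess_rescue(expr, {"wild_type": ["wt1"], "mutant": ["mut1"]}, ["g0"])

    def test_empty_class_rejected(self):
        expr = self.expr_matrix([1.0], [2.0], [1.0])
        with pytest.raises(ValidationError):
            assess_rescue(expr, self.GENO, [])

    def test_planted_eighty_percent_recovered(self, small_bundle):
        """On the synthetic bundle the measured rescue fraction tracks the
        planted 0.8 efficiency."""
        from ripscreen import compute_rpkm, compute_rpm

        rpkm = compute_rpkm(compute_rpm(small_bundle.gonad), small_bundle.annotation)
        geno = {
            g: small_bundle.gonad.samples_where(genotype=g)
            for g in ("wild_type", "mutant", "rescue")
        }
        res = assess_rescue(rpkm, geno, small_bundle.truth.class_i)
        assert res.fraction_rescued == pytest.approx(0.8, abs=0.15)
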