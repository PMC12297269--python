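"""ACO-P / ACO-C aggregation, baselines, and the comparison report."""

from __future__ import annotations

import numpy as np
import pytest

from antscale.aco import AcoRunResult, SubsetEvaluation
from antscale.pheromone import total_pheromone
from antscale.scale import ItemSubset
from antscale.selection import (
    baseline_top_loadings,
    comparison_report,
    consensus,
    evaluate_fixed_subset,
    select_aco_c,
    select_aco_p,
    subset_from_items,
)


def _run(items, phi):
    comps = total_pheromone(1.0, 0.0, [0.95], [0.95], 0.0)
    object.__setattr__(comps, "phi_total", phi)
    ev = SubsetEvaluation(ItemSubset({"f": tuple(items)}), None, comps)
    return AcoRunResult(ev, (), 1, False, 0)


class TestAcoP:
    def test_highest_pheromone_run_wins(self):
        runs = [_run("abc", 3.1), _run("abd", 3.4), _run("abd", 3.4),
                _run("acd", 2.9), _run("abd", 3.4)]
        assert select_aco_p(runs).key == ("a", "b", "d")

    def test_single_run(self):
        assert select_aco_p([_run("xyz", 1.0)]).key == ("x", "y", "z")

    def test_tie_breaks_lexicographically(self):
        runs = [_run("bcd", 3.4), _run("abc", 3.4)]
        assert select_aco_p(runs).key == ("a", "b", "c")

    def test_all_infeasible_is_fatal(self):
        bad = total_pheromone(0, 0, [0], [0], 0, feasible=False, reason="x")
        runs = [AcoRunResult(SubsetEvaluation(ItemSubset({"f": ("a",)}), None, bad),
                             (), 1, False, 0)]
        with pytest.raises(RuntimeError, match="infeasible"):
            select_aco_p(runs)


class TestAcoC:
    def _five_runs(self):
        return [_run(s, 3.0) for s in ("ABC", "ABD", "ACD", "ABC", "ABE")]

    def test_counting_example_at_60_percent(self):
        chosen, counts = select_aco_c(self._five_runs(), 0.6)
        assert chosen == ("A", "B", "C")
        assert counts == {"A": 5, "B": 4, "C": 3, "D": 2, "E": 1}

    def test_threshold_one_keeps_unanimous_items(self):
        chosen, _ = select_aco_c(self._five_runs(), 1.0)
        assert chosen == ("A",)

    def test_identical_runs_return_that_subset(self):
        runs = [_run("PQR", 2.0)] * 3
        chosen, _ = select_aco_c(runs, 0.6)
        assert chosen == ("P", "Q", "R")

    def test_vanishing_threshold_gives_union_threshold_one_intersection(self):
        runs = self._five_runs()
        union, _ = select_aco_c(runs, 1e-9)
        inter, _ = select_aco_c(runs, 1.0)
        assert set(union) == {"A", "B", "C", "D", "E"}
        assert set(inter) == {"A"}

    def test_empty_consensus_warns(self):
        runs = [_run("AB", 1.0), _run("CD", 1.0), _run("EF", 1.0)]
        with pytest.warns(RuntimeWarning, match="empty consensus"):
            chosen, _ = select_aco_c(runs, 0.9)
        assert chosen == ()

    def test_needs_two_runs(self):
        with pytest.raises(ValueError, match="2 runs"):
            select_aco_c([_run("AB", 1.0)], 0.6)

    def test_consensus_result_fields(self):
        agg = consensus(self._five_runs(), 0.6)
        assert agg.aco_p.key == ("A", "B", "C")
        assert agg.aco_c == ("A", "B", "C")
        assert agg.n_runs == 5


class TestBaseline:
    def test_top_loadings_per_factor(self, planted):
        subset = baseline_top_loadings(planted["reference"], planted["scale"])
        lam = planted["reference"].fit.loadings
        for f in planted["scale"].factors:
            chosen = set(subset.by_factor[f])
            for other in set(planted["scale"].items_in(f)) - chosen:
                assert all(lam[c] >= lam[other] for c in chosen)

    def test_quota_equal_to_pool_returns_everything(self, planted):
        scale = planted["scale"]
        full = type(scale)(scale.item_ids, scale.factor_of,
                           {f: len(scale.items_in(f)) for f in scale.factors}, 5)
        subset = baseline_top_loadings(planted["reference"], full)
        assert subset.key == tuple(sorted(scale.item_ids))

    def test_tie_at_quota_boundary_breaks_lexicographically(self, planted):
        # synthetic reference with a deliberate tie
        from antscale.aco import ReferenceFit
        from antscale.cfa import CfaFit

        scale = planted["scale"]
        lam = {i: 0.5 for i in scale.item_ids}
        lam["p01"] = lam["p02"] = 0.9  # remaining pros tie at 0.5
        fit = CfaFit(scale.item_ids, scale.factors, lam, np.eye(2),
                     0.0, 8, 1.0, 15, 1.0, 0.0, {}, True, False, 100)
        ref = ReferenceFit(fit, planted["reference"].sum_scores)
        subset = baseline_top_loadings(ref, scale)
        assert subset.by_factor["pros"] == ("p01", "p02", "p03")


class TestFixedEvaluation:
    def test_aco_best_reevaluates_to_its_recorded_score(self, planted):
        best = planted["exhaustive_best"]
        again = evaluate_fixed_subset(best.subset, planted["data"],
                                      planted["corr"], planted["reference"])
        assert again.phi_total == pytest.approx(best.phi_total, abs=1e-9)

    def test_unknown_item_is_fatal(self, planted):
        with pytest.raises(ValueError):
            evaluate_fixed_subset(ItemSubset({"pros": ("nope",)}),
                                  planted["data"], planted["corr"],
                                  planted["reference"])


class TestReport:
    def test_df_column_follows_item_count(self, planted):
        best = planted["exhaustive_best"]
        scale = planted["scale"]
        full = evaluate_fixed_subset(subset_from_items(scale.item_ids, scale),
                                     planted["data"], planted["corr"],
                                     planted["reference"])
        rep = comparison_report([("full", full), ("short", best)])
        assert rep.loc["full", "df"] == 12 * 11 // 2 - 12 - 1
        assert rep.loc["short", "df"] == 6 * 5 // 2 - 6 - 1

    def test_values_match_fit_fields_exactly(self, planted):
        best = planted["exhaustive_best"]
        rep = comparison_report([("s", best)])
        assert rep.loc["s", "cfi"] == best.fit.cfi
        assert rep.loc["s", "rmsea"] == best.fit.rmsea
        assert rep.loc["s", "phi_total"] == best.phi_total

    def test_empty_report_is_fatal(self):
        with pytest.raises(ValueError):
            comparison_report([])
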