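"""Ant-colony mechanics: sampling, deposit/evaporation, the run loop."""

from __future__ import annotations

import numpy as np
import pytest

from antscale.aco import (
    TAU_MIN,
    AcoConfig,
    PheromoneState,
    SubsetEvaluation,
    evaluate_subset,
    run_aco,
    sample_subset,
    update_pheromone,
)
from antscale.pheromone import total_pheromone
from antscale.scale import ItemSubset
from antscale.selection import subset_from_items


def _eval_stub(items_by_factor, phi):
    subset = ItemSubset(items_by_factor)
    if phi == 0:
        comps = total_pheromone(0, 0, [0], [0], 0, feasible=False, reason="stub")
    else:
        comps = total_pheromone(1.0, 0.0, [1.0], [1.0], 0.0)
        object.__setattr__(comps, "phi_total", phi)
    return SubsetEvaluation(subset, None, comps)


class TestSampling:
    def test_concentrated_tau_selects_those_items(self, small_scale):
        tau = {i: TAU_MIN for i in small_scale.item_ids}
        for i in ("a0", "a1", "a2", "b0", "b1", "b2"):
            tau[i] = 1.0
        state = PheromoneState(tau)
        rng = np.random.default_rng(0)
        hits = sum(
            sample_subset(state, small_scale, rng).key
            == ("a0", "a1", "a2", "b0", "b1", "b2")
            for _ in range(1000)
        )
        assert hits >= 999

    def test_uniform_tau_marginals_near_half(self, small_scale):
        state = PheromoneState.initial(small_scale)
        rng = np.random.default_rng(1)
        counts = {i: 0 for i in small_scale.item_ids}
        n = 10_000
        for _ in range(n):
            for i in sample_subset(state, small_scale, rng).key:
                counts[i] += 1
        freqs = np.array(list(counts.values())) / n
        # 3 of 5 chosen per factor: marginal 0.6
        np.testing.assert_allclose(freqs, 0.6, atol=0.03)

    def test_fixed_seed_is_deterministic(self, small_scale):
        state = PheromoneState.initial(small_scale)
        s1 = sample_subset(state, small_scale, np.random.default_rng(7))
        s2 = sample_subset(state, small_scale, np.random.default_rng(7))
        assert s1 == s2

    def test_quota_and_membership_respected(self, small_scale):
        state = PheromoneState.initial(small_scale)
        rng = np.random.default_rng(3)
        for _ in range(50):
            sub = sample_subset(state, small_scale, rng)
            sub.validate_against(small_scale)


class TestPheromoneUpdate:
    def test_decay_then_deposit_arithmetic(self, small_scale):
        state = PheromoneState({i: 1.0 for i in small_scale.item_ids})
        best = _eval_stub({"f1": ("a0", "a1", "a2"), "f2": ("b0", "b1", "b2")}, 2.0)
        new = update_pheromone(state, best, 0.5)
        for i in small_scale.item_ids:
            expected = 2.5 if i in best.subset.key else 0.5
            assert new.tau[i] == pytest.approx(expected)

    def test_infeasible_best_gives_pure_decay(self, small_scale):
        state = PheromoneState({i: 1.0 for i in small_scale.item_ids})
        best = _eval_stub({"f1": ("a0", "a1", "a2"), "f2": ("b0", "b1", "b2")}, 0)
        new = update_pheromone(state, best, 0.5)
        assert all(v == pytest.approx(0.5) for v in new.tau.values())

    def test_repeated_decay_floors_at_tau_min(self, small_scale):
        state = PheromoneState({i: 1.0 for i in small_scale.item_ids})
        best = _eval_stub({"f1": ("a0", "a1", "a2"), "f2": ("b0", "b1", "b2")}, 0)
        for _ in range(60):
            state = update_pheromone(state, best, 0.5)
        assert all(v == TAU_MIN for v in state.tau.values())

    def test_no_evaporation_no_deposit_is_stationary(self, small_scale):
        state = PheromoneState({i: 1.5 for i in small_scale.item_ids})
        best = _eval_stub({"f1": ("a0", "a1", "a2"), "f2": ("b0", "b1", "b2")}, 0)
        new = update_pheromone(state, best, 1.0)
        assert new.tau == state.tau


class TestEvaluate:
    def test_full_pool_subset_is_self_similar(self, planted):
        scale, data = planted["scale"], planted["data"]
        full = subset_from_items(scale.item_ids,
                                 scale)
        ev = evaluate_subset(full, data, planted["corr"], planted["reference"])
        assert ev.components.phi_corr == pytest.approx(
            1.0 / (1.0 + np.exp(85 - 100)), abs=1e-6
        )  # correlation exactly 1
        assert ev.components.phi_fc == pytest.approx(
            1.0 / (1.0 + np.exp(-3.0)), abs=1e-4
        )  # factor-correlation difference ~ 0 up to optimizer noise

    def test_planted_subset_dominates_random_rivals(self, planted):
        best = planted["exhaustive_best"]
        rng = np.random.default_rng(5)
        evals = planted["all_evaluations"]
        for _ in range(100):
            rival = evals[rng.integers(len(evals))]
            assert best.phi_total >= rival.phi_total

    def test_planted_items_score_near_the_top(self, planted):
        # at N=500 sampling noise may displace the planted set by one item,
        # but it must rank in the top 1% of all candidates
        evals = sorted(planted["all_evaluations"],
                       key=lambda e: -e.phi_total)
        keys = [e.subset.key for e in evals[:4]]
        assert tuple(sorted(planted["planted_items"])) in keys


class TestRunLoop:
    def test_trace_best_is_non_decreasing(self, planted):
        res = run_aco(planted["data"], planted["scale"],
                      AcoConfig(n_ants=20, max_iterations=10, seed=0),
                      corr=planted["corr"], reference=planted["reference"])
        best = [r["best_phi"] for r in res.trace]
        assert best == sorted(best)
        assert res.iterations_executed == len(res.trace)

    def test_zero_patience_runs_exactly_one_iteration(self, planted):
        res = run_aco(planted["data"], planted["scale"],
                      AcoConfig(n_ants=10, max_iterations=50, patience=0, seed=1),
                      corr=planted["corr"], reference=planted["reference"])
        assert res.iterations_executed == 1
        assert res.converged_early

    def test_fixed_seed_reproduces_the_trace(self, planted):
        kwargs = dict(corr=planted["corr"], reference=planted["reference"])
        cfg = AcoConfig(n_ants=15, max_iterations=8, seed=11)
        r1 = run_aco(planted["data"], planted["scale"], cfg, **kwargs)
        r2 = run_aco(planted["data"], planted["scale"], cfg, **kwargs)
        assert r1.trace == r2.trace
        assert r1.best.subset == r2.best.subset

    def test_best_subset_respects_quotas(self, planted):
        res = run_aco(planted["data"], planted["scale"],
                      AcoConfig(n_ants=10, max_iterations=5, seed=2),
                      corr=planted["corr"], reference=planted["reference"])
        res.best.subset.validate_against(planted["scale"])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"n_ants": 0}, {"evaporation": 0.0}, {"evaporation": 1.5},
                   {"max_iterations": 0}, {"patience": -1}, {"n_runs": 0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcoConfig(**kwargs)
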