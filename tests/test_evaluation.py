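"""Actionability scoring, baseline paths, comparators, Welch's t-test."""

import math
from itertools import product

import numpy as np
import pytest

import actipath as ap
from conftest import (
    LatticeDensity,
    lattice_schema,
    linear_predictor,
    random_lattice_table,
    unit_grid,
)


def scene(dim, lower, upper, table=None, coefs=None, directions=None):
    schema = lattice_schema(dim, directions)
    table = table or {
        k: -1.0 for k in product(range(lower, upper + 1), repeat=dim)
    }
    sur = LatticeDensity(schema, table)
    pred = linear_predictor(schema, coefs or {f"x{i+1}": 1.0 for i in range(dim)})
    grid = unit_grid(dim, lower, upper)
    instance = {f"x{i+1}": 0.0 for i in range(dim)}
    ev = ap.NodeEvaluator(instance, sur, pred, grid)
    return instance, sur, pred, grid, ev


class TestRandomShortestPaths:
    def test_two_step_displacement_enumerates_interleavings(self):
        _, _, _, grid, ev = scene(2, -2, 2)
        start, end = ev.get((0, 0)), ev.get((1, 1))
        paths = ap.random_shortest_paths(start, end, n=40, seed=0, evaluator=ev)
        seen = {tuple(n.offsets for n in p.nodes) for p in paths}
        allowed = {
            ((0, 0), (1, 0), (1, 1)),
            ((0, 0), (0, 1), (1, 1)),
        }
        assert seen == allowed  # both interleavings, nothing else

    def test_single_variable_displacement_unique_path(self):
        _, _, _, grid, ev = scene(2, -3, 3)
        start, end = ev.get((0, 0)), ev.get((-3, 0))
        paths = ap.random_shortest_paths(start, end, n=10, seed=1, evaluator=ev)
        first = tuple(n.offsets for n in paths[0].nodes)
        assert all(tuple(n.offsets for n in p.nodes) == first for p in paths)

    def test_length_equals_manhattan_distance(self):
        _, _, _, grid, ev = scene(3, -2, 2)
        start, end = ev.get((0, 0, 0)), ev.get((2, -1, 1))
        for p in ap.random_shortest_paths(start, end, n=15, seed=2, evaluator=ev):
            assert len(p) == 1 + 4  # nodes = moves + 1

    def test_identical_endpoints_give_zero_length_paths(self):
        _, _, _, grid, ev = scene(2, -1, 1)
        start = ev.get((0, 0))
        paths = ap.random_shortest_paths(start, start, n=3, seed=3, evaluator=ev)
        assert len(paths) == 3 and all(len(p) == 1 for p in paths)


class TestActionabilityScore:
    def test_monotone_single_variable_path_scores_exactly_zero(self):
        # optimal path moves one variable monotonically: the baseline
        # family has a single member — the path itself
        instance, sur, pred, grid, ev = scene(2, -3, 3, coefs={"x1": 1.0, "x2": 0.0})
        res = ap.plan_path(instance, sur, pred, grid, L=10_000, evaluator=ev)
        sc = ap.actionability_score(res.path, ev, n_baseline=10, seed=0)
        assert sc.score == 0.0

    def test_uniform_probabilities_score_zero(self):
        # all nodes equally probable and a Manhattan-length optimal path
        instance, sur, pred, grid, ev = scene(2, -2, 2)
        res = ap.plan_path(instance, sur, pred, grid, L=10_000, evaluator=ev)
        assert len(res.path) - 1 == sum(abs(o) for o in res.destination.offsets)
        sc = ap.actionability_score(res.path, ev, n_baseline=25, seed=1)
        assert sc.score == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_over_two_interleavings(self):
        # 2-variable, 1-step-each: baselines are exactly 2 interleavings
        table = {(0, 0): -0.5, (1, 0): -0.2, (0, 1): -1.2, (1, 1): -0.4}
        instance, sur, pred, grid, ev = scene(2, 0, 1, table=table)
        grid = ap.GridSpec(names=("x1", "x2"), steps=(1.0, 1.0),
                           lower=(0, 0), upper=(1, 1), origin=(0.0, 0.0))
        ev = ap.NodeEvaluator(instance, sur, pred, grid)
        res = ap.plan_path(instance, sur, pred, grid, objective="maximize",
                           L=100, evaluator=ev)
        assert res.destination.offsets == (1, 1)
        sc = ap.actionability_score(res.path, ev, n_baseline=1000, seed=4)
        log_a_opt = res.path.log_actionability      # routes via (1, 0)
        log_a1 = table[(0, 0)] + table[(1, 0)] + table[(1, 1)]
        log_a2 = table[(0, 0)] + table[(0, 1)] + table[(1, 1)]
        closed_form = log_a_opt - 0.5 * (log_a1 + log_a2)
        assert abs(sc.score - closed_form) < 0.05

    def test_invariant_to_constant_log_probability_shift(self):
        table = random_lattice_table(2, -2, 2, seed=9)
        instance, sur, pred, grid, ev = scene(2, -2, 2, table=table)
        res = ap.plan_path(instance, sur, pred, grid, L=10_000, evaluator=ev)
        sc = ap.actionability_score(res.path, ev, n_baseline=20, seed=5)

        shifted = {k: v + 7.5 for k, v in table.items()}
        instance2, sur2, pred2, grid2, ev2 = scene(2, -2, 2, table=shifted)
        res2 = ap.plan_path(instance2, sur2, pred2, grid2, L=10_000, evaluator=ev2)
        sc2 = ap.actionability_score(res2.path, ev2, n_baseline=20, seed=5)
        assert sc2.score == pytest.approx(sc.score, abs=1e-9)

    def test_variance_shrinks_with_more_baselines(self):
        table = random_lattice_table(2, -3, 3, seed=10)
        instance, sur, pred, grid, ev = scene(2, -3, 3, table=table)
        res = ap.plan_path(instance, sur, pred, grid, L=10_000, evaluator=ev)
        small = [ap.actionability_score(res.path, ev, n_baseline=10, seed=s).score
                 for s in range(8)]
        large = [ap.actionability_score(res.path, ev, n_baseline=1000, seed=s).score
                 for s in range(8)]
        assert np.var(large) <= np.var(small) + 1e-12

    def test_reproducible_under_fixed_seed(self):
        table = random_lattice_table(2, -2, 2, seed=11)
        instance, sur, pred, grid, ev = scene(2, -2, 2, table=table)
        res = ap.plan_path(instance, sur, pred, grid, L=10_000, evaluator=ev)
        a = ap.actionability_score(res.path, ev, n_baseline=10, seed=6)
        b = ap.actionability_score(res.path, ev, n_baseline=10, seed=6)
        assert a == b

    def test_zero_probability_baseline_reported_not_crashed(self):
        table = {k: -1.0 for k in product(range(0, 2), repeat=2)}
        table[(0, 1)] = -math.inf
        table[(1, 0)] = -math.inf
        instance, sur, pred, grid, ev = scene(2, 0, 1, table=table)
        grid = ap.GridSpec(names=("x1", "x2"), steps=(1.0, 1.0),
                           lower=(0, 0), upper=(1, 1), origin=(0.0, 0.0))
        ev = ap.NodeEvaluator(instance, sur, pred, grid)
        start, end = ev.get((0, 0)), ev.get((1, 1))
        fake = ap.PlanPath([start, ev.get((1, 0)), end])
        sc = ap.actionability_score(fake, ev, n_baseline=10, seed=7)
        assert sc.infinite_baseline and math.isinf(sc.score)


class TestRandomInterventionPaths:
    def test_nine_paths_with_matched_steps_by_default(self):
        instance, sur, pred, grid, ev = scene(
            3, -4, 4, directions=["decrease"] * 3
        )
        paths = ap.random_intervention_paths(
            instance, grid, sur.schema, n_steps=5, evaluator=ev, seed=0
        )
        assert len(paths) == 9
        assert all(len(p) == 6 for p in paths)

    def test_all_decrease_directions_never_increase(self):
        instance, sur, pred, grid, ev = scene(
            2, -6, 6, directions=["decrease", "decrease"]
        )
        paths = ap.random_intervention_paths(
            instance, grid, sur.schema, n_steps=8, evaluator=ev, seed=1
        )
        for p in paths:
            offs = np.array([n.offsets for n in p.nodes])
            assert (np.diff(offs, axis=0) <= 0).all()

    def test_bound_clipping_resamples_variable(self):
        # x1 can only move 1 cell; all further moves must go to x2
        schema = lattice_schema(2, ["decrease", "decrease"])
        table = {k: -1.0 for k in product(range(-8, 1), repeat=2)}
        sur = LatticeDensity(schema, table)
        pred = linear_predictor(schema, {"x1": 1.0, "x2": 1.0})
        grid = ap.GridSpec(names=("x1", "x2"), steps=(1.0, 1.0),
                           lower=(-1, -8), upper=(0, 0), origin=(0.0, 0.0))
        ev = ap.NodeEvaluator({"x1": 0.0, "x2": 0.0}, sur, pred, grid)
        paths = ap.random_intervention_paths(
            {"x1": 0.0, "x2": 0.0}, grid, schema, n_steps=6, evaluator=ev, seed=2
        )
        for p in paths:
            final = p.nodes[-1].offsets
            assert final[0] >= -1 and sum(-o for o in final) == 6

    def test_zero_steps_rejected(self):
        instance, sur, pred, grid, ev = scene(2, -2, 2,
                                              directions=["decrease"] * 2)
        with pytest.raises(ValueError, match="n_steps"):
            ap.random_intervention_paths(
                instance, grid, sur.schema, n_steps=0, evaluator=ev
            )

    def test_free_direction_rejected(self):
        instance, sur, pred, grid, ev = scene(2, -2, 2)
        with pytest.raises(ValueError, match="direction"):
            ap.random_intervention_paths(
                instance, grid, sur.schema, n_steps=2, evaluator=ev
            )

    def test_all_variables_stuck_at_bound_errors(self):
        schema = lattice_schema(1, ["decrease"])
        table = {(0,): -1.0}
        sur = LatticeDensity(schema, table)
        pred = linear_predictor(schema, {"x1": 1.0})
        grid = ap.GridSpec(names=("x1",), steps=(1.0,), lower=(0,), upper=(0,),
                           origin=(0.0,))
        ev = ap.NodeEvaluator({"x1": 0.0}, sur, pred, grid)
        with pytest.raises(ValueError, match="bound"):
            ap.random_intervention_paths(
                {"x1": 0.0}, grid, schema, n_steps=1, evaluator=ev
            )


class TestWelch:
    def test_identical_groups(self):
        res = ap.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["statistic"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_large_separation_tiny_p(self):
        a = [1.0, 2.0, 3.0]
        b = [101.001, 102.0, 102.999]
        assert ap.welch_t_test(a, b)["p_value"] < 1e-4

    def test_matches_textbook_formula(self):
        a = [2.1, 2.5, 2.9, 3.3]
        b = [1.0, 1.6, 2.0]
        got = ap.welch_t_test(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t = (ma - mb) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy import stats

        p = 2 * stats.t.sf(abs(t), df)
        assert got["statistic"] == pytest.approx(t)
        assert got["df"] == pytest.approx(df)
        assert got["p_value"] == pytest.approx(p)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ap.welch_t_test([1.0], [1.0, 2.0])
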