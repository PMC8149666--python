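"""Step 3: grid geometry and the capped min-cost path search."""

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


def make_scene(dim, lower, upper, table=None, coefs=None, directions=None):
    """Hand-controlled planning scene on a unit lattice."""
    schema = lattice_schema(dim, directions)
    table = table or {k: -1.0 for k in product(range(lower, upper + 1), repeat=dim)}
    surrogate = LatticeDensity(schema, table)
    coefs = coefs or {f"x{i + 1}": 1.0 for i in range(dim)}
    predictor = linear_predictor(schema, coefs)
    grid = unit_grid(dim, lower, upper)
    instance = {f"x{i + 1}": 0.0 for i in range(dim)}
    return instance, surrogate, predictor, grid


class TestNeighbors:
    def test_interior_node_degree(self):
        grid = unit_grid(3, -2, 2)
        assert len(ap.neighbors((0, 0, 0), grid)) == 6

    def test_corner_node_degree(self):
        grid = unit_grid(2, -1, 1)
        assert len(ap.neighbors((-1, -1), grid)) == 2

    def test_matches_brute_force_enumeration(self):
        grid = unit_grid(3, -1, 2)
        for off in product(range(-1, 3), repeat=3):
            got = set(ap.neighbors(off, grid))
            want = set()
            for delta in product((-1, 0, 1), repeat=3):
                if sum(abs(d) for d in delta) != 1:
                    continue
                cand = tuple(o + d for o, d in zip(off, delta))
                if all(-1 <= c <= 2 for c in cand):
                    want.add(cand)
            assert got == want


class TestGridSpec:
    def test_bounds_must_include_origin(self):
        with pytest.raises(ValueError, match="offset 0"):
            ap.GridSpec(names=("x1",), steps=(1.0,), lower=(1,), upper=(2,),
                        origin=(0.0,))

    def test_missing_intervention_value_rejected(self):
        schema = lattice_schema(2)
        with pytest.raises(ValueError, match="missing"):
            ap.GridSpec.around_instance(
                {"x1": float("nan"), "x2": 0.0}, schema
            )

    def test_bounds_follow_training_range(self, bench_prepared):
        schema = bench_prepared.train.schema
        row = bench_prepared.train.row_vector(0)
        grid = ap.GridSpec.around_instance(
            row, schema, train=bench_prepared.train, step=0.2
        )
        for name, o, lo, hi in zip(grid.names, grid.origin, grid.lower, grid.upper):
            col = bench_prepared.train.values[name]
            assert o + (lo - 1) * 0.2 <= col.min() or lo == 0
            assert o + (hi + 1) * 0.2 >= col.max() or hi == 0


class TestPlanPath:
    def test_uniform_probabilities_straight_descent(self):
        # equal node probabilities; response decreasing in x1 only =>
        # monotone descent in x1 to the grid bound
        instance, sur, pred, grid = make_scene(
            2, -3, 3, coefs={"x1": 1.0, "x2": 0.0}
        )
        res = ap.plan_path(instance, sur, pred, grid, objective="minimize", L=10_000)
        assert res.destination.offsets == (-3, 0)
        assert [n.offsets for n in res.path.nodes] == [
            (0, 0), (-1, 0), (-2, 0), (-3, 0)
        ]

    def test_optimal_route_prefers_probable_corner(self):
        # two routes to the best node; the more probable interleaving wins
        table = {(0, 0): -1.0, (1, 0): -0.1, (0, 1): -5.0, (1, 1): -1.0}
        schema = lattice_schema(2)
        sur = LatticeDensity(schema, table)
        pred = linear_predictor(schema, {"x1": 1.0, "x2": 1.0})
        grid = ap.GridSpec(names=("x1", "x2"), steps=(1.0, 1.0),
                           lower=(0, 0), upper=(1, 1), origin=(0.0, 0.0))
        res = ap.plan_path({"x1": 0.0, "x2": 0.0}, sur, pred, grid,
                           objective="maximize", L=100)
        assert res.destination.prediction == 2.0  # (1,1) is the unique best
        # the path to (1,1) must route through the cheap (1,0) corner
        assert [n.offsets for n in res.path.nodes] == [(0, 0), (1, 0), (1, 1)]

    def test_destination_tie_broken_by_minimum_cost(self):
        # (1,0) and (1,1) share the best prediction (response ignores x2);
        # the destination must be the cheaper of the two
        table = {(0, 0): -1.0, (1, 0): -0.5, (0, 1): -1.0, (1, 1): -2.0}
        schema = lattice_schema(2)
        sur = LatticeDensity(schema, table)
        pred = linear_predictor(schema, {"x1": 1.0, "x2": 0.0})
        grid = ap.GridSpec(names=("x1", "x2"), steps=(1.0, 1.0),
                           lower=(0, 0), upper=(1, 1), origin=(0.0, 0.0))
        res = ap.plan_path({"x1": 0.0, "x2": 0.0}, sur, pred, grid,
                           objective="maximize", L=100)
        assert res.destination.offsets == (1, 0)

    def test_destination_tie_min_cost_rule(self):
        # flat response => every node ties; destination = lowest-cost node,
        # which is the start itself (empty path)
        instance, sur, pred, grid = make_scene(2, -2, 2, coefs={"x1": 0.0})
        res = ap.plan_path(instance, sur, pred, grid, L=1000)
        assert res.destination.offsets == (0, 0)
        assert len(res.path) == 1
        assert res.path.cost == pytest.approx(-res.path.nodes[0].log_prob)

    def test_iteration_cap_counts_finalizations(self):
        instance, sur, pred, grid = make_scene(2, -5, 5)
        res = ap.plan_path(instance, sur, pred, grid, L=7)
        assert res.n_expanded == 7
        assert res.termination == "L exhausted"
        full = ap.plan_path(instance, sur, pred, grid, L=10_000)
        assert full.termination == "frontier empty"
        assert full.n_expanded == 11 * 11

    def test_zero_probability_start_rejected(self):
        instance, sur, pred, grid = make_scene(1, -1, 1)
        sur.table[(0,)] = -np.inf
        with pytest.raises(ValueError, match="probability 0"):
            ap.plan_path(instance, sur, pred, grid, L=10)

    def test_costs_match_exhaustive_oracle_on_small_grids(self):
        # independent route: Dijkstra on an explicit node-weighted digraph
        nx = pytest.importorskip("networkx")
        for seed in range(3):
            dim = 2 if seed % 2 else 3
            lo, hi = (-2, 2) if dim == 2 else (-1, 1)
            table = random_lattice_table(dim, lo, hi, seed)
            instance, sur, pred, grid = make_scene(dim, lo, hi, table=table)
            res = ap.plan_path(instance, sur, pred, grid, L=10_000)

            g = nx.DiGraph()
            for u in table:
                for v in ap.neighbors(u, grid):
                    g.add_edge(u, v, weight=-table[v])
            start = (0,) * dim
            lengths = nx.single_source_dijkstra_path_length(g, start)
            for node, cost in res.best_cost.items():
                want = -table[start] + (0.0 if node == start else lengths[node])
                assert cost == pytest.approx(want, abs=1e-9)

    def test_finalization_costs_are_monotone(self):
        table = random_lattice_table(2, -3, 3, seed=5)
        instance, sur, pred, grid = make_scene(2, -3, 3, table=table)
        res = ap.plan_path(instance, sur, pred, grid, L=10_000)
        # best_cost preserves finalization (insertion) order
        costs = list(res.best_cost.values())
        assert costs[0] == pytest.approx(-table[(0, 0)])
        assert all(a <= b + 1e-12 for a, b in zip(costs, costs[1:]))

    def test_returned_path_cost_recomputes_identically(self):
        table = random_lattice_table(2, -3, 3, seed=6)
        instance, sur, pred, grid = make_scene(2, -3, 3, table=table)
        res = ap.plan_path(instance, sur, pred, grid, L=10_000)
        independent = -sum(table[n.offsets] for n in res.path.nodes)
        assert res.path.cost == pytest.approx(independent, abs=1e-9)
        assert res.path.log_actionability == pytest.approx(-independent, abs=1e-9)

    def test_larger_cap_never_worsens_destination(self):
        table = random_lattice_table(3, -2, 2, seed=7)
        instance, sur, pred, grid = make_scene(3, -2, 2, table=table)
        prev = np.inf
        for L in (5, 20, 60, 1000):
            res = ap.plan_path(instance, sur, pred, grid, L=L)
            assert res.destination.prediction <= prev + 1e-12
            prev = res.destination.prediction

    def test_fifo_expansion_mode_runs(self):
        table = random_lattice_table(2, -2, 2, seed=8)
        instance, sur, pred, grid = make_scene(2, -2, 2, table=table)
        res = ap.plan_path(instance, sur, pred, grid, L=10_000, expansion="fifo")
        assert res.destination.offsets in res.best_cost

    def test_plan_result_json_round_trip(self, tmp_path):
        instance, sur, pred, grid = make_scene(2, -2, 2)
        res = ap.plan_path(instance, sur, pred, grid, L=100)
        res.to_json(tmp_path / "plan.json")
        import json

        payload = json.loads((tmp_path / "plan.json").read_text())
        assert payload["cost"] == pytest.approx(res.path.cost)
        assert len(payload["path"]) == len(res.path)


class TestRealizePath:
    def test_empty_path_single_row(self):
        instance, sur, pred, grid = make_scene(2, -2, 2, coefs={"x1": 0.0})
        res = ap.plan_path(instance, sur, pred, grid, L=100)
        report = ap.realize_path(res.path)
        assert len(report) == 1

    def test_steps_change_one_variable_each(self):
        instance, sur, pred, grid = make_scene(2, -3, 3)
        res = ap.plan_path(instance, sur, pred, grid, L=10_000)
        report = ap.realize_path(res.path)
        assert len(report) == len(res.path)
        assert (report.loc[1:, "variable"] != "").all()
        assert set(report.loc[1:, "direction"]) <= {"increase", "decrease"}

    def test_destandardized_values_round_trip(self):
        instance, sur, pred, grid = make_scene(1, -2, 0)
        res = ap.plan_path(instance, sur, pred, grid, L=100)
        stats = ap.Standardization(mean={"x1": 10.0}, std={"x1": 2.0})
        report = ap.realize_path(res.path, stats)
        for i, node in enumerate(res.path.nodes):
            if i == 0:
                continue
            assert report.loc[i, "new_value"] == pytest.approx(
                node.x["x1"] * 2.0 + 10.0
            )

    def test_path_rejects_non_adjacent_nodes(self):
        instance, sur, pred, grid = make_scene(2, -1, 1)
        ev = ap.NodeEvaluator(instance, sur, pred, grid)
        a, b = ev.get((0, 0)), ev.get((1, 1))
        with pytest.raises(ValueError, match="adjacent"):
            ap.PlanPath([a, b])


def test_heatmap_rendering_writes_image(tmp_path, bench_prepared):
    pytest.importorskip("matplotlib")
    from actipath.viz import plot_path_heatmap

    instance, sur, pred, grid = make_scene(2, -2, 2)
    res = ap.plan_path(instance, sur, pred, grid, L=100)
    schema = lattice_schema(2)
    import pandas as pd

    rng = np.random.default_rng(0)
    frame = pd.DataFrame(
        {"x1": rng.normal(size=50), "x2": rng.normal(size=50),
         "y": rng.normal(size=50)}
    )
    data = ap.Dataset(frame, schema)
    out = tmp_path / "path.png"
    plot_path_heatmap(res, data, "x1", "x2", out)
    assert out.stat().st_size > 0
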