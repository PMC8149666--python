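"""Actionability scoring and the comparator paths used for assessment.

The actionability score asks how much more probable the planned path is
than a naive one with the same endpoints: optimal log-actionability
minus the log of the geometric-mean actionability of random
Manhattan-shortest baseline paths. Random guideline-direction paths with
matched step counts reproduce the comparator used when clinicians judge
planned paths, and Welch's t-test compares predicted-response changes
between two groups of paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .pathplan import GridSpec, Node, NodeEvaluator, Offsets, PlanPath
from .schema import VariableSchema


def random_shortest_paths(
    start: Node,
    end: Node,
    n: int,
    seed: int,
    evaluator: NodeEvaluator,
) -> list[PlanPath]:
    """Uniformly random Manhattan-shortest paths between two grid nodes.

    Each path is a random interleaving of exactly the per-variable unit
    moves required to reach ``end`` (monotone in every variable), sampled
    by shuffling the move multiset; node probabilities come from the
    surrogate via ``evaluator``.
    """
    rng = np.random.default_rng(seed)
    delta = [e - s for s, e in zip(start.offsets, end.offsets)]
    moves: list[tuple[int, int]] = []
    for i, d in enumerate(delta):
        moves.extend([(i, 1 if d > 0 else -1)] * abs(d))
    paths = []
    for _ in range(n):
        order = list(moves)
        rng.shuffle(order)
        offsets = [start.offsets]
        for var, sign in order:
            cur = list(offsets[-1])
            cur[var] += sign
            offsets.append(tuple(cur))
        nodes = evaluator.get_many(offsets)
        paths.append(PlanPath(list(nodes)))
    return paths


@dataclass
class ActionabilityScore:
    """Optimal-vs-baseline log-actionability decomposition.

    ``score = optimal_log_actionability - baseline_log_actionability``
    where the baseline term is the log geometric mean over sampled
    shortest paths. ``infinite_baseline`` flags a baseline node with zero
    probability (score reported as +inf, not an error).
    """

    optimal_log_actionability: float
    baseline_log_actionability: float
    score: float
    n_baseline: int
    seed: int
    infinite_baseline: bool = False


def actionability_score(
    optimal: PlanPath,
    evaluator: NodeEvaluator,
    n_baseline: int = 10,
    seed: int = 0,
) -> ActionabilityScore:
    """Score the planned path against random shortest baselines.

    Baselines share the optimal path's endpoints; when the optimal path
    is longer than the Manhattan distance the baselines simply have fewer
    nodes and are scored exactly as defined (product over their own
    nodes, no per-node normalization).
    """
    start, end = optimal.nodes[0], optimal.nodes[-1]
    baselines = random_shortest_paths(start, end, n_baseline, seed, evaluator)
    log_a_opt = optimal.log_actionability
    base_logs = np.array([p.log_actionability for p in baselines])
    baseline_log = float(np.mean(base_logs))
    infinite = bool(np.isneginf(base_logs).any())
    score = math.inf if infinite else log_a_opt - baseline_log
    return ActionabilityScore(
        optimal_log_actionability=float(log_a_opt),
        baseline_log_actionability=baseline_log,
        score=float(score),
        n_baseline=n_baseline,
        seed=seed,
        infinite_baseline=infinite,
    )


def random_intervention_paths(
    instance: Mapping[str, object],
    grid: GridSpec,
    schema: VariableSchema,
    n_steps: int,
    n_paths: int = 9,
    seed: int = 0,
    evaluator: Optional[NodeEvaluator] = None,
) -> list[PlanPath]:
    """Random guideline-direction comparator paths with matched step counts.

    Each path takes exactly ``n_steps`` unit moves; at every step the
    intervened variable is chosen uniformly at random and moved one cell
    in its declared direction (``increase``/``decrease`` in the schema).
    A variable already at its bound is resampled; if every variable is
    stuck the path cannot be built and an error is raised.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    dirs = []
    for name in grid.names:
        d = schema[name].direction
        if d not in ("increase", "decrease"):
            raise ValueError(
                f"variable {name!r} needs a declared direction (increase/decrease)"
            )
        dirs.append(1 if d == "increase" else -1)
    rng = np.random.default_rng(seed)
    if evaluator is None:
        raise ValueError("an evaluator is required to attach predictions")
    paths = []
    for _ in range(n_paths):
        offsets = [(0,) * grid.dim]
        for _ in range(n_steps):
            movable = [
                i
                for i in range(grid.dim)
                if grid.in_bounds(
                    tuple(
                        o + (dirs[i] if j == i else 0)
                        for j, o in enumerate(offsets[-1])
                    )
                )
            ]
            if not movable:
                raise ValueError(
                    "all intervention variables are at their bound in the declared direction"
                )
            i = int(rng.choice(movable))
            cur = list(offsets[-1])
            cur[i] += dirs[i]
            offsets.append(tuple(cur))
        nodes = evaluator.get_many(offsets)
        paths.append(PlanPath(list(nodes)))
    return paths


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-tailed Welch's t-test (unequal variances).

    Returns the statistic, the Welch–Satterthwaite degrees of freedom
    and the two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) <= 0 and b.var(ddof=1) <= 0:
        if np.allclose(a.mean(), b.mean()):
            return {"statistic": 0.0, "df": float(len(a) + len(b) - 2), "p_value": 1.0}
        raise ValueError("degenerate variance in both groups")
    res = _stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (
        va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
    )
    return {
        "statistic": float(res.statistic),
        "df": float(df),
        "p_value": float(res.pvalue),
    }
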