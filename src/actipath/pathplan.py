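"""Step 3 — grid discretization and the capped-iteration optimal-path search.

The intervention variables span a lattice around one instance: unit cell
0.2 standard deviations per variable, non-intervention variables frozen
at the instance's values. Each node's probability comes from the
surrogate, its predicted response from the prediction model. Path cost
is the negative log of actionability (the product of nodal
probabilities), so the min-cost-frontier search below — uniform-cost
(Dijkstra) finalization, capped at L node finalizations — returns the
most actionable path to every node it finalizes. The destination is the
finalized node with the best predicted response; ties go to the cheaper
path, then to the lexicographically smallest offset.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset, Standardization
from .predictor import PredictionModel
from .preprocess import destandardize_value
from .schema import VariableSchema
from .surrogate import SurrogateModel

Offsets = tuple[int, ...]


@dataclass(frozen=True)
class GridSpec:
    """Lattice over the intervention variables around one instance.

    Steps and bounds are expressed in the planner's working units (the
    standardized scale on which the surrogate and predictor were fitted);
    0.2 there corresponds to 0.2 sigma in original units. Bounds are
    inclusive integer offsets with ``lower <= 0 <= upper``.
    """

    names: tuple[str, ...]
    steps: tuple[float, ...]
    lower: tuple[int, ...]
    upper: tuple[int, ...]
    origin: tuple[float, ...]

    def __post_init__(self):
        k = len(self.names)
        if not (len(self.steps) == len(self.lower) == len(self.upper) == len(self.origin) == k):
            raise ValueError("grid field lengths disagree")
        if any(s <= 0 for s in self.steps):
            raise ValueError("grid steps must be positive")
        if any(l > 0 or u < 0 for l, u in zip(self.lower, self.upper)):
            raise ValueError("bounds must include offset 0")

    @property
    def dim(self) -> int:
        return len(self.names)

    def in_bounds(self, offsets: Offsets) -> bool:
        return all(
            l <= o <= u for o, l, u in zip(offsets, self.lower, self.upper)
        )

    def realize(self, offsets: Offsets) -> dict[str, float]:
        return {
            n: o0 + o * s
            for n, o0, o, s in zip(self.names, self.origin, offsets, self.steps)
        }

    @classmethod
    def around_instance(
        cls,
        instance: Mapping[str, object],
        schema: VariableSchema,
        train: Optional[Dataset] = None,
        step: float = 0.2,
        max_abs: float = 4.0,
        names: Optional[Sequence[str]] = None,
    ) -> "GridSpec":
        """Grid centred on ``instance`` over its intervenable variables.

        Bounds default to the training data's observed min/max per
        variable (the surrogate is untrustworthy under extrapolation),
        clamped to ``max_abs`` working units from the origin.
        """
        names = tuple(names if names is not None else schema.intervenable_names)
        if not names:
            raise ValueError("no intervention variables declared")
        for n in names:
            var = schema[n]
            if not (var.intervenable and var.kind == "continuous"):
                raise ValueError(f"{n!r} is not a continuous intervenable variable")
        origin = []
        for n in names:
            v = instance[n]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(f"instance has a missing value for {n!r}")
            origin.append(float(v))
        lower, upper = [], []
        for n, o in zip(names, origin):
            lo_val, hi_val = o - max_abs, o + max_abs
            if train is not None:
                col = train.values[n].dropna()
                lo_val = max(lo_val, float(col.min()))
                hi_val = min(hi_val, float(col.max()))
            lower.append(min(0, int(np.floor((lo_val - o) / step))))
            upper.append(max(0, int(np.ceil((hi_val - o) / step))))
        return cls(
            names=names,
            steps=(step,) * len(names),
            lower=tuple(lower),
            upper=tuple(upper),
            origin=tuple(origin),
        )


@dataclass(frozen=True)
class Node:
    """One grid point: offsets, realized full state, density and prediction."""

    offsets: Offsets
    x: dict[str, object]
    log_prob: float
    prediction: float


@dataclass
class PlanPath:
    """Ordered node sequence starting at offset 0.

    ``cost`` is the sum of −log node probabilities over *all* nodes on
    the path (start included), so ``actionability = exp(-cost)`` is the
    product of nodal probabilities.
    """

    nodes: list[Node]

    def __post_init__(self):
        for a, b in zip(self.nodes, self.nodes[1:]):
            diff = [abs(x - y) for x, y in zip(a.offsets, b.offsets)]
            if sum(diff) != 1:
                raise ValueError(
                    f"consecutive nodes {a.offsets} -> {b.offsets} are not lattice-adjacent"
                )

    @property
    def cost(self) -> float:
        return float(sum(-n.log_prob for n in self.nodes))

    @property
    def log_actionability(self) -> float:
        return -self.cost

    @property
    def actionability(self) -> float:
        return math.exp(-self.cost)

    @property
    def response_trajectory(self) -> list[float]:
        return [n.prediction for n in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class PlanResult:
    path: PlanPath
    destination: Node
    n_expanded: int
    best_cost: dict[Offsets, float]
    termination: Literal["L exhausted", "frontier empty"]
    objective: str
    grid: GridSpec
    nodes: dict[Offsets, Node] = field(default_factory=dict, repr=False)

    def to_json(self, path: str | FsPath) -> None:
        payload = {
            "objective": self.objective,
            "termination": self.termination,
            "n_expanded": self.n_expanded,
            "grid": {
                "names": list(self.grid.names),
                "steps": list(self.grid.steps),
                "lower": list(self.grid.lower),
                "upper": list(self.grid.upper),
                "origin": list(self.grid.origin),
            },
            "path": [
                {
                    "offsets": list(n.offsets),
                    "x": {k: v for k, v in n.x.items()},
                    "log_prob": n.log_prob,
                    "prediction": n.prediction,
                }
                for n in self.path.nodes
            ],
            "cost": self.path.cost,
            "log_actionability": self.path.log_actionability,
        }
        FsPath(path).write_text(json.dumps(payload, indent=2, default=float))


def neighbors(offsets: Offsets, grid: GridSpec) -> list[Offsets]:
    """In-bounds lattice neighbours: ±1 in exactly one coordinate."""
    out = []
    for i in range(grid.dim):
        for delta in (-1, 1):
            cand = list(offsets)
            cand[i] += delta
            cand = tuple(cand)
            if grid.in_bounds(cand):
                out.append(cand)
    return out


class NodeEvaluator:
    """Lazy, memoized node evaluation (the planning-time hotspot).

    Realizes each offset vector once, batches the prediction-model and
    surrogate calls over a list of offsets, and caches per offset.
    """

    def __init__(
        self,
        instance: Mapping[str, object],
        surrogate: SurrogateModel,
        predictor: PredictionModel,
        grid: GridSpec,
        include_response: bool = True,
        response_mode: Literal["label", "probability"] = "label",
    ):
        self.instance = dict(instance)
        self.surrogate = surrogate
        self.predictor = predictor
        self.grid = grid
        self.include_response = include_response
        self.response_mode = response_mode
        self.schema = surrogate.schema
        self.cache: dict[Offsets, Node] = {}
        resp = self.schema.response.name
        self._base = {
            v.name: self.instance.get(v.name) for v in self.schema.explanatory
        }
        self._resp_name = resp

    def realize(self, offsets: Offsets) -> dict[str, object]:
        x = dict(self._base)
        x.update(self.grid.realize(offsets))
        return x

    def get_many(self, offsets_list: Sequence[Offsets]) -> list[Node]:
        todo = [o for o in offsets_list if o not in self.cache]
        if todo:
            rows = [self.realize(o) for o in todo]
            frame = pd.DataFrame(rows)
            frame[self._resp_name] = np.nan
            frame = frame[self.schema.names]
            preds = self.predictor.predict_frame(frame)
            xc = np.asarray(
                [
                    [float(r[v.name]) for v in self.schema.continuous_explanatory]
                    for r in rows
                ]
            )
            codes = [
                [v.categories.index(r[v.name]) for r in rows]
                for v in self.schema.discrete_explanatory
            ]
            if self.surrogate.task == "classification" and self.response_mode == "label":
                y_dens = (preds >= 0.5).astype(float)
            else:
                y_dens = preds
            logp = self.surrogate.log_state_probability_batch(
                xc, codes, y_dens, include_response=self.include_response
            )
            for o, r, p, lp in zip(todo, rows, preds, logp):
                self.cache[o] = Node(
                    offsets=o, x=r, log_prob=float(lp), prediction=float(p)
                )
        return [self.cache[o] for o in offsets_list]

    def get(self, offsets: Offsets) -> Node:
        return self.get_many([offsets])[0]


def plan_path(
    instance: Mapping[str, object],
    surrogate: SurrogateModel,
    predictor: PredictionModel,
    grid: GridSpec,
    objective: Literal["minimize", "maximize"] = "minimize",
    L: int = 20000,
    include_response: bool = True,
    expansion: Literal["min-cost", "fifo"] = "min-cost",
    evaluator: Optional[NodeEvaluator] = None,
) -> PlanResult:
    """Capped optimal-path search over the intervention grid.

    Uniform-cost finalization: repeatedly finalize the cheapest reached
    node and relax its neighbours with ``cost(child) = cost(parent) −
    log p(child)``; stop after ``L`` finalizations or when the frontier
    empties. The start node's own −log p is part of every cost, so
    exp(−cost) is a true product of nodal probabilities. A FIFO expansion
    order is available for fidelity experiments; min-cost is the default
    because it makes per-node paths provably optimal.
    """
    if objective not in ("minimize", "maximize"):
        raise ValueError("objective must be 'minimize' or 'maximize'")
    ev = evaluator or NodeEvaluator(
        instance, surrogate, predictor, grid, include_response=include_response
    )
    start: Offsets = (0,) * grid.dim
    start_node = ev.get(start)
    if not math.isfinite(start_node.log_prob):
        raise ValueError("start node has probability 0 (-log p not finite)")

    best: dict[Offsets, float] = {start: -start_node.log_prob}
    parent: dict[Offsets, Optional[Offsets]] = {start: None}
    finalized: dict[Offsets, float] = {}
    counter = 0
    heap: list[tuple[float, int, Offsets]] = [(best[start], counter, start)]

    n_expanded = 0
    termination: Literal["L exhausted", "frontier empty"] = "frontier empty"
    while heap:
        if n_expanded >= L:
            termination = "L exhausted"
            break
        if expansion == "min-cost":
            cost, _, off = heapq.heappop(heap)
            if off in finalized or cost > best.get(off, math.inf):
                continue
        else:  # FIFO expansion order (fidelity experiments)
            _, _, off = heap.pop(0)
            if off in finalized:
                continue
            cost = best[off]
        finalized[off] = cost
        n_expanded += 1
        nbrs = neighbors(off, grid)
        nodes = ev.get_many([o for o in nbrs if o not in finalized])
        for child in nodes:
            step_cost = -child.log_prob
            new_cost = cost + step_cost
            if new_cost < best.get(child.offsets, math.inf):
                best[child.offsets] = new_cost
                parent[child.offsets] = off
                counter += 1
                entry = (new_cost, counter, child.offsets)
                if expansion == "min-cost":
                    heapq.heappush(heap, entry)
                else:
                    heap.append(entry)

    # destination: best predicted response among finalized nodes
    sign = 1.0 if objective == "minimize" else -1.0
    dest = min(
        finalized,
        key=lambda o: (sign * ev.cache[o].prediction, finalized[o], o),
    )
    chain: list[Offsets] = []
    cur: Optional[Offsets] = dest
    while cur is not None:
        chain.append(cur)
        cur = parent[cur]
    chain.reverse()
    path = PlanPath([ev.cache[o] for o in chain])
    return PlanResult(
        path=path,
        destination=ev.cache[dest],
        n_expanded=n_expanded,
        best_cost=finalized,
        termination=termination,
        objective=objective,
        grid=grid,
        nodes=ev.cache,
    )


def realize_path(
    path: PlanPath, standardization: Optional[Standardization] = None
) -> pd.DataFrame:
    """Stepwise report in original (de-standardized) units.

    One row per node: the variable changed, the direction of the unit
    step, the new value, and the new predicted response — the textual
    equivalent of a step plot.
    """
    rows = []
    for i, node in enumerate(path.nodes):
        if i == 0:
            changed, direction, new_value = "", "", float("nan")
        else:
            prev = path.nodes[i - 1]
            changed = next(
                k
                for k in node.x
                if isinstance(node.x[k], float)
                and isinstance(prev.x[k], float)
                and node.x[k] != prev.x[k]
            )
            delta = float(node.x[changed]) - float(prev.x[changed])
            direction = "increase" if delta > 0 else "decrease"
            new_value = float(node.x[changed])
            if standardization is not None:
                new_value = destandardize_value(changed, new_value, standardization)
        rows.append(
            {
                "step": i,
                "variable": changed,
                "direction": direction,
                "new_value": new_value,
                "prediction": node.prediction,
                "log_prob": node.log_prob,
            }
        )
    return pd.DataFrame(rows)
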