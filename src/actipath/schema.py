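"""Variable schema: names, kinds, roles and intervention constraints.

A :class:`VariableSchema` declares, for every column of a tabular health
dataset, whether it is continuous or discrete, whether it is an explanatory
variable or the response, and — for explanatory variables — whether it may
be intervened on and in which direction (e.g. "blood glucose: decrease").
The schema is the single source of truth consumed by every downstream
stage: preprocessing, prediction, the Bayesian surrogate and the planner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml

Kind = Literal["continuous", "discrete"]
Role = Literal["explanatory", "response"]
Direction = Literal["increase", "decrease", "free"]


@dataclass(frozen=True)
class Variable:
    """One column declaration.

    Parameters
    ----------
    name:
        Column name, unique within a schema.
    kind:
        ``"continuous"`` or ``"discrete"``.
    role:
        ``"explanatory"`` or ``"response"``; exactly one response per schema.
    intervenable:
        Whether the planner may change this variable. Only continuous
        explanatory variables may be intervenable.
    direction:
        Clinically sensible direction of intervention: ``"increase"``,
        ``"decrease"`` or ``"free"`` (either way).
    categories:
        Ordered category labels; required (>= 2) for discrete variables.
    """

    name: str
    kind: Kind = "continuous"
    role: Role = "explanatory"
    intervenable: bool = False
    direction: Direction = "free"
    categories: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.role not in ("explanatory", "response"):
            raise ValueError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.direction not in ("increase", "decrease", "free"):
            raise ValueError(
                f"variable {self.name!r}: unknown direction {self.direction!r}"
            )
        if self.kind == "discrete" and len(self.categories) < 2:
            raise ValueError(
                f"discrete variable {self.name!r} must list >= 2 categories"
            )
        if self.kind == "continuous" and self.categories:
            raise ValueError(
                f"continuous variable {self.name!r} must not list categories"
            )
        if self.intervenable:
            if self.role != "explanatory":
                raise ValueError(
                    f"intervenable variable {self.name!r} must be explanatory"
                )
            if self.kind != "continuous":
                raise ValueError(
                    f"intervenable variable {self.name!r} must be continuous"
                )
        object.__setattr__(self, "categories", tuple(self.categories))


class VariableSchema:
    """Ordered collection of :class:`Variable` records.

    Invariants enforced on construction: unique names, exactly one
    response variable, and the per-variable constraints of
    :class:`Variable`.
    """

    def __init__(self, variables: Iterable[Variable]):
        self.variables: tuple[Variable, ...] = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        responses = [v for v in self.variables if v.role == "response"]
        if len(responses) != 1:
            raise ValueError(
                f"schema must declare exactly one response variable, got {len(responses)}"
            )
        self._by_name = {v.name: v for v in self.variables}

    # ------------------------------------------------------------------ views
    def __getitem__(self, name: str) -> Variable:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __eq__(self, other) -> bool:
        return isinstance(other, VariableSchema) and self.variables == other.variables

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def response(self) -> Variable:
        return next(v for v in self.variables if v.role == "response")

    @property
    def explanatory(self) -> list[Variable]:
        return [v for v in self.variables if v.role == "explanatory"]

    @property
    def continuous_explanatory(self) -> list[Variable]:
        return [v for v in self.explanatory if v.kind == "continuous"]

    @property
    def discrete_explanatory(self) -> list[Variable]:
        return [v for v in self.explanatory if v.kind == "discrete"]

    @property
    def continuous_names(self) -> list[str]:
        """All continuous columns, response included (used by standardization
        statistics; the response itself is never standardized)."""
        return [v.name for v in self.variables if v.kind == "continuous"]

    @property
    def intervenable_names(self) -> list[str]:
        return [v.name for v in self.explanatory if v.intervenable]

    def fingerprint(self) -> str:
        """Stable short digest identifying the schema a model was fitted on."""
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # ------------------------------------------------------- (de)serialization
    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    "role": v.role,
                    "intervenable": v.intervenable,
                    "direction": v.direction,
                    **({"categories": list(v.categories)} if v.categories else {}),
                }
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "VariableSchema":
        records: Sequence[dict] = payload["variables"]
        return cls(
            Variable(
                name=r["name"],
                kind=r.get("kind", "continuous"),
                role=r.get("role", "explanatory"),
                intervenable=bool(r.get("intervenable", False)),
                direction=r.get("direction", "free"),
                categories=tuple(r.get("categories", ())),
            )
            for r in records
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "VariableSchema":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(payload)
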