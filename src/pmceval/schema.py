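"""Evaluation framework: primary variables and their binary sub-variables.

A PMC evaluation framework is a two-level tree: primary variables (the
evaluation dimensions, conventionally ``X1``..``Xn``) each own an ordered
list of binary sub-variables (``Xi_j``).  Each sub-variable is a yes/no
criterion applied to a policy document; the framework carries the
criterion text alongside the ids so coded matrices stay interpretable.

The framework is data, not code: it is loaded from a YAML file, and the
default instance shipped with the package is the nine-dimension,
41-criterion framework used for Chinese medicine new-drug registration
policies (per-dimension sub-variable counts 6, 3, 4, 4, 6, 6, 3, 4, 5).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml

__all__ = [
    "SchemaError",
    "SubVariable",
    "PrimaryVariable",
    "EvaluationSchema",
    "load_schema",
    "write_schema",
    "default_schema",
]


class SchemaError(ValueError):
    """Raised when an evaluation framework is malformed."""


@dataclass(frozen=True)
class SubVariable:
    """One binary evaluation criterion (``Xi_j``)."""

    id: str
    label: str = ""
    criterion: str = ""

    def __post_init__(self) -> None:
        if not self.id or not str(self.id).strip():
            raise SchemaError("sub-variable id must be non-empty")


@dataclass(frozen=True)
class PrimaryVariable:
    """One evaluation dimension (``Xi``) with its sub-variables.

    The number of sub-variables ``T`` is the divisor used when averaging
    binary flags into the dimension's first-level value.
    """

    id: str
    label: str = ""
    subvariables: tuple[SubVariable, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subvariables", tuple(self.subvariables))
        if not self.id or not str(self.id).strip():
            raise SchemaError("primary variable id must be non-empty")
        if len(self.subvariables) == 0:
            raise SchemaError(f"primary variable {self.id!r} has no sub-variables")

    @property
    def n_subvariables(self) -> int:
        return len(self.subvariables)

    @property
    def subvariable_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.subvariables)


@dataclass(frozen=True)
class EvaluationSchema:
    """A validated two-level evaluation framework."""

    name: str
    primaries: tuple[PrimaryVariable, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "primaries", tuple(self.primaries))
        if len(self.primaries) == 0:
            raise SchemaError("schema has no primary variables")
        seen: set[str] = set()
        for p in self.primaries:
            if p.id in seen:
                raise SchemaError(f"duplicate primary variable id {p.id!r}")
            seen.add(p.id)
            for s in p.subvariables:
                if s.id in seen:
                    raise SchemaError(f"duplicate id {s.id!r}")
                seen.add(s.id)

    @property
    def n_primaries(self) -> int:
        return len(self.primaries)

    @property
    def total_subvariables(self) -> int:
        return sum(p.n_subvariables for p in self.primaries)

    @property
    def primary_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.primaries)

    @property
    def subvariable_ids(self) -> tuple[str, ...]:
        return tuple(s.id for p in self.primaries for s in p.subvariables)

    @property
    def max_pmc(self) -> int:
        """Maximum attainable PMC index: one point per primary variable."""
        return self.n_primaries

    def primary(self, primary_id: str) -> PrimaryVariable:
        for p in self.primaries:
            if p.id == primary_id:
                return p
        raise KeyError(primary_id)

    def parent_of(self, subvariable_id: str) -> PrimaryVariable:
        for p in self.primaries:
            if subvariable_id in p.subvariable_ids:
                return p
        raise KeyError(subvariable_id)


Source = Union[str, Path, io.TextIOBase]


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if isinstance(source, str) and "\n" in text:
        return text  # inline YAML
    path = Path(source)
    if path.exists():
        return path.read_text(encoding="utf-8")
    if ":" in text:
        return text  # single-line inline YAML
    raise FileNotFoundError(source)


def load_schema(source: Source) -> EvaluationSchema:
    """Load and validate an evaluation framework from YAML.

    ``source`` may be a path, an open text stream, or an inline YAML
    string.  Ordering of primaries and sub-variables is preserved exactly
    as written.  Duplicate ids and empty primaries raise
    :class:`SchemaError` naming the offender.
    """
    data = yaml.safe_load(_read_text(source))
    if not isinstance(data, dict) or "primaries" not in data:
        raise SchemaError("schema config must be a mapping with a 'primaries' list")
    primaries = []
    for p in data["primaries"]:
        subs = [
            SubVariable(
                id=str(s["id"]),
                label=str(s.get("label", "")),
                criterion=str(s.get("criterion", "")),
            )
            for s in (p.get("subvariables") or [])
        ]
        if not subs:
            raise SchemaError(f"primary variable {p.get('id')!r} has no sub-variables")
        primaries.append(
            PrimaryVariable(id=str(p["id"]), label=str(p.get("label", "")), subvariables=subs)
        )
    return EvaluationSchema(name=str(data.get("name", "")), primaries=tuple(primaries))


def write_schema(schema: EvaluationSchema, destination: Union[str, Path, io.TextIOBase]) -> None:
    """Serialise a schema back to YAML, preserving order."""
    data = {
        "name": schema.name,
        "primaries": [
            {
                "id": p.id,
                "label": p.label,
                "subvariables": [
                    {"id": s.id, "label": s.label, "criterion": s.criterion}
                    for s in p.subvariables
                ],
            }
            for p in schema.primaries
        ],
    }
    text = yaml.safe_dump(data, sort_keys=False, allow_unicode=True)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text, encoding="utf-8")


@lru_cache(maxsize=1)
def default_schema() -> EvaluationSchema:
    """The packaged nine-primary / 41-sub-variable framework."""
    ref = resources.files("pmceval.data").joinpath("default_schema.yml")
    return load_schema(io.StringIO(ref.read_text(encoding="utf-8")))
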