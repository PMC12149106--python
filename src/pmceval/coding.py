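"""The multi-input-output table: policies x sub-variables binary coding.

Every policy is coded against every sub-variable of the framework with a
0/1 flag (1 when the policy text satisfies the criterion).  The complete
matrix is the sole input to PMC scoring, so the reader here is strict:
cells must be exactly 0 or 1, no cell may be missing, and the column set
must match the framework.

Coding in the original studies is manual.  For reproducible pipelines
this module also offers a transparent keyword-rule coder
(:func:`apply_rules`): each rule maps literal keyword patterns onto one
sub-variable, and a cell becomes 1 iff the rule matches the document.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .schema import EvaluationSchema

__all__ = [
    "CodingError",
    "SchemaMismatchError",
    "PolicyRecord",
    "CodingRule",
    "CodingMatrix",
    "read_coding_matrix",
    "write_coding_matrix",
    "apply_rules",
    "column_means",
    "lint_exclusive_blocks",
]

_META_COLUMNS = ("policy_id", "title", "issuer", "year")


class CodingError(ValueError):
    """Raised when a coding matrix violates the binary-completeness contract."""


class SchemaMismatchError(CodingError):
    """Raised when a matrix's columns do not match the framework."""


@dataclass(frozen=True)
class PolicyRecord:
    """Identifying metadata for one policy document."""

    policy_id: str
    title: str = ""
    issuer: str = ""
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.policy_id:
            raise CodingError("policy_id must be non-empty")
        if self.year is not None and not (1900 <= int(self.year) <= 2100):
            raise CodingError(
                f"policy {self.policy_id!r}: year {self.year} outside 1900-2100"
            )


@dataclass(frozen=True)
class CodingRule:
    """Keyword rule for one sub-variable.

    ``mode='any'`` sets the flag when any pattern occurs in the document;
    ``mode='all'`` requires every pattern.  Matching is plain substring
    containment after whitespace stripping; Latin text is case-folded,
    Chinese text is matched verbatim.
    """

    subvariable_id: str
    patterns: tuple[str, ...]
    mode: str = "any"

    def __post_init__(self) -> None:
        object.__setattr__(self, "patterns", tuple(self.patterns))
        if not self.patterns:
            raise CodingError(f"rule for {self.subvariable_id!r} has no patterns")
        if self.mode not in ("any", "all"):
            raise CodingError(f"rule mode must be 'any' or 'all', got {self.mode!r}")

    def matches(self, text: str) -> bool:
        norm = _normalize(text)
        hits = (_normalize(p) in norm for p in self.patterns)
        return any(hits) if self.mode == "any" else all(hits)


def _normalize(text: str) -> str:
    text = unicodedata.normalize("NFKC", text)
    return "".join(text.split()).casefold()


class CodingMatrix:
    """A complete, validated policies x sub-variables binary table.

    ``values`` is a pandas DataFrame indexed by policy_id with one int
    column per sub-variable, in framework order.
    """

    def __init__(
        self,
        policies: Sequence[PolicyRecord],
        schema: EvaluationSchema,
        values: pd.DataFrame,
    ):
        self.policies = tuple(policies)
        self.schema = schema
        ids = [p.policy_id for p in self.policies]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise CodingError(f"duplicate policy_id {dup!r}")
        expected = list(schema.subvariable_ids)
        missing = [c for c in expected if c not in values.columns]
        if missing:
            raise SchemaMismatchError(f"missing sub-variable column(s): {missing}")
        extra = [c for c in values.columns if c not in expected]
        if extra:
            raise SchemaMismatchError(f"unknown sub-variable column(s): {extra}")
        values = values.loc[ids, expected]
        if values.isna().any().any():
            r, c = next(zip(*np.nonzero(values.isna().to_numpy())))
            raise CodingError(
                f"missing cell at policy {ids[r]!r}, column {expected[c]!r}"
            )
        arr = values.to_numpy()
        ok = (arr == 0) | (arr == 1)
        if not ok.all():
            r, c = next(zip(*np.nonzero(~ok)))
            raise CodingError(
                f"cell at policy {ids[r]!r}, column {expected[c]!r} is "
                f"{arr[r, c]!r}; cells must be exactly 0 or 1"
            )
        self.values = values.astype(np.int8)

    # -- basic container protocol -------------------------------------
    @property
    def policy_ids(self) -> tuple[str, ...]:
        return tuple(p.policy_id for p in self.policies)

    @property
    def n_policies(self) -> int:
        return len(self.policies)

    def __len__(self) -> int:
        return self.n_policies

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CodingMatrix)
            and self.policies == other.policies
            and self.values.equals(other.values)
        )

    def row(self, policy_id: str) -> pd.Series:
        return self.values.loc[policy_id]

    def to_frame(self) -> pd.DataFrame:
        """Full table including policy metadata columns."""
        meta = pd.DataFrame(
            {
                "policy_id": [p.policy_id for p in self.policies],
                "title": [p.title for p in self.policies],
                "issuer": [p.issuer for p in self.policies],
                "year": [p.year if p.year is not None else "" for p in self.policies],
            }
        ).set_index("policy_id")
        return meta.join(self.values)


def read_coding_matrix(path: Union[str, Path], schema: EvaluationSchema) -> CodingMatrix:
    """Read a coding matrix from CSV and validate it against ``schema``.

    Expected layout: UTF-8, header row; columns ``policy_id``, optional
    ``title``/``issuer``/``year``, then one 0/1 column per sub-variable
    named by its id.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if "policy_id" not in df.columns:
        raise CodingError("first column must be 'policy_id'")
    policies = []
    for _, r in df.iterrows():
        year = r.get("year", "")
        policies.append(
            PolicyRecord(
                policy_id=r["policy_id"],
                title=r.get("title", ""),
                issuer=r.get("issuer", ""),
                year=int(year) if str(year).strip() else None,
            )
        )
    sub_cols = [c for c in df.columns if c not in _META_COLUMNS]
    vals = df[sub_cols].copy()
    for c in sub_cols:
        col = vals[c].str.strip()
        bad = ~col.isin(["0", "1"])
        if bad.any():
            i = int(np.nonzero(bad.to_numpy())[0][0])
            raise CodingError(
                f"cell at policy {df['policy_id'].iloc[i]!r}, column {c!r} is "
                f"{col.iloc[i]!r}; cells must be exactly 0 or 1"
            )
        vals[c] = col.astype(np.int8)
    vals.index = df["policy_id"]
    return CodingMatrix(policies, schema, vals)


def write_coding_matrix(matrix: CodingMatrix, path: Union[str, Path]) -> None:
    matrix.to_frame().to_csv(path, encoding="utf-8")


def apply_rules(
    texts: Mapping[str, str],
    rules: Iterable[CodingRule],
    schema: EvaluationSchema,
) -> CodingMatrix:
    """Code raw documents with keyword rules into a binary matrix.

    Sub-variables with no rule default to 0.  Deterministic and
    order-independent: each document is coded in isolation.
    """
    rules = list(rules)
    known = set(schema.subvariable_ids)
    by_sub: dict[str, CodingRule] = {}
    for rule in rules:
        if rule.subvariable_id not in known:
            raise SchemaMismatchError(
                f"rule references unknown sub-variable {rule.subvariable_id!r}"
            )
        by_sub[rule.subvariable_id] = rule
    ids = list(texts)
    data = {
        sid: [int(by_sub[sid].matches(texts[pid])) if sid in by_sub else 0 for pid in ids]
        for sid in schema.subvariable_ids
    }
    values = pd.DataFrame(data, index=pd.Index(ids, name="policy_id"))
    policies = [PolicyRecord(policy_id=pid) for pid in ids]
    return CodingMatrix(policies, schema, values)


def column_means(matrix: CodingMatrix) -> pd.Series:
    """Fraction of policies satisfying each sub-variable (column mean)."""
    if matrix.n_policies == 0:
        raise CodingError("cannot take column means of an empty matrix")
    return matrix.values.mean(axis=0)


def lint_exclusive_blocks(
    matrix: CodingMatrix, blocks: Sequence[Sequence[str]]
) -> list[str]:
    """Warn (do not reject) when a configured mutually-exclusive block of
    sub-variables does not have exactly one flag set in some row.

    Returns a list of human-readable warnings, empty when clean.
    """
    warnings = []
    for block in blocks:
        sums = matrix.values[list(block)].sum(axis=1)
        for pid, s in sums.items():
            if s != 1:
                warnings.append(
                    f"policy {pid!r}: block {tuple(block)} has row sum {int(s)} (expected 1)"
                )
    return warnings
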