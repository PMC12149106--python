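"""PMC index computation, grading, and corpus aggregates.

The Policy Modeling Consistency (PMC) index of a policy is the sum of
its first-level variable values, where each first-level value is the
mean of the binary sub-variable flags under that dimension:

    Xi  = (1/Ti) * sum_j Xij          Xij in {0, 1}
    PMC = sum_i Xi                    PMC in [0, n_primaries]

Two summation conventions are supported.  ``full-precision`` sums the
exact fractions.  ``report-parity`` (the default) first rounds each
first-level value half-up to a fixed number of decimals (2 by default)
and then sums — this is the arithmetic used in the published score
tables, whose printed PMC column equals the sum of the printed
two-decimal first-level values rather than of the exact fractions.

Grading for the default nine-dimension framework follows the standard
four-interval scale: Bad [0, 4), Good [4, 6), Excellent [6, 8),
Perfect [8, 9].  The top interval is closed so a perfect score is
classifiable.  Custom frameworks with a different number of primaries
must supply their own cut-points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .coding import CodingMatrix
from .schema import EvaluationSchema

__all__ = [
    "GRADE_LABELS",
    "RoundingPolicy",
    "PolicyScore",
    "CorpusSummary",
    "round_half_up",
    "first_level_score",
    "pmc_index",
    "grade",
    "default_cutpoints",
    "score_corpus",
    "score_from_first_level",
    "summarize",
    "scores_to_frame",
    "write_scores",
]

GRADE_LABELS = ("Bad", "Good", "Excellent", "Perfect")

#: Lower bounds of the four grade intervals on the default 0-9 scale.
_DEFAULT_BOUNDS = (0.0, 4.0, 6.0, 8.0)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.675 -> 0.68), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RoundingPolicy:
    """Summation convention for the PMC index.

    ``mode`` is ``'report-parity'`` (round each first-level value
    half-up to ``decimals`` places before summing) or
    ``'full-precision'`` (sum exact fractions).
    """

    mode: str = "report-parity"
    decimals: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("report-parity", "full-precision"):
            raise ValueError(f"unknown rounding mode {self.mode!r}")
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")

    def apply(self, value: float) -> float:
        if self.mode == "report-parity":
            return round_half_up(value, self.decimals)
        return float(value)


REPORT_PARITY = RoundingPolicy("report-parity")
FULL_PRECISION = RoundingPolicy("full-precision")


@dataclass(frozen=True)
class PolicyScore:
    """Per-policy result: first-level values, PMC index, and grade."""

    policy_id: str
    first_level: Mapping[str, float]
    pmc: float
    grade: str

    @property
    def first_level_values(self) -> tuple[float, ...]:
        return tuple(self.first_level.values())


@dataclass(frozen=True)
class CorpusSummary:
    """Corpus-level aggregates over a list of policy scores."""

    n_policies: int
    mean_pmc: float
    grade_counts: Mapping[str, int]
    grade_percent: Mapping[str, float]
    variable_means: Mapping[str, float]


def first_level_score(subscores: Sequence[int]) -> float:
    """Mean of a dimension's binary flags, at full precision."""
    subscores = list(subscores)
    if not subscores:
        raise ValueError("sub-variable list must be non-empty")
    for v in subscores:
        if v not in (0, 1):
            raise ValueError(f"sub-variable value {v!r} is not binary")
    return sum(subscores) / len(subscores)


def pmc_index(
    first_level: Sequence[float], rounding: RoundingPolicy = REPORT_PARITY
) -> float:
    """Sum first-level values into the PMC index under ``rounding``."""
    vals = [float(v) for v in first_level]
    for v in vals:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"first-level value {v} outside [0, 1]")
    total = sum(rounding.apply(v) for v in vals)
    # re-round the sum at the same precision to clear float residue
    # (0.67 + 0.25 + ... accumulates 1e-16 noise)
    return round_half_up(total, rounding.decimals) if rounding.mode == "report-parity" else total


def default_cutpoints(max_score: float = 9.0) -> tuple[tuple[float, float, str], ...]:
    """Four grade intervals for a given maximum score (default 0-9 scale)."""
    b = _DEFAULT_BOUNDS
    return (
        (b[0], b[1], "Bad"),
        (b[1], b[2], "Good"),
        (b[2], b[3], "Excellent"),
        (b[3], float(max_score), "Perfect"),
    )


def grade(
    pmc: float,
    cutpoints: Optional[Sequence[tuple[float, float, str]]] = None,
    max_score: float = 9.0,
) -> str:
    """Classify a PMC value into a grade label.

    Intervals are half-open on the left except the top interval, which
    is closed at ``max_score``.
    """
    cps = tuple(cutpoints) if cutpoints is not None else default_cutpoints(max_score)
    lo0, hi_last = cps[0][0], cps[-1][1]
    if not (lo0 <= pmc <= hi_last):
        raise ValueError(f"PMC value {pmc} outside [{lo0}, {hi_last}]")
    for lo, hi, label in cps[:-1]:
        if lo <= pmc < hi:
            return label
    return cps[-1][2]


def score_from_first_level(
    values: Sequence[float],
    rounding: RoundingPolicy = REPORT_PARITY,
    policy_id: str = "",
    primary_ids: Optional[Sequence[str]] = None,
    cutpoints: Optional[Sequence[tuple[float, float, str]]] = None,
) -> PolicyScore:
    """Build a :class:`PolicyScore` from first-level values directly.

    This is the entry point for published score tables, which report
    first-level values but not the underlying binary matrix.  Values are
    stored verbatim.
    """
    values = [float(v) for v in values]
    if primary_ids is None:
        primary_ids = [f"X{i}" for i in range(1, len(values) + 1)]
    if len(primary_ids) != len(values):
        raise ValueError(
            f"got {len(values)} values for {len(primary_ids)} primary variables"
        )
    pmc = pmc_index(values, rounding)
    g = grade(pmc, cutpoints=cutpoints, max_score=float(len(values)))
    return PolicyScore(
        policy_id=policy_id,
        first_level=dict(zip(primary_ids, values)),
        pmc=pmc,
        grade=g,
    )


def score_corpus(
    matrix: CodingMatrix,
    schema: Optional[EvaluationSchema] = None,
    rounding: RoundingPolicy = REPORT_PARITY,
    cutpoints: Optional[Sequence[tuple[float, float, str]]] = None,
) -> list[PolicyScore]:
    """Score every policy in a validated coding matrix, in input order."""
    schema = schema if schema is not None else matrix.schema
    scores = []
    for pid in matrix.policy_ids:
        row = matrix.row(pid)
        firsts = [
            first_level_score([int(row[sid]) for sid in p.subvariable_ids])
            for p in schema.primaries
        ]
        scores.append(
            score_from_first_level(
                firsts,
                rounding=rounding,
                policy_id=pid,
                primary_ids=schema.primary_ids,
                cutpoints=cutpoints,
            )
        )
    return scores


def summarize(scores: Sequence[PolicyScore]) -> CorpusSummary:
    """Aggregate a corpus of policy scores.

    Percentages are reported to one decimal, round-half-up.  Variable
    means are full-precision column means of the first-level values.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("cannot summarize an empty score list")
    n = len(scores)
    pmcs = [s.pmc for s in scores]
    counts = {label: 0 for label in GRADE_LABELS}
    for s in scores:
        counts[s.grade] += 1
    percent = {label: round_half_up(100.0 * c / n, 1) for label, c in counts.items()}
    primary_ids = list(scores[0].first_level)
    var_means = {
        pid: float(np.mean([s.first_level[pid] for s in scores])) for pid in primary_ids
    }
    return CorpusSummary(
        n_policies=n,
        mean_pmc=float(np.mean(pmcs)),
        grade_counts=counts,
        grade_percent=percent,
        variable_means=var_means,
    )


def scores_to_frame(scores: Sequence[PolicyScore]) -> pd.DataFrame:
    """Score table as a DataFrame: one row per policy, X columns, pmc, grade."""
    rows = []
    for s in scores:
        row = {"policy_id": s.policy_id, **s.first_level, "pmc": s.pmc, "grade": s.grade}
        rows.append(row)
    return pd.DataFrame(rows).set_index("policy_id")


def write_scores(scores: Sequence[PolicyScore], path: Union[str, Path]) -> None:
    scores_to_frame(scores).to_csv(path, encoding="utf-8")
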