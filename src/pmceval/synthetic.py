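"""Synthetic inputs with known ground truth, plus the published score table.

Two generators emulate the statistical structure the pipeline assumes:

* :func:`generate_matrix` draws binary coding matrices.  Independent
  columns are Bernoulli(p) with a per-sub-variable satisfaction
  probability; *exclusive blocks* model groups of mutually exclusive
  flags (e.g. the four issuer flags, of which real corpora set exactly
  one per policy — which pins that dimension's first-level value to
  1/4) by drawing exactly one member per row from categorical weights.

* :func:`generate_corpus` emits token streams (and raw text) over a
  weighted vocabulary, optionally planting term pairs that co-occur in
  a document with a configured probability, so frequency ranking and
  co-occurrence counting can be checked against ground truth.

Both are driven by a single integer seed through one
``numpy.random.Generator``; no global random state is touched.

:func:`load_reference_scores` returns the published first-level score
table for the 165 Chinese medicine registration policies (values stored
verbatim as printed, typographical quirks included), which lets the
scoring, grading and aggregation stages run against real published
numbers without any download.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coding import CodingMatrix, PolicyRecord
from .pmc import REPORT_PARITY, PolicyScore, RoundingPolicy, pmc_index, score_from_first_level
from .schema import EvaluationSchema, default_schema

__all__ = [
    "ExclusiveBlock",
    "MatrixGeneratorConfig",
    "MatrixSample",
    "generate_matrix",
    "expected_pmc",
    "CorpusGeneratorConfig",
    "CorpusSample",
    "generate_corpus",
    "ReferenceScoreTable",
    "load_reference_scores",
]

#: Pinned SHA-256 of the packaged published score table.
REFERENCE_SCORES_SHA256 = (
    "c6c07cbb1e94c8297e03823f6a57bf12723e08c4d38901db89d5de362ce46fe8"
)


# ---------------------------------------------------------------------------
# binary matrix generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusiveBlock:
    """A group of sub-variables of which exactly one is set per policy."""

    members: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.members) != len(self.weights):
            raise ValueError("one weight per block member required")
        if any(w < 0 for w in self.weights):
            raise ValueError("block weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("block weights must sum to 1")


@dataclass(frozen=True)
class MatrixGeneratorConfig:
    """Sampling plan for a synthetic coding matrix."""

    n_policies: int
    probabilities: Mapping[str, float] = field(default_factory=dict)
    exclusive_blocks: tuple[ExclusiveBlock, ...] = ()
    seed: int = 0
    default_probability: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "exclusive_blocks", tuple(self.exclusive_blocks))
        if self.n_policies < 1:
            raise ValueError("n_policies must be >= 1")
        for sid, p in self.probabilities.items():
            if not (0.0 <= float(p) <= 1.0):
                raise ValueError(f"probability for {sid!r} is {p}, outside [0, 1]")
        if not (0.0 <= self.default_probability <= 1.0):
            raise ValueError("default_probability outside [0, 1]")
        seen: set[str] = set()
        for b in self.exclusive_blocks:
            for m in b.members:
                if m in seen:
                    raise ValueError(f"sub-variable {m!r} in more than one block")
                seen.add(m)
            overlap = seen & set(self.probabilities)
            if overlap:
                raise ValueError(
                    f"block members {sorted(overlap)} also have independent probabilities"
                )

    def column_probability(self, subvariable_id: str) -> float:
        """Marginal P(flag = 1) for a column under this plan."""
        for b in self.exclusive_blocks:
            if subvariable_id in b.members:
                return b.weights[b.members.index(subvariable_id)]
        return float(self.probabilities.get(subvariable_id, self.default_probability))


@dataclass(frozen=True)
class MatrixSample:
    """A generated matrix plus the ground truth that produced it."""

    matrix: CodingMatrix
    config: MatrixGeneratorConfig
    block_selections: Mapping[str, np.ndarray]  # block key -> chosen member index per row


def generate_matrix(
    config: MatrixGeneratorConfig, schema: Optional[EvaluationSchema] = None
) -> MatrixSample:
    """Draw a reproducible synthetic coding matrix for ``schema``."""
    schema = schema if schema is not None else default_schema()
    rng = np.random.default_rng(config.seed)
    n = config.n_policies
    sub_ids = list(schema.subvariable_ids)
    block_members = {m for b in config.exclusive_blocks for m in b.members}
    unknown = block_members - set(sub_ids)
    if unknown:
        raise ValueError(f"block members not in schema: {sorted(unknown)}")

    values = pd.DataFrame(
        0, index=pd.Index([f"S{i+1}" for i in range(n)], name="policy_id"),
        columns=sub_ids, dtype=np.int8,
    )
    for sid in sub_ids:
        if sid in block_members:
            continue
        p = config.column_probability(sid)
        values[sid] = (rng.random(n) < p).astype(np.int8)
    selections: dict[str, np.ndarray] = {}
    for b in config.exclusive_blocks:
        choice = rng.choice(len(b.members), size=n, p=b.weights)
        for j, member in enumerate(b.members):
            values[member] = (choice == j).astype(np.int8)
        selections["+".join(b.members)] = choice

    policies = [PolicyRecord(policy_id=pid) for pid in values.index]
    return MatrixSample(
        matrix=CodingMatrix(policies, schema, values),
        config=config,
        block_selections=selections,
    )


def expected_pmc(
    config: MatrixGeneratorConfig, schema: Optional[EvaluationSchema] = None
) -> float:
    """Closed-form expected full-precision PMC under the sampling plan:
    sum over primaries of (sum of column probabilities) / T."""
    schema = schema if schema is not None else default_schema()
    total = 0.0
    for p in schema.primaries:
        total += sum(config.column_probability(s) for s in p.subvariable_ids) / p.n_subvariables
    return total


# ---------------------------------------------------------------------------
# token corpus generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusGeneratorConfig:
    """Sampling plan for a synthetic token corpus.

    Tokens are drawn i.i.d. from ``vocabulary`` with probability
    proportional to the weights.  Each planted pair ``(a, b, p)`` is,
    with probability ``p`` per document, forced to co-occur by writing
    ``a`` and ``b`` over two distinct token positions.
    """

    n_documents: int
    vocabulary: Mapping[str, float]
    tokens_per_document: int = 50
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    sentence_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "planted_pairs",
            tuple((a, b, float(p)) for a, b, p in self.planted_pairs),
        )
        if not self.vocabulary:
            raise ValueError("vocabulary must be non-empty")
        if any(w <= 0 for w in self.vocabulary.values()):
            raise ValueError("vocabulary weights must be positive")
        if self.n_documents < 1 or self.tokens_per_document < 1:
            raise ValueError("n_documents and tokens_per_document must be >= 1")
        for a, b, p in self.planted_pairs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"planted pair ({a}, {b}) probability {p} outside [0, 1]")
        if self.planted_pairs and self.tokens_per_document < 2:
            raise ValueError("planting pairs requires at least 2 tokens per document")


@dataclass(frozen=True)
class CorpusSample:
    """Generated corpus: raw texts, pre-tokenized streams, ground truth."""

    texts: Mapping[str, str]
    tokens: Mapping[str, tuple[str, ...]]
    planted: Mapping[str, tuple[tuple[str, str], ...]]  # doc -> pairs planted there
    config: CorpusGeneratorConfig


def generate_corpus(config: CorpusGeneratorConfig) -> CorpusSample:
    """Draw a reproducible synthetic corpus.

    Raw text renders each document as space-separated tokens with a
    sentence-final period every ``sentence_length`` tokens (one sentence
    per document when unset), so whitespace tokenization recovers the
    token stream exactly.
    """
    rng = np.random.default_rng(config.seed)
    terms = list(config.vocabulary)
    weights = np.array([config.vocabulary[t] for t in terms], dtype=float)
    probs = weights / weights.sum()

    texts: dict[str, str] = {}
    tokens: dict[str, tuple[str, ...]] = {}
    planted: dict[str, tuple[tuple[str, str], ...]] = {}
    for d in range(config.n_documents):
        pid = f"D{d+1}"
        toks = [terms[i] for i in rng.choice(len(terms), size=config.tokens_per_document, p=probs)]
        placed: list[tuple[str, str]] = []
        for a, b, p in config.planted_pairs:
            if rng.random() < p:
                i, j = rng.choice(len(toks), size=2, replace=False)
                toks[int(i)], toks[int(j)] = a, b
                placed.append((a, b))
        tokens[pid] = tuple(toks)
        planted[pid] = tuple(placed)
        L = config.sentence_length or len(toks)
        parts = [" ".join(toks[i : i + L]) + "." for i in range(0, len(toks), L)]
        texts[pid] = " ".join(parts)
    return CorpusSample(texts=texts, tokens=tokens, planted=planted, config=config)


# ---------------------------------------------------------------------------
# published score table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceScoreTable:
    """The published 165-policy first-level score table, verbatim.

    ``frame`` has one row per policy (index ``P1``..``P165`` in
    publication order) with the policy label, nine first-level values
    and the printed PMC index.  ``average`` is the printed average row.
    Values are stored exactly as printed — including a handful of
    first-level values not expressible with the default framework's
    sub-variable counts; :meth:`parity_mismatches` reports (never
    corrects) rows whose printed PMC is not the two-decimal sum of the
    printed first-level values.
    """

    frame: pd.DataFrame
    average: pd.Series

    @property
    def n_policies(self) -> int:
        return len(self.frame)

    @property
    def primary_ids(self) -> tuple[str, ...]:
        return tuple(f"X{i}" for i in range(1, 10))

    def first_level(self, policy_id: str) -> tuple[float, ...]:
        return tuple(float(self.frame.loc[policy_id, x]) for x in self.primary_ids)

    def printed_pmc(self, policy_id: str) -> float:
        return float(self.frame.loc[policy_id, "pmc"])

    def scores(self, rounding: RoundingPolicy = REPORT_PARITY) -> list[PolicyScore]:
        """Score every row from its printed first-level values."""
        return [
            score_from_first_level(
                self.first_level(pid), rounding=rounding, policy_id=pid
            )
            for pid in self.frame.index
        ]

    def parity_mismatches(self, tolerance: float = 0.01) -> list[tuple[str, float, float]]:
        """Rows where the two-decimal sum differs from the printed PMC.

        Returns (policy_id, recomputed, printed) triples; empty when the
        whole table reproduces under report-parity summation.
        """
        out = []
        for pid in self.frame.index:
            recomputed = pmc_index(self.first_level(pid), REPORT_PARITY)
            printed = self.printed_pmc(pid)
            if abs(recomputed - printed) > tolerance + 1e-12:
                out.append((pid, recomputed, printed))
        return out


def _data_bytes(name: str) -> bytes:
    return resources.files("pmceval.data").joinpath(name).read_bytes()


@lru_cache(maxsize=1)
def load_reference_scores() -> ReferenceScoreTable:
    """Load the packaged published score table (165 rows + average row)."""
    raw = _data_bytes("published_scores.csv")
    digest = hashlib.sha256(raw).hexdigest()
    if digest != REFERENCE_SCORES_SHA256:
        raise RuntimeError(
            "packaged score table is corrupted: checksum "
            f"{digest} != {REFERENCE_SCORES_SHA256}"
        )
    import io

    frame = pd.read_csv(io.BytesIO(raw), index_col="policy_id", encoding="utf-8")
    avg = pd.read_csv(
        io.BytesIO(_data_bytes("published_scores_average.csv")), encoding="utf-8"
    ).iloc[0]
    return ReferenceScoreTable(frame=frame, average=avg)
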