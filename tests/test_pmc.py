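"""PMC scoring: first-level values, index summation, grades, aggregates."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmceval import (
    FULL_PRECISION,
    REPORT_PARITY,
    CodingMatrix,
    PolicyRecord,
    RoundingPolicy,
    first_level_score,
    grade,
    load_schema,
    pmc_index,
    round_half_up,
    score_corpus,
    score_from_first_level,
    summarize,
)

P1_ROW = (0.67, 1, 0.25, 1, 0.5, 0.5, 0.67, 0.5, 0.8)
P156_ROW = (0.83, 1, 0.25, 1, 1, 0.83, 1, 1, 1)
P3_ROW = (0.5, 0.67, 0.25, 0.5, 0.33, 0.33, 0.67, 0.25, 0.4)


class TestFirstLevel:
    @pytest.mark.parametrize(
        "flags,expected",
        [([1, 1, 1, 1, 1], 1.0), ([0, 0, 0], 0.0), ([1, 1, 1, 1, 0], 0.8),
         ([1, 0, 0], 1 / 3)],
    )
    def test_mean_of_flags(self, flags, expected):
        assert first_level_score(flags) == pytest.approx(expected)

    def test_rejects_empty_and_non_binary(self):
        with pytest.raises(ValueError):
            first_level_score([])
        with pytest.raises(ValueError):
            first_level_score([1, 2, 0])


class TestPmcIndex:
    def test_published_report_parity_rows(self):
        assert pmc_index(P1_ROW, REPORT_PARITY) == 5.89
        assert pmc_index(P156_ROW, REPORT_PARITY) == 7.91
        assert pmc_index(P3_ROW, REPORT_PARITY) == 3.9

    def test_zeros(self):
        assert pmc_index([0.0] * 9) == 0.0

    def test_report_parity_rounds_before_summing(self):
        # exact thirds etc. sum to 5.883...; two-decimal summation gives 5.89
        exact = (2 / 3, 1, 0.25, 1, 0.5, 0.5, 2 / 3, 0.5, 0.8)
        assert pmc_index(exact, FULL_PRECISION) == pytest.approx(5.8833333333)
        assert pmc_index(exact, REPORT_PARITY) == 5.89

    def test_round_half_up_not_bankers(self):
        assert round_half_up(0.625, 2) == 0.63
        assert round_half_up(0.125, 2) == 0.13  # banker's would give 0.12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pmc_index([1.2, 0.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_parity_vs_full_precision_bound(self, values):
        # each rounded term moves by at most 0.005
        diff = abs(pmc_index(values, REPORT_PARITY) - pmc_index(values, FULL_PRECISION))
        assert diff <= len(values) * 0.005 + 1e-9


class TestGrade:
    @pytest.mark.parametrize(
        "pmc,expected",
        [(0.0, "Bad"), (3.9, "Bad"), (3.93, "Bad"), (4.0, "Good"), (5.89, "Good"),
         (6.0, "Excellent"), (7.91, "Excellent"), (8.0, "Perfect"), (9.0, "Perfect")],
    )
    def test_interval_membership(self, pmc, expected):
        assert grade(pmc) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            grade(9.5)
        with pytest.raises(ValueError):
            grade(-0.1)

    @given(st.floats(0, 9))
    def test_partition_no_gaps_and_monotone(self, x):
        g = grade(x)
        assert g in ("Bad", "Good", "Excellent", "Perfect")
        order = {"Bad": 0, "Good": 1, "Excellent": 2, "Perfect": 3}
        if x + 0.25 <= 9:
            assert order[grade(x + 0.25)] >= order[g]

    def test_custom_cutpoints_for_non_default_schema(self):
        cps = ((0, 1, "low"), (1, 2, "high"))
        assert grade(0.5, cutpoints=cps) == "low"
        assert grade(2.0, cutpoints=cps) == "high"


def _tiny_matrix(schema, cells):
    values = pd.DataFrame(
        cells, index=[f"P{i+1}" for i in range(len(cells))],
        columns=list(schema.subvariable_ids),
    )
    policies = [PolicyRecord(policy_id=p) for p in values.index]
    return CodingMatrix(policies, schema, values)


class TestScoreCorpus:
    def test_all_ones_and_all_zeros(self, schema):
        ones = _tiny_matrix(schema, [[1] * 41] * 2)
        zeros = _tiny_matrix(schema, [[0] * 41] * 2)
        for s in score_corpus(ones):
            assert s.pmc == 9.0 and s.grade == "Perfect"
        for s in score_corpus(zeros):
            assert s.pmc == 0.0 and s.grade == "Bad"

    def test_planted_row_sums(self, schema):
        # one policy satisfying exactly the first k sub-variables per primary
        row = []
        planted = {}
        for p in schema.primaries:
            k = min(2, p.n_subvariables)
            row.extend([1] * k + [0] * (p.n_subvariables - k))
            planted[p.id] = k / p.n_subvariables
        m = _tiny_matrix(schema, [row])
        (s,) = score_corpus(m, rounding=FULL_PRECISION)
        for pid, expected in planted.items():
            assert s.first_level[pid] == pytest.approx(expected)
        assert s.pmc == pytest.approx(sum(planted.values()))

    @given(st.data())
    def test_agrees_with_brute_force_enumeration(self, data):
        """Exact-fraction oracle on tiny random schemas and matrices."""
        n_prim = data.draw(st.integers(1, 3))
        counts = [data.draw(st.integers(1, 4)) for _ in range(n_prim)]
        yaml_text = "name: rnd\nprimaries:\n" + "".join(
            f"  - id: X{i+1}\n    subvariables:\n" + "".join(
                f"      - {{id: X{i+1}_{j+1}}}\n" for j in range(c)
            )
            for i, c in enumerate(counts)
        )
        sch = load_schema(yaml_text)
        n_pol = data.draw(st.integers(1, 5))
        cells = [
            [data.draw(st.integers(0, 1)) for _ in range(sum(counts))]
            for _ in range(n_pol)
        ]
        m = _tiny_matrix(sch, cells)
        cps = ((0.0, float(n_prim), "any"), (float(n_prim), float(n_prim), "top"))
        scores = score_corpus(m, rounding=FULL_PRECISION, cutpoints=cps)
        # oracle: direct cell enumeration with exact rational arithmetic
        for row, s in zip(cells, scores):
            offset, expect = 0, Fraction(0)
            for c in counts:
                expect += Fraction(sum(row[offset : offset + c]), c)
                offset += c
            assert s.pmc == pytest.approx(float(expect), abs=1e-12)

    def test_monotone_under_zero_to_one_flip(self, schema):
        rng = np.random.default_rng(7)
        row = rng.integers(0, 2, 41)
        m = _tiny_matrix(schema, [list(row)])
        (base,) = score_corpus(m, rounding=FULL_PRECISION)
        zero_cols = [i for i, v in enumerate(row) if v == 0]
        for i in zero_cols:
            flipped = list(row)
            flipped[i] = 1
            (s,) = score_corpus(_tiny_matrix(schema, [flipped]), rounding=FULL_PRECISION)
            sid = schema.subvariable_ids[i]
            T = schema.parent_of(sid).n_subvariables
            assert s.pmc == pytest.approx(base.pmc + 1 / T)


class TestScoreFromFirstLevel:
    def test_published_rows(self):
        assert score_from_first_level(P3_ROW).pmc == 3.9
        assert score_from_first_level(P3_ROW).grade == "Bad"
        s = score_from_first_level([1] * 9)
        assert s.pmc == 9 and s.grade == "Perfect"

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_from_first_level([0.5, 0.5], primary_ids=["X1", "X2", "X3"])

    def test_values_stored_verbatim(self):
        s = score_from_first_level(P1_ROW)
        assert s.first_level_values == tuple(float(v) for v in P1_ROW)


class TestSummarize:
    def test_boundary_membership(self):
        scores = [score_from_first_level([v / 9] * 9) for v in (4.0, 6.0)]
        # force exact pmc values via direct construction
        a = score_from_first_level([0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.0])
        b = score_from_first_level([1, 1, 1, 1, 1, 1, 0, 0, 0])
        assert a.pmc == 4.0 and b.pmc == 6.0
        s = summarize([a, b])
        assert s.mean_pmc == 5.0
        assert s.grade_counts["Good"] == 1 and s.grade_counts["Excellent"] == 1

    def test_single_score(self):
        s = summarize([score_from_first_level([0.5] * 9 + [], policy_id="p")])
        assert s.n_policies == 1 and s.grade_counts["Good"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_percent_round_half_up(self):
        scores = [score_from_first_level([1] * 9)] * 39 + [
            score_from_first_level([0.5] * 8 + [0.0])
        ] * 126
        s = summarize(scores)
        assert s.grade_percent["Perfect"] == round_half_up(100 * 39 / 165, 1) == 23.6
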