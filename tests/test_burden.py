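"""Exact 2x2 inference against printed values and independent oracles."""

import math
from dataclasses import dataclass
from math import comb
from typing import Optional

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twohitscan.burden import (
    Contingency2x2,
    association_tables,
    burden_scan,
    exact_2x2,
    fisher_two_sided,
    or_conditional_mle,
    rank_sum_test,
    variant_level_test,
)


def fisher_oracle(a, b, c, d):
    """Integer-exact enumeration of the two-sided point-probability p."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    scale = 10**7
    kept = sum(v for v in nums if v * scale <= obs * (scale + 1))
    return kept / comb(n, c1)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "cells,expected,places",
        [
            ((4, 8, 1, 69), 0.0013, 4),
            ((2, 10, 1, 69), 0.0547, 4),
            ((9, 1, 15, 31), 0.001, 3),
            ((2, 10, 2, 68), 0.1002, 4),
            ((2, 10, 4, 66), 0.2108, 4),
            ((2, 10, 7, 63), 0.6134, 4),
            ((5, 5, 5, 5), 1.0, 6),
        ],
    )
    def test_printed_values(self, cells, expected, places):
        assert round(fisher_two_sided(Contingency2x2(*cells)), places) == expected

    def test_degenerate_margins_give_p_one(self):
        assert fisher_two_sided(Contingency2x2(0, 0, 3, 4)) == 1.0
        assert fisher_two_sided(Contingency2x2(0, 3, 0, 4)) == 1.0

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_matches_integer_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = Contingency2x2(a, b, c, d)
        assert fisher_two_sided(t) == pytest.approx(min(1.0, fisher_oracle(a, b, c, d)), abs=1e-10)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_transposition_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p1 = fisher_two_sided(Contingency2x2(a, b, c, d))
        p2 = fisher_two_sided(Contingency2x2(a, c, b, d))
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestConditionalMleOr:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((4, 8, 1, 69), 31.66),
            ((13, 2, 17, 39), 14.31),
            ((9, 1, 15, 31), 17.67),
        ],
    )
    def test_printed_estimates(self, cells, expected):
        res = or_conditional_mle(Contingency2x2(*cells))
        assert round(res.or_cmle, 2) == expected
        assert res.ci_low < res.or_cmle < res.ci_high

    def test_printed_ci_bounds(self):
        res = or_conditional_mle(Contingency2x2(4, 8, 1, 69))
        assert res.ci_low == pytest.approx(2.7317, abs=1e-3)
        res2 = or_conditional_mle(Contingency2x2(9, 1, 15, 31))
        assert res2.ci_low == pytest.approx(2.123, abs=1e-2)

    def test_extreme_cells_give_zero_and_infinity(self):
        res = or_conditional_mle(Contingency2x2(0, 12, 7, 63))
        assert res.or_cmle == 0.0 and res.ci_low == 0.0 and res.ci_high > 0
        res = or_conditional_mle(Contingency2x2(2, 10, 0, 70))
        assert res.or_cmle == math.inf and res.ci_high == math.inf and res.ci_low > 1

    def test_degenerate_margins_flagged(self):
        res = or_conditional_mle(Contingency2x2(0, 0, 5, 5))
        assert res.degenerate and res.or_cmle is None

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(1, 12), st.integers(1, 12), st.integers(1, 12), st.integers(1, 12))
    def test_score_equation_satisfied(self, a, b, c, d):
        """The fitted psi makes the expected a-cell equal the observed one."""
        from twohitscan.burden import _mean, _support

        t = Contingency2x2(a, b, c, d)
        res = or_conditional_mle(t)
        if res.or_cmle in (0.0, math.inf, None):
            return
        k, logw = _support(t)
        assert _mean(logw, k, math.log(res.or_cmle)) == pytest.approx(a, abs=1e-6)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(1, 10), st.integers(1, 10), st.integers(1, 10), st.integers(1, 10))
    def test_row_swap_gives_reciprocal(self, a, b, c, d):
        r1 = or_conditional_mle(Contingency2x2(a, b, c, d))
        r2 = or_conditional_mle(Contingency2x2(c, d, a, b))
        assert r1.or_cmle * r2.or_cmle == pytest.approx(1.0, rel=1e-6)

    def test_psi_one_reduces_to_central_hypergeometric(self):
        from scipy.stats import hypergeom

        from twohitscan.burden import _support

        t = Contingency2x2(3, 7, 6, 14)
        k, logw = _support(t)
        p = np.exp(logw - np.logaddexp.reduce(logw))
        expected = hypergeom.pmf(k, 30, 10, 9)
        assert np.allclose(p, expected, atol=1e-12)


class TestBurdenScan:
    def scan(self, fixtures):
        case = {}
        for r in fixtures.table2.itertuples():
            case[r.gene] = {
                "non_LS": {f"n{i}" for i in range(r.n_nonls)},
                "LS": {f"l{i}" for i in range(r.n_ls)},
            }
        ref = {
            r.gene: {f"r{i}" for i in range(r.n_reference)}
            for r in fixtures.table2.itertuples()
        }
        return burden_scan(case, ref, {"non_LS": 12, "LS": 7, "reference": 70})

    def test_printed_table_rows(self, fixtures):
        rows = {r.gene: r for r in self.scan(fixtures)}
        assert round(rows["RECQL5"].nonls_vs_ref.p_two_sided, 4) == 0.0013
        assert round(rows["RECQL5"].nonls_vs_ref.or_cmle, 2) == 31.66
        assert rows["RECQL5"].significant
        assert round(rows["EME2"].nonls_vs_ref.p_two_sided, 4) == 0.0547
        assert round(rows["MSH3"].nonls_vs_ref.p_two_sided, 4) == 0.1002
        assert rows["MLH1"].ls_vs_ref.p_two_sided < 0.0001
        assert rows["MLH1"].nonls_vs_ref.p_two_sided > 0.999

    def test_rows_sorted_by_nonls_p(self, fixtures):
        rows = self.scan(fixtures)
        p = [r.nonls_vs_ref.p_two_sided for r in rows]
        assert p == sorted(p)

    def test_single_carrier_genes_excluded(self):
        rows = burden_scan(
            {"G1": {"non_LS": {"a"}, "LS": set()}},
            {},
            {"non_LS": 12, "LS": 7, "reference": 70},
        )
        assert rows == []

    def test_carrier_count_exceeding_group_size_rejected(self):
        with pytest.raises(ValueError):
            burden_scan(
                {"G1": {"non_LS": {"a", "b", "c"}, "LS": set()}},
                {},
                {"non_LS": 2, "LS": 7, "reference": 70},
            )


class TestVariantLevel:
    def test_recurrent_variant_absent_from_reference(self):
        assert round(variant_level_test(2, 12, 0, 70), 2) == 0.02

    def test_null_case(self):
        assert variant_level_test(0, 12, 0, 70) == 1.0

    def test_extreme_case_matches_enumeration(self):
        assert variant_level_test(12, 12, 0, 70) == pytest.approx(
            fisher_oracle(12, 0, 0, 70), abs=1e-12
        )


@dataclass
class P:
    is_carrier: bool
    early_onset: bool
    strong_fh: Optional[bool]
    synchronous: bool


def cohort_from_margins(n, n_carrier, n_eo, n_carrier_eo, n_fh_known, n_fh_pos,
                        n_carrier_fh_known, n_carrier_fh_pos):
    """Deterministic patient list reproducing the given margins."""
    pts = []
    for i in range(n):
        carrier = i < n_carrier
        if carrier:
            eo = i < n_carrier_eo
            fh_known = i < n_carrier_fh_known
            fh = fh_known and i < n_carrier_fh_pos
        else:
            j = i - n_carrier
            eo = j < n_eo - n_carrier_eo
            fh_known = j < n_fh_known - n_carrier_fh_known
            fh = fh_known and j < (n_fh_pos - n_carrier_fh_pos)
        pts.append(P(carrier, eo, fh if fh_known else None, synchronous=i % 2 == 0))
    return pts


class TestAssociations:
    def test_tables_from_printed_margins(self, fixtures):
        m = fixtures.cohort_margins
        pts = cohort_from_margins(
            m["n_patients"], m["n_ls_carriers"], m["n_eo"], m["n_ls_eo"],
            m["n_fh_known"], m["n_fh_ge2"], m["n_ls_fh_known"], m["n_ls_fh_ge2"],
        )
        assoc = {label: (t, res) for label, t, res in association_tables(pts)}
        t_eo, res_eo = assoc["eoMPC"]
        assert (t_eo.a, t_eo.b, t_eo.c, t_eo.d) == (13, 2, 17, 39)
        assert round(res_eo.or_cmle, 2) == 14.31
        t_fh, res_fh = assoc["strong_family_history"]
        assert (t_fh.a, t_fh.b, t_fh.c, t_fh.d) == (9, 1, 15, 31)
        assert round(res_fh.or_cmle, 2) == 17.67
        assert round(res_fh.p_two_sided, 3) == 0.001
        # unknown family history excluded: denominators sum to 56, not 71
        assert t_fh.a + t_fh.b + t_fh.c + t_fh.d == 56

    def test_degenerate_table_flagged_without_estimate(self):
        pts = [P(True, True, True, True) for _ in range(5)]
        assoc = {label: (t, res) for label, t, res in association_tables(pts)}
        t, res = assoc["eoMPC"]
        assert res is None and t.degenerate


class TestRankSum:
    def test_identical_samples(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_exact_small_sample(self):
        # complete separation of 3 vs 3: the smallest attainable two-sided p
        assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_shift_invariance_of_decision(self):
        p1 = rank_sum_test([1.0, 2.0, 5.0, 7.0], [3.0, 4.0, 6.0, 8.0])
        p2 = rank_sum_test([101.0, 102.0, 105.0, 107.0], [103.0, 104.0, 106.0, 108.0])
        assert p1 == pytest.approx(p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def test_exact_result_invariants():
    res = exact_2x2(Contingency2x2(3, 9, 2, 68))
    assert 0 <= res.p_two_sided <= 1
    assert res.ci_low <= res.or_cmle <= res.ci_high
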