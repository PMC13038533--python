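"""Disproportionality statistics: hand oracles, library cross-checks,
and structural invariants."""

from __future__ import annotations

import math
from itertools import product

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal import (
    ContingencyTable,
    DisproportionalityModel,
    build_contingency,
    classical_ror,
    expected_count,
    flag_signal,
    ic_interval,
    scan_all_terms,
    shrunk_ratio_and_ic,
)
from pvsignal.terminology import TermMap

from conftest import make_cases


class TestExpectedCount:
    @pytest.mark.parametrize("n_drug,n_event,n_total,expected", [
        (100, 50, 1000, 5.0),
        (0, 7, 100, 0.0),
        (7, 3, 21, 1.0),
    ])
    def test_arithmetic(self, n_drug, n_event, n_total, expected):
        assert expected_count(n_drug, n_event, n_total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            expected_count(1, 1, 0)


class TestShrunkRatio:
    def test_null_symmetry(self):
        ratio, ic = shrunk_ratio_and_ic(7, 7)
        assert ratio == 1.0 and ic == 0.0

    def test_hand_values(self):
        ratio, ic = shrunk_ratio_and_ic(2, 0.5)
        assert ratio == pytest.approx(2.5)
        assert ic == pytest.approx(math.log2(2.5))  # ~1.3219
        ratio0, ic0 = shrunk_ratio_and_ic(0, 10)
        assert ratio0 == pytest.approx(0.5 / 10.5)
        assert ic0 == pytest.approx(math.log2(0.5 / 10.5))  # ~-4.392


class TestIcInterval:
    def test_hand_value_n3(self):
        lo, _ = ic_interval(1.0, 3)
        assert lo == pytest.approx(1 - 3.3 * 3.5 ** -0.5 - 2 * 3.5 ** -1.5)
        assert lo == pytest.approx(-1.0694, abs=1e-4)

    def test_hand_value_n0(self):
        lo, _ = ic_interval(0.0, 0)
        assert lo == pytest.approx(-3.3 * 0.5 ** -0.5 - 2 * 0.5 ** -1.5)
        assert lo == pytest.approx(-10.324, abs=1e-3)

    def test_width_strictly_decreasing_and_vanishing(self):
        widths = []
        for n in (0, 1, 3, 10, 100, 10_000, 1_000_000):
            lo, hi = ic_interval(2.0, n)
            assert lo < 2.0 < hi
            widths.append(hi - lo)
        assert all(w1 > w2 for w1, w2 in zip(widths, widths[1:]))
        assert widths[-1] < 0.01


class TestClassicalRor:
    def test_null_table(self):
        ror, lo, hi, corrected = classical_ror(ContingencyTable(10, 10, 10, 10))
        assert ror == 1.0 and lo < 1.0 < hi and not corrected

    def test_hand_value(self):
        ror, lo, hi, corrected = classical_ror(ContingencyTable(20, 10, 5, 10))
        assert ror == pytest.approx(4.0)
        assert lo == pytest.approx(math.exp(math.log(4) - 1.96 * math.sqrt(0.45)), rel=1e-6)
        assert (lo, hi) == (pytest.approx(1.074, abs=1e-3), pytest.approx(14.90, abs=1e-2))

    def test_zero_cell_haldane_correction(self):
        ror, lo, hi, corrected = classical_ror(ContingencyTable(0, 5, 5, 5))
        assert corrected
        assert ror == pytest.approx(0.5 * 5.5 / (5.5 * 5.5))  # ~0.0909

    def test_matches_statsmodels_on_small_tables(self):
        """Independent oracle: statsmodels Table2x2 over all cells in 1..5."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for a, b, c, d in product(range(1, 6), repeat=4):
            table = sm.Table2x2([[a, b], [c, d]], shift_zeros=False)
            ror, lo, hi, _ = classical_ror(ContingencyTable(a, b, c, d))
            assert ror == pytest.approx(table.oddsratio, rel=1e-9)
            sm_lo, sm_hi = table.oddsratio_confint(0.05)
            # statsmodels uses z=1.95996...; we use the printed 1.96
            assert lo == pytest.approx(sm_lo, rel=1e-3)
            assert hi == pytest.approx(sm_hi, rel=1e-3)

    def test_matches_case_list_enumeration(self):
        """Second oracle: literal enumeration of a toy case list."""
        cases = make_cases(
            [{"caseid": f"t{i}", "target_drug": True, "pts": {"X"}} for i in range(3)]
            + [{"caseid": f"u{i}", "target_drug": True, "pts": {"Y"}} for i in range(2)]
            + [{"caseid": f"v{i}", "target_drug": False, "pts": {"X"}} for i in range(4)]
            + [{"caseid": f"w{i}", "target_drug": False, "pts": {"Y"}} for i in range(5)]
        )
        # brute force: count (case, term) pairs directly
        pairs = [(bool(t), pt) for t, pts in zip(cases.cases["target_drug"], cases.cases["pts"])
                 for pt in pts]
        a = sum(1 for t, pt in pairs if t and pt == "X")
        b = sum(1 for t, pt in pairs if t and pt != "X")
        c = sum(1 for t, pt in pairs if not t and pt == "X")
        d = sum(1 for t, pt in pairs if not t and pt != "X")
        table = build_contingency(cases, "X")
        assert (table.a, table.b, table.c, table.d) == (a, b, c, d) == (3, 2, 4, 5)
        ror, *_ = classical_ror(table)
        assert ror == pytest.approx((a / b) / (c / d))


class TestFlagSignal:
    @pytest.mark.parametrize("n,ror_l95,ic_025,rule,expected", [
        (3, 1.2, 0.1, "either", True),
        (2, 5.0, 2.0, "either", False),   # below the three-report floor
        (10, 0.8, -0.2, "either", False),
        (5, 1.2, -0.1, "either", True),   # ROR bound alone suffices
        (5, 1.2, -0.1, "both", False),    # conjunction rule
        (5, 1.2, 0.1, "both", True),
    ])
    def test_rules(self, n, ror_l95, ic_025, rule, expected):
        assert flag_signal(n, ror_l95, ic_025, rule=rule) is expected

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            flag_signal(3, 2.0, 1.0, rule="any")


class TestBuildContingency:
    def test_single_target_case(self):
        cases = make_cases([{"caseid": "c1", "target_drug": True, "pts": {"X"}}])
        table = build_contingency(cases, "X")
        assert (table.a, table.c) == (1, 0)

    def test_four_case_hand_enumeration(self):
        cases = make_cases([
            {"caseid": "c1", "target_drug": True, "pts": {"X"}},
            {"caseid": "c2", "target_drug": True, "pts": {"Y"}},
            {"caseid": "c3", "target_drug": False, "pts": {"X"}},
            {"caseid": "c4", "target_drug": False, "pts": {"Y"}},
        ])
        table = build_contingency(cases, "X")
        assert (table.a, table.b, table.c, table.d) == (1, 1, 1, 1)

    def test_label_swap_symmetry(self):
        rows = [
            {"caseid": "c1", "target_drug": True, "pts": {"X", "Y"}},
            {"caseid": "c2", "target_drug": True, "pts": {"Y"}},
            {"caseid": "c3", "target_drug": False, "pts": {"X"}},
            {"caseid": "c4", "target_drug": False, "pts": {"Z"}},
        ]
        swapped = [dict(r, target_drug=not r["target_drug"]) for r in rows]
        t1 = build_contingency(make_cases(rows), "X")
        t2 = build_contingency(make_cases(swapped), "X")
        assert (t1.a, t1.b, t1.c, t1.d) == (t2.c, t2.d, t2.a, t2.b)

    def test_absent_term_still_valid(self):
        cases = make_cases([{"caseid": "c1", "target_drug": True, "pts": {"X"}}])
        table = build_contingency(cases, "Nope")
        assert table.a == table.c == 0 and table.n_total == 1

    def test_universe_conserved_across_terms(self):
        cases = make_cases([
            {"caseid": "c1", "target_drug": True, "pts": {"X", "Y", "Z"}},
            {"caseid": "c2", "target_drug": False, "pts": {"X"}},
            {"caseid": "c3", "target_drug": False, "pts": {"Y", "Z"}},
        ])
        totals = {t: build_contingency(cases, t).n_total for t in "XYZ"}
        assert set(totals.values()) == {6}

    def test_soc_level_aggregation(self):
        tmap = TermMap.from_pairs([("X", "S1"), ("Y", "S1"), ("Z", "S2")])
        cases = make_cases([
            {"caseid": "c1", "target_drug": True, "pts": {"X", "Y"}},  # one S1 pair
            {"caseid": "c2", "target_drug": False, "pts": {"Z"}},
        ])
        table = build_contingency(cases, "S1", level="SOC", term_map=tmap)
        assert (table.a, table.b, table.c, table.d) == (1, 0, 0, 1)


class TestScan:
    def test_no_target_cases_gives_empty_scan(self):
        cases = make_cases([{"caseid": "c1", "target_drug": False, "pts": {"X"}}])
        assert scan_all_terms(cases).empty

    def test_identical_counts_tie_break_by_term_name(self):
        cases = make_cases(
            [{"caseid": f"c{i}", "target_drug": True, "pts": {"B", "A"}} for i in range(4)]
            + [{"caseid": f"d{i}", "target_drug": False, "pts": {"C"}} for i in range(4)]
        )
        frame = scan_all_terms(cases)
        assert list(frame["term"]) == ["A", "B"]
        pd.testing.assert_series_equal(
            frame.loc[0, ["ror", "ic"]], frame.loc[1, ["ror", "ic"]], check_names=False
        )

    def test_ic_identity_and_flag_consistency(self):
        cases = make_cases(
            [{"caseid": f"c{i}", "target_drug": True, "pts": {"X", "Y"}} for i in range(5)]
            + [{"caseid": f"d{i}", "target_drug": False, "pts": {"Y", "Z"}} for i in range(7)]
        )
        frame = scan_all_terms(cases)
        for row in frame.itertuples(index=False):
            assert row.ic == pytest.approx(math.log2(row.ror_shrunk), abs=1e-12)
            assert row.significant == flag_signal(row.a, row.ror_l95, row.ic_025)

    def test_results_contingency_round_trip(self):
        cases = make_cases(
            [{"caseid": f"c{i}", "target_drug": True, "pts": {"X"}} for i in range(3)]
            + [{"caseid": f"d{i}", "target_drug": False, "pts": {"Y"}} for i in range(3)]
        )
        res = DisproportionalityModel(cases).fit()
        table = res.contingency("X")
        assert (table.a, table.b, table.c, table.d) == (3, 0, 0, 3)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n_obs=st.integers(min_value=0, max_value=10_000),
    n_exp=st.floats(min_value=0.0, max_value=10_000.0, allow_nan=False),
)
def test_ic_is_log2_of_shrunk_ratio_and_bounds_bracket(n_obs, n_exp):
    ratio, ic = shrunk_ratio_and_ic(n_obs, n_exp)
    assert ic == pytest.approx(math.log2(ratio), abs=1e-12)
    lo, hi = ic_interval(ic, n_obs)
    assert lo < ic < hi
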