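"""2x2 statistics, the signal screen, strata, ages and class summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from thrombosignal import signals
from thrombosignal.signals import (ContingencyTable, contingency, fisher_p,
                                   haldane, ror, ror_ci)


class TestHaldane:
    def test_zero_cell_shifts_all_four(self):
        t = haldane(ContingencyTable(0, 10, 5, 20))
        assert t.cells == (0.5, 10.5, 5.5, 20.5)
        assert t.corrected

    def test_no_zero_cell_is_identity(self):
        t = ContingencyTable(1, 1, 1, 1)
        assert haldane(t) is t

    def test_all_zero_cells_give_unit_ror(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)  # empty table is invalid...
        t = haldane(ContingencyTable(0, 0, 0, 1))  # ...one report suffices
        assert min(t.cells) == 0.5


class TestRor:
    def test_balanced_table_is_one(self):
        assert ror(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_direct_arithmetic(self):
        assert ror(ContingencyTable(20, 80, 10, 90)) == pytest.approx(2.25)

    def test_corrected_zero_cell_value(self):
        t = haldane(ContingencyTable(0, 10, 5, 20))
        assert ror(t) == pytest.approx(0.5 * 20.5 / (10.5 * 5.5))

    def test_zero_denominator_directs_to_haldane(self):
        with pytest.raises(ZeroDivisionError, match="haldane"):
            ror(ContingencyTable(5, 0, 5, 5))

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50), st.floats(0.01, 100))
    def test_scale_invariance(self, a, b, c, d, k):
        base = ror(ContingencyTable(a, b, c, d))
        scaled = ror(ContingencyTable(a * k, b * k, c * k, d * k))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_monotone_in_a(self):
        values = [ror(ContingencyTable(a, 10, 10, 10)) for a in range(1, 6)]
        assert all(x < y for x, y in zip(values, values[1:]))


class TestRorCi:
    def test_symmetric_about_one_on_log_scale(self):
        lo, hi = ror_ci(ContingencyTable(5, 5, 5, 5))
        assert math.log(lo) == pytest.approx(-math.log(hi))

    def test_hand_computed_woolf_interval(self):
        lo, hi = ror_ci(ContingencyTable(20, 80, 10, 90), z=1.96)
        assert (lo, hi) == pytest.approx((0.994, 5.092), abs=5e-3)

    def test_degenerate_quantile_collapses_to_point(self):
        t = ContingencyTable(20, 80, 10, 90)
        lo, hi = ror_ci(t, z=0.0)
        assert lo == hi == pytest.approx(ror(t))

    def test_zero_cell_requires_correction_first(self):
        with pytest.raises(ValueError):
            ror_ci(ContingencyTable(0, 10, 5, 20))


class TestFisherP:
    def test_balanced_table_is_one(self):
        assert fisher_p(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_enumerated_value_1991(self):
        # hypergeometric enumeration: p = 202 / C(20, 10)
        assert fisher_p(ContingencyTable(1, 9, 9, 1)) \
            == pytest.approx(202 / 184756, rel=1e-9)

    def test_perfect_separation(self):
        assert fisher_p(ContingencyTable(10, 0, 0, 10)) \
            == pytest.approx(2 / 184756, rel=1e-9)

    def test_corrected_or_fractional_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_p(haldane(ContingencyTable(0, 10, 5, 20)))
        with pytest.raises(ValueError):
            fisher_p(ContingencyTable(1.5, 2, 3, 4))

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_transposition_symmetry(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_p(ContingencyTable(a, b, c, d)) \
            == pytest.approx(fisher_p(ContingencyTable(a, c, b, d)),
                             rel=1e-9)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    def test_matches_scipy_reference(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        expected = fisher_exact([[a, b], [c, d]])[1]
        assert fisher_p(ContingencyTable(a, b, c, d)) \
            == pytest.approx(expected, rel=1e-7)


class TestContingency:
    def test_hand_enumerated_cells(self, tiny_rows, term_set):
        t = contingency(tiny_rows, "DRUGA", term_set)
        # DRUGA rows: DVT, HEADACHE, PE, NAUSEA -> a=2, b=2
        # others: DRUGB (2 non-events), DRUGC (DVT, PE + 2 non) -> c=2, d=4
        assert t.cells == (2, 2, 2, 4)
        assert t.total == len(tiny_rows)

    def test_terms_covering_all_pts_zero_b_and_d(self, tiny_rows):
        all_pts = set(tiny_rows["pt"])
        t = contingency(tiny_rows, "DRUGA", all_pts)
        assert t.b == 0 and t.d == 0

    def test_absent_drug_gives_empty_exposed_row(self, tiny_rows, term_set):
        t = contingency(tiny_rows, "NOSUCH", term_set)
        assert t.a == 0 and t.b == 0
        assert t.c + t.d == len(tiny_rows)


def _rows_for(n_drug_event, n_drug_other, n_other_event, n_other_other):
    recs = []
    recs += [(f"a{i}", "TARGET", "DEEP VEIN THROMBOSIS")
             for i in range(n_drug_event)]
    recs += [(f"b{i}", "TARGET", "HEADACHE") for i in range(n_drug_other)]
    recs += [(f"c{i}", "OTHER", "DEEP VEIN THROMBOSIS")
             for i in range(n_other_event)]
    recs += [(f"d{i}", "OTHER", "HEADACHE") for i in range(n_other_other)]
    return pd.DataFrame(recs, columns=["case_id", "drug_name", "pt"])


class TestSignalScan:
    def test_flag_rule_positive_case(self, term_set):
        rows = _rows_for(40, 60, 10, 90)
        res = signals.signal_scan(rows, terms=term_set, min_drug_reports=10)
        row = res.set_index("drug_name").loc["TARGET"]
        assert row["ror"] == pytest.approx(6.0)
        assert row["flagged"]

    def test_report_threshold_boundary_excludes(self, term_set):
        rows = _rows_for(400, 599, 10, 990)  # 999 target rows, huge ROR
        res = signals.signal_scan(rows, terms=term_set,
                                  min_drug_reports=1000)
        row = res.set_index("drug_name").loc["TARGET"]
        assert row["n_drug_reports"] == 999
        assert row["p"] < 0.05 and row["ln_ror"] > 0
        assert not row["flagged"]

    def test_cohort_drug_without_reports_still_reported(self, term_set):
        rows = _rows_for(5, 5, 5, 5)
        res = signals.signal_scan(rows, cohort=["TARGET", "GHOST"],
                                  terms=term_set, min_drug_reports=1)
        ghost = res.set_index("drug_name").loc["GHOST"]
        assert ghost["a"] == 0 and ghost["b"] == 0
        assert not ghost["flagged"]

    def test_bh_adjustment_is_conservative(self, term_set):
        rows = pd.concat([_rows_for(12, 8, 50, 150)] +
                         [_rows_for(0, 0, 0, 0)], ignore_index=True)
        raw = signals.RorSignalScreen(term_set=term_set,
                                      min_drug_reports=1).fit(rows)
        adj = signals.RorSignalScreen(term_set=term_set, min_drug_reports=1,
                                      bh=True).fit(rows)
        assert (adj.results_["p_adj"] >= adj.results_["p"] - 1e-12).all()
        assert set(adj.flagged_drugs_) <= set(raw.flagged_drugs_)

    def test_estimator_follows_sklearn_param_protocol(self, term_set):
        screen = signals.RorSignalScreen(term_set=term_set)
        assert screen.get_params()["alpha"] == 0.05
        screen.set_params(alpha=0.01)
        assert screen.alpha == 0.01


class TestVolcano:
    def test_axis_conventions(self):
        res = pd.DataFrame({
            "drug_name": ["P1", "R1", "X"],
            "ln_ror": [0.5, 0.0, math.log(2.25)],
            "p": [1.0, 0.5, 0.01],
        })
        pts = signals.volcano_points(res)
        assert pts.loc[0, "y"] == 0.0           # p = 1 -> y = 0
        assert pts.loc[1, "x"] == 0.0           # ROR = 1 -> x = 0
        assert pts.loc[2, "x"] == pytest.approx(math.log(2.25))
        assert pts.loc[2, "y"] == pytest.approx(2.0)

    def test_p_floor_keeps_y_finite(self):
        res = pd.DataFrame({"drug_name": ["A"], "ln_ror": [1.0],
                            "p": [0.0]})
        y = signals.volcano_points(res)["y"].iloc[0]
        assert np.isfinite(y)


class TestStratifiedRor:
    def test_identical_event_proportions_give_unit_rors(self, term_set):
        recs = []
        for label, prefix in [("F", "f"), ("M", "m")]:
            recs += [(f"{prefix}{i}", "D", "DEEP VEIN THROMBOSIS")
                     for i in range(5)]
            recs += [(f"{prefix}x{i}", "D", "HEADACHE") for i in range(15)]
        rows = pd.DataFrame(recs, columns=["case_id", "drug_name", "pt"])
        strata = {cid: ("F" if cid.startswith("f") else "M")
                  for cid in rows["case_id"]}
        res = signals.stratified_ror(rows, strata, term_set)
        assert res["ror"].tolist() == pytest.approx([1.0, 1.0])

    def test_hand_built_three_strata(self, term_set):
        spec = {"ORAL": (20, 80), "TOPICAL": (10, 90), "NASAL": (5, 95)}
        recs, strata = [], {}
        for label, (ev, non) in spec.items():
            for i in range(ev):
                cid = f"{label}e{i}"
                recs.append((cid, "D", "THROMBOSIS"))
                strata[cid] = label
            for i in range(non):
                cid = f"{label}n{i}"
                recs.append((cid, "D", "HEADACHE"))
                strata[cid] = label
        rows = pd.DataFrame(recs, columns=["case_id", "drug_name", "pt"])
        res = signals.stratified_ror(rows, strata, term_set) \
            .set_index("stratum")
        # ORAL: (20/80) / (15/185) = 3.0833...
        assert res.loc["ORAL", "ror"] \
            == pytest.approx((20 * 185) / (80 * 15))
        assert res.loc["NASAL", "ror"] \
            == pytest.approx((5 * 170) / (95 * 30))

    def test_unlabeled_cases_excluded(self, term_set):
        rows = _rows_for(5, 5, 5, 5)
        strata = {cid: "F" for cid in rows["case_id"][:10]}
        res = signals.stratified_ror(rows, strata, term_set)
        assert res["a"].sum() + res["b"].sum() == 10


class TestAgeComparison:
    @staticmethod
    def _build(event_ages, non_ages):
        recs, demo = [], []
        for i, age in enumerate(event_ages):
            recs.append((f"e{i}", "D", "DEEP VEIN THROMBOSIS"))
            demo.append((f"e{i}", "F", age))
        for i, age in enumerate(non_ages):
            recs.append((f"n{i}", "D", "HEADACHE"))
            demo.append((f"n{i}", "F", age))
        return (pd.DataFrame(recs, columns=["case_id", "drug_name", "pt"]),
                pd.DataFrame(demo, columns=["case_id", "sex", "age_years"]))

    def test_identical_groups(self, term_set):
        ages = list(range(30, 60))
        rows, demo = self._build(ages, ages)
        res = signals.age_comparison(rows, demo, term_set)
        assert res.median_event == res.median_nonevent
        assert res.p == pytest.approx(1.0)

    def test_shifted_groups_detected(self, term_set):
        rows, demo = self._build(range(1, 101), range(51, 151))
        res = signals.age_comparison(rows, demo, term_set)
        assert res.median_nonevent - res.median_event == pytest.approx(50)
        assert res.p < 1e-3

    def test_empty_event_group_is_error(self, term_set):
        rows, demo = self._build([], range(30, 40))
        with pytest.raises(ValueError):
            signals.age_comparison(rows, demo, term_set)


class TestClassSummary:
    def test_percentages_and_pooling(self, term_set):
        rows = pd.concat([
            _rows_for(40, 60, 100, 800),
        ], ignore_index=True)
        # build a screen over four drugs of one class, three flagged
        recs = []
        for i, (ev, non) in enumerate([(40, 60), (35, 65), (30, 70),
                                       (5, 95)]):
            recs += [(f"x{i}{j}", f"AND{i}", "DEEP VEIN THROMBOSIS")
                     for j in range(ev)]
            recs += [(f"y{i}{j}", f"AND{i}", "HEADACHE")
                     for j in range(non)]
        recs += [(f"z{j}", "BKG", "DEEP VEIN THROMBOSIS")
                 for j in range(100)]
        recs += [(f"w{j}", "BKG", "HEADACHE") for j in range(1900)]
        all_rows = pd.DataFrame(recs,
                                columns=["case_id", "drug_name", "pt"])
        res = signals.signal_scan(all_rows,
                                  cohort=[f"AND{i}" for i in range(4)],
                                  terms=term_set, min_drug_reports=10)
        assert res["flagged"].sum() == 3
        cmap = {f"AND{i}": "Androgen" for i in range(4)}
        summary = signals.class_summary(res, cmap).set_index("class")
        assert summary.loc["Androgen", "n_flagged"] == 3
        assert summary.loc["Androgen", "n_total"] == 4
        assert summary.loc["Androgen", "pct_flagged"] == 75.0
        # pooled 2x2: a=110, b=290, c=100, d=1900
        assert summary.loc["Androgen", "ror"] \
            == pytest.approx((110 * 1900) / (290 * 100))

    def test_absent_class_warns(self, term_set):
        rows = _rows_for(10, 10, 10, 10)
        res = signals.signal_scan(rows, cohort=["TARGET"], terms=term_set,
                                  min_drug_reports=1)
        cmap = {"TARGET": "Androgen", "SOMETHING": "Estrogen"}
        with pytest.warns(UserWarning, match="Estrogen"):
            signals.class_summary(res, cmap)
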