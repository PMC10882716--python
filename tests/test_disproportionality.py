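import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.disproportionality import (ContingencyTable, ReportFacts,
                                        build_contingency, compute_ror,
                                        extract_facts, grouped_ror,
                                        scan_signals)
from faerspv.cohort import DrugLexicon


def facts(pid, regimens=(), pts=()):
    return ReportFacts(primaryid=pid, ps_regimens=frozenset(regimens),
                       pts=frozenset(p.upper() for p in pts))


def test_four_report_enumeration():
    universe = [
        facts("1", regimens=["semaglutide"], pts=["INSOMNIA"]),  # drug+event
        facts("2", regimens=["semaglutide"], pts=["NAUSEA"]),    # drug only
        facts("3", pts=["INSOMNIA"]),                            # event only
        facts("4", pts=["NAUSEA"]),                              # neither
    ]
    t = build_contingency(universe, ["semaglutide"], ["INSOMNIA"])
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
    assert t.total == 4


def test_report_level_counting_not_pt_occurrences():
    universe = [facts("1", regimens=["exenatide"],
                      pts=["INSOMNIA", "ANXIETY"]),
                facts("2", pts=["NAUSEA"])]
    t = build_contingency(universe, ["exenatide"], ["INSOMNIA", "ANXIETY"])
    assert t.a == 1  # two matching PTs still count one report


def test_closed_form_ror_and_ci():
    ror, lo, hi = compute_ror(ContingencyTable(10, 10, 10, 10))
    assert ror == 1.0
    # exp(+-1.96 * sqrt(4/10)), cross-checked against statsmodels Table2x2
    assert lo == pytest.approx(0.289496277, abs=1e-6)
    assert hi == pytest.approx(3.454275858, abs=1e-6)
    # independent oracle: statsmodels Table2x2 (which uses z = ppf(0.975)
    # instead of the rounded 1.96 -- pass the same quantile for the check)
    import statsmodels.api as sm
    from scipy import stats
    table = sm.stats.Table2x2([[10, 10], [10, 10]])
    z = stats.norm.ppf(0.975)
    _, lo_z, hi_z = compute_ror(ContingencyTable(10, 10, 10, 10), z=z)
    assert lo_z == pytest.approx(table.oddsratio_confint()[0], rel=1e-9)
    assert hi_z == pytest.approx(table.oddsratio_confint()[1], rel=1e-9)


def test_proportional_table_gives_unity_exactly():
    ror, _, _ = compute_ror(ContingencyTable(20, 180, 200, 1800))
    assert ror == 1.0


def test_rare_event_elevated_ror_shape():
    # a sparse cell-a table with a strongly elevated reporting odds ratio
    ror, lo, hi = compute_ror(ContingencyTable(7, 993, 1860, 997_140))
    assert ror == pytest.approx(3.779, abs=0.001)
    assert lo > 1.0


def test_zero_cell_not_computable_without_haldane():
    assert compute_ror(ContingencyTable(0, 10, 10, 10)) is None
    est = compute_ror(ContingencyTable(0, 10, 10, 10), haldane=True)
    assert est is not None and est[0] > 0


tables = st.tuples(st.integers(1, 500), st.integers(1, 500),
                   st.integers(1, 500), st.integers(1, 500))


@settings(max_examples=200, deadline=None)
@given(tables)
def test_reciprocity(cells):
    a, b, c, d = cells
    ror, lo, hi = compute_ror(ContingencyTable(a, b, c, d))
    rror, rlo, rhi = compute_ror(ContingencyTable(b, a, d, c))
    assert rror == pytest.approx(1 / ror, rel=1e-12)
    assert rlo == pytest.approx(1 / hi, rel=1e-12)
    assert rhi == pytest.approx(1 / lo, rel=1e-12)


@settings(max_examples=100, deadline=None)
@given(tables)
def test_monotonic_in_a(cells):
    a, b, c, d = cells
    r1, _, _ = compute_ror(ContingencyTable(a, b, c, d))
    r2, _, _ = compute_ror(ContingencyTable(a + 1, b, c, d))
    assert r2 > r1


def _universe_with(a, b, c, d, pt="INSOMNIA", regimen="semaglutide"):
    out = []
    for i in range(a):
        out.append(facts(f"a{i}", regimens=[regimen], pts=[pt]))
    for i in range(b):
        out.append(facts(f"b{i}", regimens=[regimen], pts=["NAUSEA"]))
    for i in range(c):
        out.append(facts(f"c{i}", pts=[pt]))
    for i in range(d):
        out.append(facts(f"d{i}", pts=["NAUSEA"]))
    return out


def test_planted_cells_recovered_exactly():
    universe = _universe_with(50, 950, 500, 98_500)
    t = build_contingency(universe, ["semaglutide"], ["INSOMNIA"])
    assert (t.a, t.b, t.c, t.d) == (50, 950, 500, 98_500)
    assert t.total == len(universe)


def test_cell_conservation_for_every_event_set():
    universe = _universe_with(5, 20, 30, 100)
    for pts in (["INSOMNIA"], ["NAUSEA"], ["INSOMNIA", "NAUSEA"], ["OTHER"]):
        t = build_contingency(universe, ["semaglutide"], pts)
        assert t.total == len(universe)


def test_empty_universe_is_an_error():
    with pytest.raises(ValueError):
        build_contingency([], ["semaglutide"], ["INSOMNIA"])


def test_signal_criteria_boundaries():
    # a=4 with an elevated CI is still not a signal: count rules first
    u = _universe_with(4, 100, 20, 10_000)
    res = scan_signals(u, {"drug": ["semaglutide"]}, {"pt": ["INSOMNIA"]})
    assert len(res) == 1
    assert not res[0].is_signal
    assert res[0].reason == "below_count_threshold"
    assert res[0].ci_low > 1
    # a=5 exactly at the count threshold with ci_low > 1 is a signal
    u = _universe_with(5, 95, 100, 9_900)
    res = scan_signals(u, {"drug": ["semaglutide"]}, {"pt": ["INSOMNIA"]})
    assert res[0].table.a == 5
    assert res[0].ci_low > 1
    assert res[0].is_signal


def test_scan_orders_signals_by_descending_ror(small_universe, small_retained):
    _, truth = small_universe
    facts_ = extract_facts(small_retained, DrugLexicon.glp1())
    res = scan_signals(facts_, {"overall": None},
                       {pt: [pt] for pt in truth.planted_tables})
    rors = [r.ror for r in res if r.is_signal]
    assert rors == sorted(rors, reverse=True)
    # pipeline cells equal the generator's exact bookkeeping
    for r in res:
        t = truth.planted_tables[r.event_label]
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == \
            (t.a, t.b, t.c, t.d)


def test_grouped_ror_degenerate_and_overlap():
    u = _universe_with(5, 20, 30, 100)
    single = grouped_ror(u, ["semaglutide"], ["INSOMNIA"])
    direct = scan_signals(u, {"target": ["semaglutide"]},
                          {"INSOMNIA": ["INSOMNIA"]})[0]
    assert single.table == direct.table

    # disjoint report sets add; co-reported PTs on one report count once
    disjoint = ([facts(f"x{i}", regimens=["exenatide"], pts=["ANXIETY"])
                 for i in range(5)] +
                [facts(f"y{i}", regimens=["exenatide"], pts=["STRESS"])
                 for i in range(7)] +
                [facts(f"z{i}", pts=["NAUSEA"]) for i in range(50)])
    g = grouped_ror(disjoint, ["exenatide"], ["ANXIETY", "STRESS"])
    assert g.table.a == 12
    co = ([facts(f"x{i}", regimens=["exenatide"], pts=["ANXIETY", "STRESS"])
           for i in range(5)] +
          [facts(f"z{i}", pts=["NAUSEA"]) for i in range(50)])
    g = grouped_ror(co, ["exenatide"], ["ANXIETY", "STRESS"])
    assert g.table.a == 5

    with pytest.raises(ValueError):
        grouped_ror(u, ["semaglutide"], [])


def test_class_exclusive_comparator_drops_sibling_reports():
    universe = (_universe_with(5, 20, 30, 100) +
                [facts(f"s{i}", regimens=["exenatide"], pts=["INSOMNIA"])
                 for i in range(10)])
    full = scan_signals(universe, {"d": ["semaglutide"]},
                        {"pt": ["INSOMNIA"]})[0]
    excl = scan_signals(universe, {"d": ["semaglutide"],
                                   "other": ["exenatide"]},
                        {"pt": ["INSOMNIA"]}, class_exclusive=True)
    excl_d = [r for r in excl if r.drug_label == "d"][0]
    # sibling exenatide reports sit in the comparator under the full-database
    # rule but vanish under the class-exclusive rule
    assert full.table.c == excl_d.table.c + 10
    assert full.table.n_drug == excl_d.table.n_drug
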