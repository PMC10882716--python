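import pytest

from faerspv.cohort import (DrugLexicon, PSYCHIATRIC_SOC, PtSocMap,
                            build_cohort, match_drug)
from faerspv.io import DrugRecord

from conftest import make_bundle

LEX = DrugLexicon.glp1()
SOC = PtSocMap.from_pairs({
    "INSOMNIA": (PSYCHIATRIC_SOC, "10037175"),
    "ANXIETY": (PSYCHIATRIC_SOC, "10037175"),
    "NAUSEA": ("gastrointestinal disorders", "10017947"),
})


def _drug(name, prod_ai="", role="PS"):
    return DrugRecord(primaryid="1", drug_seq="1", drugname=name,
                      prod_ai=prod_ai, role_cod=role)


@pytest.mark.parametrize("name, expected", [
    ("OZEMPIC", {"semaglutide"}),
    ("ozempic 0.5 mg pen", {"semaglutide"}),          # whole-word containment
    ("Semaglutide", {"semaglutide"}),
    ("BYETTA", {"exenatide"}),
    ("TRULICITY (DULAGLUTIDE)", {"dulaglutide"}),
    ("metformin", set()),
    ("OZEMPICX", set()),                              # no substring matching
    ("", set()),
])
def test_match_drug_by_name(name, expected):
    assert match_drug(_drug(name), LEX) == frozenset(expected)


def test_match_drug_via_active_ingredient_field():
    rec = _drug("SOME TRADE NAME 2MG", prod_ai="TIRZEPATIDE")
    assert match_drug(rec, LEX) == frozenset({"tirzepatide"})
    # restricting the matched fields is configurable
    assert match_drug(rec, LEX, fields=("drugname",)) == frozenset()


def test_cohort_requires_primary_suspect_role():
    ps = make_bundle(pid="1", drugs=(("1", "BYETTA", "PS"),),
                     pts=("Insomnia",))
    conc = make_bundle(pid="2", drugs=(("1", "VICTOZA", "C"),),
                       pts=("Insomnia",))
    res = build_cohort([ps, conc], LEX, SOC)
    assert [r.primaryid for r in res.reports] == ["1"]
    assert res.reports[0].regimens == frozenset({"exenatide"})
    assert res.reports[0].is_target_soc


def test_target_soc_flag_and_unmapped_pts():
    b = make_bundle(pid="1", pts=("Nausea", "Mystery Term"))
    res = build_cohort([b], LEX, SOC)
    assert res.n == 1
    assert not res.reports[0].is_target_soc          # no psychiatric PT
    assert res.unmapped_pts == {"MYSTERY TERM": 1}   # counted, not dropped
    assert res.reports[0].pt_soc["MYSTERY TERM"] is None


def test_lexicon_monotonicity():
    bundles = [make_bundle(pid="1", drugs=(("1", "OZEMPIC", "PS"),)),
               make_bundle(pid="2", drugs=(("1", "NEWDRUG", "PS"),))]
    small = DrugLexicon.from_names({"semaglutide": ["OZEMPIC"]})
    large = DrugLexicon.from_names({"semaglutide": ["OZEMPIC"],
                                    "newdrug": ["NEWDRUG"]})
    n_small = build_cohort(bundles, small, SOC).n
    n_large = build_cohort(bundles, large, SOC).n
    assert n_large >= n_small


def test_per_regimen_counts_vs_overall():
    # equality when no report names two regimens as primary suspect...
    single = [make_bundle(pid="1", drugs=(("1", "OZEMPIC", "PS"),),
                          pts=("Insomnia",)),
              make_bundle(pid="2", drugs=(("1", "BYETTA", "PS"),),
                          pts=("Anxiety",))]
    res = build_cohort(single, LEX, SOC)
    counts = res.counts_by_regimen(target_only=True)
    assert sum(counts.values()) == res.n_target_soc
    # ...and a strict excess when one report does
    dual = single + [make_bundle(
        pid="3", drugs=(("1", "OZEMPIC", "PS"), ("2", "BYETTA", "PS")),
        pts=("Insomnia",))]
    res2 = build_cohort(dual, LEX, SOC)
    counts2 = res2.counts_by_regimen(target_only=True)
    assert sum(counts2.values()) == res2.n_target_soc + 1


def test_planted_cohort_recovered_exactly(small_universe, small_retained,
                                          small_config):
    _, truth = small_universe
    res = build_cohort(small_retained, LEX, small_config.soc_map())
    assert frozenset(r.caseid for r in res.reports) == truth.cohort_caseids
    assert frozenset(r.caseid for r in res.reports if r.is_target_soc) == \
        truth.target_soc_caseids
    assert res.counts_by_regimen() == {
        k: v for k, v in truth.regimen_counts.items() if v > 0}
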