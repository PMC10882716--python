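import math

import numpy as np
import pytest
from scipy import stats

from faerspv.cohort import DrugLexicon, build_cohort
from faerspv.onset import (EXCLUDED_INVALID_ORDER,
                           EXCLUDED_MISSING, EXCLUDED_NONPOSITIVE, INCLUDED,
                           STATUSES, bin_counts, compare_onset, compute_onset,
                           compute_onsets, summarize_onset)

from conftest import make_bundle

LEX = DrugLexicon.glp1()


def _cohort_report(event, thers, drugs=(("1", "OZEMPIC", "PS"),), soc_map=None):
    from faerspv.cohort import PSYCHIATRIC_SOC, PtSocMap
    soc = soc_map or PtSocMap.from_pairs(
        {"INSOMNIA": (PSYCHIATRIC_SOC, "10037175")})
    b = make_bundle(pid="1", event=event, drugs=drugs, pts=("Insomnia",),
                    thers=thers)
    return build_cohort([b], LEX, soc).reports[0]


@pytest.mark.parametrize("start, event, status, days", [
    ("20200101", "20200201", INCLUDED, 31),
    ("20200101", "20200101", EXCLUDED_NONPOSITIVE, None),
    ("20200301", "20200101", EXCLUDED_INVALID_ORDER, None),
    ("", "20200201", EXCLUDED_MISSING, None),
    ("202001", "20200201", EXCLUDED_MISSING, None),   # month precision unusable
    ("20200101", "", EXCLUDED_MISSING, None),
    ("20200101", "202002", EXCLUDED_MISSING, None),
])
def test_onset_status_rules(start, event, status, days):
    thers = ((("1", start),) if start else ())
    rec = compute_onset(_cohort_report(event, thers))
    assert rec.status == status
    assert rec.onset_days == days


def test_earliest_matched_start_date_is_initiation():
    # two therapy rows for the matched drug: the earlier one counts;
    # an unmatched concomitant's therapy row is ignored
    rec = compute_onset(_cohort_report(
        "20200301",
        thers=(("1", "20200210"), ("1", "20200110"), ("2", "20190101")),
        drugs=(("1", "OZEMPIC", "PS"), ("2", "METFORMIN", "C"))))
    assert rec.status == INCLUDED
    assert rec.onset_days == 51  # from 2020-01-10


def test_bin_counts_hand_countable():
    counts = bin_counts([10, 20, 40])
    assert counts["0-30"] == 2 and counts["30-60"] == 1
    # edges: day 30 belongs to the first bin, day 31 to the second
    edges = bin_counts([30, 31, 360, 361])
    assert edges["0-30"] == 1 and edges["30-60"] == 1
    assert edges["180-360"] == 1 and edges["360+"] == 1


def test_summary_quantiles_and_bin_conservation():
    from faerspv.onset import OnsetRecord
    values = [10, 20, 40, 75, 400]
    recs = [OnsetRecord(str(i), "semaglutide", INCLUDED, v)
            for i, v in enumerate(values)]
    recs.append(OnsetRecord("x", "semaglutide", EXCLUDED_MISSING))
    summary = summarize_onset(recs)["semaglutide"]
    assert summary.n_included == 5
    assert summary.median == 40
    assert sum(summary.bin_counts.values()) == summary.n_included
    assert summary.exclusions[EXCLUDED_MISSING] == 1
    assert summary.curve.cum_fraction.iloc[-1] == 1.0


def test_insufficient_group_is_marked():
    from faerspv.onset import OnsetRecord
    recs = [OnsetRecord("1", "lixisenatide", INCLUDED, 5)]
    summary = summarize_onset(recs, min_included=5)["lixisenatide"]
    assert summary.insufficient
    assert summary.median is None


def test_every_report_lands_in_exactly_one_status(small_retained,
                                                  small_config):
    cohort = build_cohort(small_retained, LEX, small_config.soc_map())
    cases = [r for r in cohort.reports if r.is_target_soc]
    records = compute_onsets(cases)
    assert len(records) == len(cases)  # single-regimen generator
    assert all(r.status in STATUSES for r in records)
    summaries = summarize_onset(records)
    overall = summaries["overall"]
    assert sum(overall.exclusions.values()) == len(records)
    assert sum(overall.bin_counts.values()) == overall.n_included


def test_generator_onset_statuses_match_pipeline(small_universe,
                                                 small_retained, small_config):
    _, truth = small_universe
    cohort = build_cohort(small_retained, LEX, small_config.soc_map())
    got = {r.caseid: compute_onset(r) for r in cohort.reports}
    for t in truth.onsets:
        rec = got[t.caseid]
        assert rec.status == t.status, t.caseid
        if t.status == INCLUDED:
            assert rec.onset_days == t.true_days


def test_identical_samples_are_not_significant():
    x = list(range(1, 101))
    cmp = compare_onset({"a": x, "b": x})
    assert cmp.kruskal_p > 0.9
    assert (cmp.pairwise.p_holm > 0.9).all()


def test_scale_shifted_samples_are_detected():
    rng = np.random.default_rng(0)
    a = rng.lognormal(math.log(10), 1.0, 500)
    b = rng.lognormal(math.log(30), 1.0, 500)
    cmp = compare_onset({"a": a, "b": b}, include_logrank=True)
    assert cmp.kruskal_p < 1e-3
    assert (cmp.pairwise.p_holm < 1e-3).all()
    assert (cmp.logrank.p_raw < 1e-3).all()


def test_degenerate_groups_are_skipped_with_reason():
    cmp = compare_onset({"a": [1], "b": [1, 2, 3], "c": [2, 3, 4]})
    assert cmp.skipped == {"a": "n=1 < 2"}
    assert set(cmp.groups) == {"b", "c"}
    allsame = compare_onset({"a": [5, 5], "b": [5, 5]})
    assert allsame.kruskal_p is None
    assert allsame.skipped == {"a": "all-ties", "b": "all-ties"}


def test_mannwhitney_agrees_with_permutation_oracle():
    rng = np.random.default_rng(7)
    a = rng.lognormal(math.log(12), 0.8, 120)
    b = rng.lognormal(math.log(17), 0.8, 120)
    cmp = compare_onset({"a": a, "b": b})
    p_mw = float(cmp.pairwise.p_raw.iloc[0])

    def u_stat(x, y, axis):
        pooled = np.concatenate([x, y], axis=axis)
        ranks = stats.rankdata(pooled, axis=axis)
        n1 = x.shape[axis]
        r1 = np.take(ranks, np.arange(n1), axis=axis).sum(axis=axis)
        return r1 - n1 * (n1 + 1) / 2

    perm = stats.permutation_test(
        (a, b), u_stat, permutation_type="independent",
        alternative="two-sided", n_resamples=10_000,
        rng=np.random.default_rng(1))
    assert abs(p_mw - perm.pvalue) < 0.02


def test_global_test_type_i_error_near_nominal():
    # three identical log-normal groups: non-significant at alpha=0.05 in
    # >= 94% of replicates
    rng = np.random.default_rng(3)
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        groups = {k: rng.lognormal(math.log(20), 1.0, 30) for k in "abc"}
        cmp = compare_onset(groups)
        hits += cmp.kruskal_p > 0.05
    assert hits / n_rep >= 0.94
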